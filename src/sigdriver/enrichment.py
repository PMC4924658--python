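"""Pathway over-representation by the right-tailed Fisher exact test.

With a universe of N genes, a pathway of K members, a signature of n genes
and an overlap of x, the right-tail probability is the hypergeometric upper
tail P(X >= x). Raw p-values are the primary statistic; Benjamini-Hochberg
adjusted values are reported alongside.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .exceptions import AnalysisError


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene sets: name <tab> description <tab> genes..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3 or not line.strip():
                continue
            sets[cols[0]] = [g for g in cols[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sets:
            fh.write("\t".join([name, description, *sets[name]]) + "\n")


def fisher_right_tail(x: int, n: int, K: int, N: int) -> float:
    """P(overlap >= x) for a signature of n and a pathway of K in N genes.

    Computed from the hypergeometric survival function (log-space internally),
    so x = 0 gives exactly 1.
    """
    if not (0 <= x <= min(n, K)) or n > N or K > N or min(n, K, N) < 0:
        raise AnalysisError(
            f"inconsistent counts: x={x}, n={n}, K={K}, N={N}")
    return float(hypergeom.sf(x - 1, N, K, n))


def enrich(signature: Sequence[str], pathways: Mapping[str, Sequence[str]],
           universe: Sequence[str]) -> pd.DataFrame:
    """Test each pathway for over-representation of the signature.

    Signature and pathway genes outside the universe are dropped (the dropped
    signature genes are recorded in ``attrs["dropped_signature_genes"]``).
    Results are sorted by ascending raw p (ties by pathway id) and carry
    Benjamini-Hochberg adjusted p-values.
    """
    uni = set(universe)
    if not uni:
        raise AnalysisError("empty gene universe")
    sig = set(signature) & uni
    dropped = sorted(set(signature) - uni)
    N, n = len(uni), len(sig)

    rows = []
    for name in sorted(pathways):
        members = set(pathways[name]) & uni
        K = len(members)
        x = len(sig & members)
        p = fisher_right_tail(x, n, K, N) if K else 1.0
        rows.append((name, x, n, K, N, p))
    out = pd.DataFrame(rows, columns=["pathway", "x", "n", "K", "N", "p_right"])
    if len(out):
        out["p_adj"] = multipletests(out["p_right"], method="fdr_bh")[1]
    else:
        out["p_adj"] = []
    out = out.sort_values(["p_right", "pathway"]).reset_index(drop=True)
    out.attrs["dropped_signature_genes"] = dropped
    return out
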