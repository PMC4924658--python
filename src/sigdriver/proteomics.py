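"""Paired two-class t-test over replicate protein abundance pairs.

Each protein is measured in matched (control, treated) replicate pairs on the
log2 scale. The reported difference is mean(control - treated), so a negative
difference means the protein is *up*-regulated under treatment; the paired t
statistic is mean(d) / (sd(d) / sqrt(n_pairs)) with n_pairs - 1 degrees of
freedom. Proteins passing p < alpha (default 0.001) become the seed list for
interaction-network expansion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AnalysisError


@dataclass
class PairedAbundanceTable:
    """Log2 abundances in matched control/treated column pairs."""

    proteins: pd.Index
    control: pd.DataFrame   # proteins x pairs
    treated: pd.DataFrame   # proteins x pairs, same pair order

    @property
    def n_pairs(self) -> int:
        return self.control.shape[1]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PairedAbundanceTable":
        """Columns: protein, control_1..k, treated_1..k (any id column name)."""
        frame = frame.set_index(frame.columns[0])
        ctrl_cols = sorted([c for c in frame.columns if c.startswith("control")],
                           key=lambda c: int(c.split("_")[-1]))
        trt_cols = sorted([c for c in frame.columns if c.startswith("treated")],
                          key=lambda c: int(c.split("_")[-1]))
        if len(ctrl_cols) != len(trt_cols) or not ctrl_cols:
            raise AnalysisError("columns must come in complete "
                                "control_i/treated_i pairs")
        if len(ctrl_cols) < 2:
            raise AnalysisError("need >= 2 replicate pairs for a paired t-test")
        return cls(proteins=frame.index,
                   control=frame[ctrl_cols], treated=frame[trt_cols])

    @classmethod
    def from_tsv(cls, path) -> "PairedAbundanceTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def paired_t(table: PairedAbundanceTable) -> pd.DataFrame:
    """Per-protein paired t-test of control vs treated.

    Returns a frame with ``t_diff`` (mean control - treated), ``t_stat``,
    two-sided ``p`` and ``pattern`` (up/down in treated; ``unchanged`` for an
    exactly flat protein). Proteins with any missing value are excluded and
    listed in ``attrs["excluded"]``; zero-variance differences get p = 1 when
    the mean difference is 0, otherwise the p -> 0 limit, with a
    ``degenerate`` flag either way.
    """
    ctrl = table.control.to_numpy(float)
    trt = table.treated.to_numpy(float)
    complete = ~(np.isnan(ctrl).any(axis=1) | np.isnan(trt).any(axis=1))
    excluded = sorted(table.proteins[~complete].astype(str))

    d = (ctrl - trt)[complete]
    n = d.shape[1]
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p[degenerate & (mean == 0)] = 1.0
    p[degenerate & (mean != 0)] = 0.0
    t[degenerate & (mean == 0)] = 0.0

    pattern = np.where(mean < 0, "up", np.where(mean > 0, "down", "unchanged"))
    out = pd.DataFrame({
        "t_diff": mean, "t_stat": t, "p": p, "pattern": pattern,
        "degenerate": degenerate,
    }, index=pd.Index(table.proteins[complete], name="protein"))
    out.attrs["excluded"] = excluded
    return out


def filter_significant(results: pd.DataFrame, alpha: float = 0.001
                       ) -> pd.DataFrame:
    """Retain proteins with p < alpha, sorted by ascending p (ties by id)."""
    out = results[results["p"] < alpha].copy()
    out["_id"] = out.index
    out = out.sort_values(["p", "_id"]).drop(columns="_id")
    return out
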