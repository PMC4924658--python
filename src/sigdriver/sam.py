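"""Two-class significance analysis with a moderated t-like statistic.

For gene i the score is

    d_i = (mean_case - mean_control) / (s_i + s0)

where s_i is the pooled standard error of the two group means and s0, the
exchangeability constant, is a small positive offset chosen so that the
spread of d is as uniform as possible across the range of s (it protects
low-variance genes from dominating the ranking). Significance is assessed by
comparing the ordered observed scores to the mean ordered scores under group
label permutations: gene ranks whose observed score departs from the permuted
expectation by at least ``delta`` are called, and the false discovery rate at
that ``delta`` is the median permuted count of scores beyond the calling
cutoffs divided by the number of calls.

Fold changes are computed on the linear scale from log2 group means,
2**(mean_case - mean_control); the fold-change filter is applied
symmetrically as max(fc, 1/fc) >= cutoff so down-regulation passes too.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ExpressionCohort
from .exceptions import AnalysisError

DEFAULT_S0_PERCENTILES = tuple(range(0, 101, 5))


# ---------------------------------------------------------------------------
# core statistic
# ---------------------------------------------------------------------------

def sam_scatter(matrix: np.ndarray, case_mask: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene numerator (case mean - control mean) and pooled scatter s.

    s_i = sqrt( (1/n1 + 1/n2)/(n1 + n2 - 2) * (SS_control + SS_case) ),
    the pooled standard error of the difference of the two group means.
    """
    case_mask = np.asarray(case_mask, bool)
    n2 = int(case_mask.sum())
    n1 = int((~case_mask).sum())
    if n1 < 2 or n2 < 2:
        raise AnalysisError("need >= 2 samples per group")
    ctrl = matrix[:, ~case_mask]
    case = matrix[:, case_mask]
    numerator = case.mean(axis=1) - ctrl.mean(axis=1)
    ss = (((ctrl - ctrl.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
          + ((case - case.mean(axis=1, keepdims=True)) ** 2).sum(axis=1))
    a = (1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2)
    return numerator, np.sqrt(a * ss)


def choose_s0(s: np.ndarray, numerators: np.ndarray,
              percentiles=DEFAULT_S0_PERCENTILES) -> float:
    """Pick the exchangeability constant from candidate percentiles of s.

    For each candidate s0 the scores d = numerator/(s + s0) are windowed by
    s-quantile; the candidate minimizing the coefficient of variation of the
    windows' median absolute deviations of d wins (ties go to the smaller
    percentile). Deterministic given its inputs.
    """
    s = np.asarray(s, float)
    numerators = np.asarray(numerators, float)
    if s.size < 10:
        raise AnalysisError("need >= 10 genes to calibrate s0")
    if np.all(s == 0):
        warnings.warn("all per-gene scatters are zero; s0 = 0", stacklevel=2)
        return 0.0

    order = np.argsort(s, kind="stable")
    n_windows = min(100, max(2, s.size // 10))
    windows = np.array_split(order, n_windows)

    best = (np.inf, 0.0)
    for p in percentiles:
        s0 = float(np.percentile(s, p))
        with np.errstate(invalid="ignore", divide="ignore"):
            d = numerators / (s + s0)
        d[~np.isfinite(d)] = 0.0  # 0/0 for exactly flat genes
        mads = []
        for w in windows:
            dw = d[w]
            mads.append(np.median(np.abs(dw - np.median(dw))))
        mads = np.asarray(mads)
        mean = mads.mean()
        cv = mads.std(ddof=1) / mean if mean > 0 else np.inf
        if cv < best[0] - 1e-15:
            best = (cv, s0)
    return best[1]


# ---------------------------------------------------------------------------
# permutations
# ---------------------------------------------------------------------------

def _permutation_masks(n: int, n_case: int, B: int, seed: int
                       ) -> tuple[np.ndarray, bool]:
    """Boolean case-assignment masks: all C(n, n_case) if they fit in B,
    otherwise B random draws. Returns (masks, enumerated)."""
    total = math.comb(n, n_case)
    if total <= B:
        masks = np.zeros((total, n), dtype=bool)
        for r, combo in enumerate(itertools.combinations(range(n), n_case)):
            masks[r, list(combo)] = True
        return masks, True
    rng = np.random.default_rng(seed)
    masks = np.zeros((B, n), dtype=bool)
    for r in range(B):
        masks[r, rng.choice(n, size=n_case, replace=False)] = True
    return masks, False


def _perm_order_stats(matrix: np.ndarray, masks: np.ndarray, s0: float
                      ) -> np.ndarray:
    """Sorted permuted d scores, one row per permutation."""
    out = np.empty((masks.shape[0], matrix.shape[0]))
    for r, mask in enumerate(masks):
        num, s = sam_scatter(matrix, mask)
        out[r] = np.sort(num / (s + s0))
    return out


@dataclass
class _PermutationContext:
    d_sorted: np.ndarray        # ascending observed d (ties broken by gene id)
    sort_idx: np.ndarray        # gene index per rank
    dbar: np.ndarray            # expected order statistics over permutations
    perm_sorted: np.ndarray     # permutations x genes, each row ascending
    enumerated: bool


def _build_context(matrix: np.ndarray, case_mask: np.ndarray, s0: float,
                   gene_ids: np.ndarray, B: int, seed: int
                   ) -> _PermutationContext:
    num, s = sam_scatter(matrix, case_mask)
    d = num / (s + s0)
    # stable rank: ascending d, ties broken by gene id for determinism
    sort_idx = np.lexsort((gene_ids, d))
    masks, enumerated = _permutation_masks(matrix.shape[1],
                                           int(case_mask.sum()), B, seed)
    perm_sorted = _perm_order_stats(matrix, masks, s0)
    return _PermutationContext(d[sort_idx], sort_idx, perm_sorted.mean(axis=0),
                               perm_sorted, enumerated)


def _evaluate_delta(ctx: _PermutationContext, delta: float,
                    fc_pass: np.ndarray | None) -> tuple[np.ndarray, float]:
    """Called flags (in rank order) and estimated FDR at one delta."""
    diff = ctx.d_sorted - ctx.dbar
    called = np.abs(diff) >= delta
    if fc_pass is not None:
        called &= fc_pass[ctx.sort_idx]
    n_called = int(called.sum())
    if n_called == 0:
        return called, 0.0
    pos = called & (diff >= delta)
    neg = called & (diff <= -delta)
    cut_up = ctx.d_sorted[pos].min() if pos.any() else np.inf
    cut_low = ctx.d_sorted[neg].max() if neg.any() else -np.inf
    false = ((ctx.perm_sorted >= cut_up).sum(axis=1)
             + (ctx.perm_sorted <= cut_low).sum(axis=1))
    fdr = float(np.median(false)) / n_called
    return called, float(min(max(fdr, 0.0), 1.0))


def permutation_fdr(matrix: np.ndarray, case_mask: np.ndarray, delta: float,
                    B: int, seed: int, s0: float | None = None,
                    fc_cutoff: float | None = None
                    ) -> tuple[np.ndarray, float]:
    """Called flags (gene order) and the FDR estimate at threshold ``delta``.

    When all distinct case/control label assignments fit within ``B`` they
    are enumerated exhaustively and the result does not depend on ``seed``.
    """
    if B < 1:
        raise AnalysisError("permutation count B must be >= 1")
    matrix = np.asarray(matrix, float)
    num, s = sam_scatter(matrix, case_mask)
    if s0 is None:
        s0 = choose_s0(s, num)
    gene_ids = np.arange(matrix.shape[0])
    ctx = _build_context(matrix, case_mask, s0, gene_ids, B, seed)
    fc_pass = None
    if fc_cutoff is not None:
        fc = 2.0 ** num
        fc_pass = np.maximum(fc, 1.0 / fc) >= fc_cutoff
    called_ranked, fdr = _evaluate_delta(ctx, delta, fc_pass)
    called = np.zeros(matrix.shape[0], dtype=bool)
    called[ctx.sort_idx] = called_ranked
    return called, fdr


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

@dataclass
class SamResults:
    """Per-gene scores and calls from a fitted :class:`SamModel`.

    ``table`` has one row per gene: d, s, numerator (log2 case - control
    mean), fold_change (linear), expected d (permutation order statistic at
    the gene's rank), called, direction. Scalars: s0, delta, fdr (estimate at
    delta), n_permutations, enumerated.
    """

    table: pd.DataFrame
    s0: float
    delta: float
    fdr: float
    n_permutations: int
    enumerated: bool
    fc_cutoff: float | None
    fdr_target: float | None

    @property
    def called(self) -> pd.Series:
        return self.table["called"]

    @property
    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["called"]])

    def summary(self) -> str:
        n_up = int((self.table["called"] & (self.table["direction"] == "up")).sum())
        n_down = int((self.table["called"]
                      & (self.table["direction"] == "down")).sum())
        return "\n".join([
            "Significance analysis (permutation d-statistic)",
            "=" * 47,
            f"genes: {len(self.table)}   permutations: {self.n_permutations}"
            f" ({'exhaustive' if self.enumerated else 'sampled'})",
            f"s0 = {self.s0:.4f}   delta = {self.delta:.2f}   "
            f"estimated FDR = {self.fdr:.4f}",
            f"called: {n_up + n_down}  (up {n_up}, down {n_down})",
        ])

    def plot(self, ax=None):
        """Observed-vs-expected score plot with the delta calling band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.table.sort_values("d")
        colors = np.where(~t["called"], "0.6",
                          np.where(t["direction"] == "up", "red", "green"))
        ax.scatter(t["expected_d"], t["d"], s=8, c=colors)
        lo, hi = t["expected_d"].min(), t["expected_d"].max()
        grid = np.linspace(lo, hi, 2)
        ax.plot(grid, grid, "k-", lw=0.8)
        ax.plot(grid, grid + self.delta, "k--", lw=0.8)
        ax.plot(grid, grid - self.delta, "k--", lw=0.8)
        ax.set_xlabel("expected d (permutations)")
        ax.set_ylabel("observed d")
        return ax


class SamModel:
    """Two-class significance model over a log2 expression matrix.

    Parameters
    ----------
    matrix : pandas.DataFrame
        Genes x samples, log2 scale.
    groups : sequence of {"control", "case"}
        One label per sample column.
    """

    def __init__(self, matrix: pd.DataFrame, groups):
        self.matrix = matrix
        groups = np.asarray(groups)
        if groups.shape[0] != matrix.shape[1]:
            raise AnalysisError("one group label per sample required")
        self.case_mask = groups == "case"
        if self.case_mask.sum() < 2 or (~self.case_mask).sum() < 2:
            raise AnalysisError("need >= 2 samples per group")

    @classmethod
    def from_cohort(cls, cohort: ExpressionCohort,
                    samples=None) -> "SamModel":
        if samples is not None:
            cohort = cohort.subset(samples=samples)
        return cls(cohort.values, cohort.group.to_numpy())

    def fit(self, delta: float | None = None, fdr_target: float = 0.05,
            fc_cutoff: float | None = 1.2, B: int = 200, seed: int = 0,
            s0_percentiles=DEFAULT_S0_PERCENTILES,
            delta_step: float = 0.05) -> SamResults:
        """Score genes and call significance.

        If ``delta`` is None it is chosen automatically as the smallest grid
        multiple of ``delta_step`` whose estimated FDR is at most
        ``fdr_target``.
        """
        values = self.matrix.to_numpy(float)
        gene_ids = self.matrix.index.to_numpy(str)
        num, s = sam_scatter(values, self.case_mask)
        s0 = choose_s0(s, num, percentiles=s0_percentiles)
        ctx = _build_context(values, self.case_mask, s0, gene_ids, B, seed)

        fc = 2.0 ** num
        fc_pass = (np.maximum(fc, 1.0 / fc) >= fc_cutoff) \
            if fc_cutoff is not None else None

        if delta is None:
            max_dev = float(np.abs(ctx.d_sorted - ctx.dbar).max())
            grid = np.arange(delta_step,
                             max_dev + 2 * delta_step, delta_step)
            delta = float(grid[-1])
            for cand in grid:
                _, fdr_cand = _evaluate_delta(ctx, float(cand), fc_pass)
                if fdr_cand <= fdr_target:
                    delta = float(cand)
                    break
        called_ranked, fdr = _evaluate_delta(ctx, delta, fc_pass)
        called = np.zeros(values.shape[0], dtype=bool)
        called[ctx.sort_idx] = called_ranked
        expected = np.empty(values.shape[0])
        expected[ctx.sort_idx] = ctx.dbar

        d = num / (s + s0)
        table = pd.DataFrame({
            "d": d, "s": s, "numerator": num, "fold_change": fc,
            "expected_d": expected, "fdr": fdr, "called": called,
            "direction": np.where(num > 0, "up",
                                  np.where(num < 0, "down", "flat")),
        }, index=pd.Index(self.matrix.index, name="gene"))
        return SamResults(table=table, s0=float(s0), delta=float(delta),
                          fdr=float(fdr),
                          n_permutations=ctx.perm_sorted.shape[0],
                          enumerated=ctx.enumerated, fc_cutoff=fc_cutoff,
                          fdr_target=fdr_target)
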