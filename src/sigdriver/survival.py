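"""Median-split survival analysis: Kaplan-Meier curves, log-rank, correlation.

Samples are split into high/low marker-expression groups at the median
(ties to the low group), survival in each group is summarized by the
product-limit estimator, and the groups are compared with the Mantel-Cox
log-rank test: at each distinct event time t_j with n_j at risk (n_1j in
group 1) and d_j events, the group-1 expectation is E_1j = d_j n_1j / n_j
with hypergeometric variance

    V_j = d_j (n_1j / n_j) (1 - n_1j / n_j) (n_j - d_j) / (n_j - 1)

and chi2 = (sum(O_1j - E_1j))^2 / sum(V_j) on 1 degree of freedom.
Marker-marker association uses the sample Pearson correlation with the
t-distributed two-sided p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AnalysisError


def read_survival_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"time", "event", "expression"}
    missing = required - set(df.columns)
    if missing:
        raise AnalysisError(f"survival table lacks columns: {sorted(missing)}")
    return df


def median_split(table: pd.DataFrame, expr_col: str = "expression"
                 ) -> pd.DataFrame:
    """Assign each sample to ``high`` (expression > median) or ``low`` (<=).

    Values tied with the median go to the low group, the deterministic rule
    that keeps both groups non-empty whenever expression is non-constant.
    Constant expression raises :class:`AnalysisError`.
    """
    expr = table[expr_col].to_numpy(float)
    if np.all(expr == expr[0]):
        raise AnalysisError("expression is constant; median split impossible")
    med = float(np.median(expr))
    out = table.copy()
    out["group"] = np.where(expr > med, "high", "low")
    return out


@dataclass
class KMCurve:
    """Product-limit survival estimate at the distinct event times.

    ``times`` are the event times in ascending order; ``at_risk`` and
    ``events`` the risk-set size and event count at each; ``survival`` the
    running product of (1 - d/n). Censored-only times shrink later risk sets
    but contribute no step.
    """

    times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "n": self.at_risk,
                             "d": self.events, "S": self.survival})

    def survival_at(self, t: float) -> float:
        """S(t): 1 before the first event, step function thereafter."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def plot(self, ax=None, label=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xs = np.r_[0.0, np.repeat(self.times, 2)]
        ys = np.r_[1.0, 1.0, np.repeat(self.survival, 2)][:-1]
        ax.plot(xs, ys, drawstyle="default", label=label)
        ax.set_xlabel("time (months)")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.05)
        return ax


def km_curve(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if times.size == 0:
        raise AnalysisError("empty survival input")
    if times.size != events.size:
        raise AnalysisError("times and events must have equal length")

    event_times = np.unique(times[events == 1])
    at_risk, d_counts, surv = [], [], []
    s = 1.0
    for t in event_times:
        n_t = int((times >= t).sum())
        d_t = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d_t / n_t
        at_risk.append(n_t)
        d_counts.append(d_t)
        surv.append(s)
    return KMCurve(times=event_times, at_risk=np.array(at_risk),
                   events=np.array(d_counts), survival=np.array(surv))


@dataclass
class LogRankResult:
    """Mantel-Cox chi-square on 1 degree of freedom."""

    chi2: float
    p: float
    observed: float   # total observed events in group A
    expected: float   # total expected events in group A

    def summary(self) -> str:
        return (f"log-rank (Mantel-Cox): chi2 = {self.chi2:.4f}, "
                f"p = {self.p:.4g} (O_A = {self.observed:.0f}, "
                f"E_A = {self.expected:.2f})")


def logrank(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-group log-rank test over the pooled distinct event times."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if ea.sum() + eb.sum() == 0:
        raise AnalysisError("no events in either group")

    pooled_t = np.r_[ta, tb]
    pooled_e = np.r_[ea, eb]
    event_times = np.unique(pooled_t[pooled_e == 1])

    o_minus_e = 0.0
    var = 0.0
    obs_a = 0.0
    exp_a = 0.0
    for t in event_times:
        n1 = int((ta >= t).sum())
        n2 = int((tb >= t).sum())
        n = n1 + n2
        d1 = int(((ta == t) & (ea == 1)).sum())
        d2 = int(((tb == t) & (eb == 1)).sum())
        d = d1 + d2
        if n1 == 0 or n2 == 0 or d == 0:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        obs_a += d1
        exp_a += e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = (o_minus_e ** 2 / var) if var > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1))
    return LogRankResult(chi2=float(chi2), p=p,
                         observed=obs_a, expected=exp_a)


def logrank_tables(group_a: pd.DataFrame, group_b: pd.DataFrame
                   ) -> LogRankResult:
    """Log-rank on two survival tables with ``time`` and ``event`` columns."""
    return logrank(group_a["time"], group_a["event"],
                   group_b["time"], group_b["event"])


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-based p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise AnalysisError("need equal-length vectors of size >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise AnalysisError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
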