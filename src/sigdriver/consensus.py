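"""Virtual-dataset resampling and consensus signature calling.

To guard gene signatures against the instability of small cohorts, the
integrated cohort is resampled into k virtual case/control datasets, each is
scored independently with the permutation d-statistic, and a gene is declared
a *robust* signature when it is called significant with a consistent direction
in at least m of the k datasets.

Three planning modes are provided. ``random`` draws each plan's control and
case sets without replacement from the whole cohort, with sizes drawn
uniformly from the observed per-study range of the reference design
(5-11 controls, 7-16 cases). ``per_study`` makes one plan per batch holding
all of that batch's samples. ``mixed`` (the default, mirroring an
8-dataset design) combines k - n_batches random plans with the per-study ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import ExpressionCohort
from .exceptions import AnalysisError, PlanningError
from .sam import SamModel, SamResults

DEFAULT_CONTROL_RANGE = (5, 11)
DEFAULT_CASE_RANGE = (7, 16)


@dataclass
class VirtualDatasetPlan:
    """Ordered list of (control ids, case ids) plans plus provenance."""

    plans: list[tuple[list[str], list[str]]]
    mode: str
    seed: int

    def __len__(self) -> int:
        return len(self.plans)


def make_virtual_datasets(samples: pd.DataFrame, k: int, mode: str = "mixed",
                          sizes: list[tuple[int, int]] | None = None,
                          seed: int = 0,
                          control_range: tuple[int, int] = DEFAULT_CONTROL_RANGE,
                          case_range: tuple[int, int] = DEFAULT_CASE_RANGE
                          ) -> VirtualDatasetPlan:
    """Plan k virtual case/control datasets from a cohort's annotation.

    ``samples`` is the cohort annotation (index sample id, columns ``study``
    and ``group``). In random mode each plan draws without replacement within
    itself; distinct plans may overlap. ``sizes`` optionally fixes each random
    plan's (n_control, n_case). Infeasible requests raise
    :class:`PlanningError`.
    """
    rng = np.random.default_rng(seed)
    controls = samples.index[samples["group"] == "control"].to_list()
    cases = samples.index[samples["group"] == "case"].to_list()
    if not controls or not cases:
        raise PlanningError("cohort must contain both controls and cases")

    def random_plan(n_c: int, n_t: int) -> tuple[list[str], list[str]]:
        if n_c < 1 or n_t < 1:
            raise PlanningError("plan sizes must be >= 1")
        if n_c > len(controls) or n_t > len(cases):
            raise PlanningError(
                f"plan of ({n_c} controls, {n_t} cases) exceeds available "
                f"({len(controls)}, {len(cases)})")
        return (sorted(rng.choice(controls, size=n_c, replace=False)),
                sorted(rng.choice(cases, size=n_t, replace=False)))

    def study_plans() -> list[tuple[list[str], list[str]]]:
        plans = []
        for study in sorted(samples["study"].unique()):
            in_study = samples["study"] == study
            plans.append((
                sorted(samples.index[in_study & (samples["group"] == "control")]),
                sorted(samples.index[in_study & (samples["group"] == "case")])))
        return plans

    if mode == "per_study":
        plans = study_plans()
    elif mode in ("random", "mixed"):
        n_random = k - (len(samples["study"].unique()) if mode == "mixed" else 0)
        if n_random < 0:
            raise PlanningError(f"k={k} smaller than the number of studies")
        plans = []
        for i in range(n_random):
            if sizes is not None:
                n_c, n_t = sizes[i]
            else:
                n_c = int(rng.integers(control_range[0],
                                       min(control_range[1], len(controls)) + 1))
                n_t = int(rng.integers(case_range[0],
                                       min(case_range[1], len(cases)) + 1))
            plans.append(random_plan(n_c, n_t))
        if mode == "mixed":
            plans += study_plans()
    else:
        raise PlanningError(f"unknown mode: {mode!r}")

    if mode != "per_study" and len(plans) != k:
        raise PlanningError(f"planned {len(plans)} datasets, requested {k}")
    return VirtualDatasetPlan(plans=plans, mode=mode, seed=seed)


def consensus_signatures(results: list[SamResults], m: int) -> pd.DataFrame:
    """Aggregate per-dataset calls into consensus signatures.

    Returns one row per gene: ``support`` (datasets calling it),
    ``direction`` (shared direction, or ``mixed`` on conflict),
    ``direction_consistent`` and ``robust`` (support >= m and consistent).
    """
    if not results:
        raise AnalysisError("no per-dataset results to aggregate")
    if m > len(results):
        raise AnalysisError("support threshold m exceeds the dataset count")
    universe = results[0].table.index
    for r in results[1:]:
        if not r.table.index.equals(universe):
            raise AnalysisError("per-dataset results disagree on the gene universe")

    called = np.column_stack([r.table["called"].to_numpy() for r in results])
    up = np.column_stack([(r.table["direction"] == "up").to_numpy()
                          for r in results])
    support = called.sum(axis=1)
    n_up = (called & up).sum(axis=1)
    n_down = (called & ~up).sum(axis=1)
    consistent = (n_up == 0) | (n_down == 0)
    direction = np.where(support == 0, "none",
                         np.where(~consistent, "mixed",
                                  np.where(n_up > 0, "up", "down")))
    return pd.DataFrame({
        "support": support,
        "direction": direction,
        "direction_consistent": consistent,
        "robust": (support >= m) & consistent,
    }, index=pd.Index(universe, name="gene"))


def run_consensus(cohort: ExpressionCohort, k: int = 8, m: int = 6,
                  mode: str = "mixed", fdr: float = 0.05, fc: float = 1.2,
                  B: int = 200, seed: int = 0,
                  sizes: list[tuple[int, int]] | None = None
                  ) -> tuple[pd.DataFrame, list[SamResults], VirtualDatasetPlan]:
    """Plan, score and aggregate in one call.

    Each virtual dataset gets its own permutation seed derived from ``seed``.
    Returns (consensus table, per-dataset results, the plan).
    """
    plan = make_virtual_datasets(cohort.samples, k=k, mode=mode, sizes=sizes,
                                 seed=seed)
    results = []
    for i, (ctrl_ids, case_ids) in enumerate(plan.plans):
        sub = cohort.subset(samples=list(ctrl_ids) + list(case_ids))
        model = SamModel.from_cohort(sub)
        results.append(model.fit(fdr_target=fdr, fc_cutoff=fc, B=B,
                                 seed=(seed * 1009 + i) % (2**31 - 1)))
    table = consensus_signatures(results, m=m)
    return table, results, plan
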