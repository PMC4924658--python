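"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is a pure function of its configuration, including the seed,
so all downstream stages are testable without any external download. The
default multi-study design mirrors a three-cohort renal-carcinoma integration:
three studies with (control, case) sizes (10, 10), (5, 12) and (11, 16).

Expression model
----------------
For gene g, sample j in study s with case indicator x_j:

    y_gjs = alpha_g + beta_g * x_j + gamma_sg + delta_sg * eps_gj

with gamma_sg ~ Normal(0, batch_shift_sd^2) (additive batch offset),
delta_sg lognormal with unit mean and coefficient of variation
``batch_scale_sd`` (multiplicative batch dispersion), and
eps_gj ~ Normal(0, noise_sd^2). Differentially expressed genes carry
beta_g = +/- log2_fc, split 50/50 up/down; all other genes have beta_g = 0.
This is exactly the location/scale batch model the empirical-Bayes correction
assumes, which makes the correction testable by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import ExpressionCohort
from .exceptions import ConfigurationError


@dataclass
class SimulationConfig:
    """Parameters of the multi-study expression generator.

    Defaults give a desk-scale version of an integrated three-study
    case/control design: 2,000 genes, 5% of them differentially expressed at
    |log2 fold change| = 1.5 over residual noise of 0.5 log2 units, with
    additive batch offsets of SD 1.0 and ~20% multiplicative batch dispersion.
    """

    n_studies: int = 3
    controls_per_study: tuple[int, ...] = (10, 5, 11)
    cases_per_study: tuple[int, ...] = (10, 12, 16)
    n_genes: int = 2000
    de_fraction: float = 0.05
    log2_fc: float = 1.5
    batch_shift_sd: float = 1.0
    batch_scale_sd: float = 0.2
    noise_sd: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_studies < 1 or self.n_genes < 1:
            raise ConfigurationError("n_studies and n_genes must be >= 1")
        if len(self.controls_per_study) != self.n_studies \
                or len(self.cases_per_study) != self.n_studies:
            raise ConfigurationError("per-study sample counts must match n_studies")
        if min(self.controls_per_study) < 1 or min(self.cases_per_study) < 1:
            raise ConfigurationError("every study needs >= 1 control and >= 1 case")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigurationError("de_fraction must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.batch_shift_sd < 0 or self.batch_scale_sd < 0:
            raise ConfigurationError("batch effect scales must be non-negative")


@dataclass
class GroundTruth:
    """Planted structure of a simulated scenario.

    ``de_genes`` maps gene id -> direction (+1 up in cases, -1 down);
    ``hub_seeds`` lists the planted high-degree network nodes;
    ``survival_hazard_ratio`` is the planted high/low-group hazard ratio.
    """

    de_genes: dict[str, int] = field(default_factory=dict)
    hub_seeds: list[str] = field(default_factory=list)
    survival_hazard_ratio: float = 1.0

    @property
    def up_genes(self) -> list[str]:
        return [g for g, d in self.de_genes.items() if d > 0]

    @property
    def down_genes(self) -> list[str]:
        return [g for g, d in self.de_genes.items() if d < 0]


def _unit_mean_lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Lognormal draws with mean 1 and coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    s2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-s2 / 2.0, sigma=math.sqrt(s2), size=size)


def simulate_multistudy_expression(config: SimulationConfig
                                   ) -> tuple[ExpressionCohort, GroundTruth]:
    """Generate an integrated multi-study cohort with planted DE genes.

    Returns the concatenated cohort (batch label = study of origin) and the
    ground truth listing planted DE genes with their directions.
    """
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    genes = [f"G{i:05d}" for i in range(n_genes)]

    n_de = int(round(config.de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    directions = np.ones(n_de, dtype=int)
    directions[n_de // 2:] = -1  # 50/50 up/down split
    beta = np.zeros(n_genes)
    beta[de_idx] = directions * config.log2_fc

    alpha = rng.normal(config.baseline_mean, config.baseline_sd, n_genes)

    blocks, sample_ids, studies, groups = [], [], [], []
    for s in range(config.n_studies):
        n_c, n_t = config.controls_per_study[s], config.cases_per_study[s]
        n_s = n_c + n_t
        x = np.r_[np.zeros(n_c), np.ones(n_t)]
        gamma = rng.normal(0.0, config.batch_shift_sd, n_genes)
        delta = _unit_mean_lognormal(rng, config.batch_scale_sd, n_genes)
        eps = rng.normal(0.0, config.noise_sd, (n_genes, n_s))
        block = (alpha[:, None] + np.outer(beta, x) + gamma[:, None]
                 + delta[:, None] * eps)
        blocks.append(block)
        sample_ids += [f"S{s + 1}_C{i + 1}" for i in range(n_c)]
        sample_ids += [f"S{s + 1}_T{i + 1}" for i in range(n_t)]
        studies += [f"study{s + 1}"] * n_s
        groups += ["control"] * n_c + ["case"] * n_t

    values = pd.DataFrame(np.hstack(blocks), index=genes, columns=sample_ids)
    samples = pd.DataFrame({"study": studies, "group": groups},
                           index=pd.Index(sample_ids, name="sample_id"))
    truth = GroundTruth(de_genes={genes[i]: int(d)
                                  for i, d in zip(de_idx, directions)})
    return ExpressionCohort(values, samples, name="simulated"), truth


def simulate_ppi(n_nodes: int, n_seed_hubs: int, attachment: int, seed: int,
                 node_ids: list[str] | None = None,
                 hub_ids: list[str] | None = None
                 ) -> tuple[pd.DataFrame, GroundTruth]:
    """Scale-free interaction edge table with planted high-degree hub nodes.

    A preferential-attachment graph is grown, then ``n_seed_hubs`` nodes are
    wired to enough extra random partners that each planted hub's degree
    reaches at least the graph's 90th degree percentile. Returns an undirected
    simple edge table (node_a, interaction, node_b) and the hub truth.

    ``node_ids`` renames the nodes (e.g. to gene ids shared with an expression
    simulation); ``hub_ids`` forces specific ids to be the planted hubs.
    """
    if n_seed_hubs >= n_nodes:
        raise ConfigurationError("n_seed_hubs must be < n_nodes")
    if attachment >= n_nodes:
        raise ConfigurationError("attachment must be < n_nodes")
    if node_ids is not None and len(node_ids) != n_nodes:
        raise ConfigurationError("node_ids length must equal n_nodes")

    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(n_nodes, attachment,
                                 seed=int(rng.integers(2**31 - 1)))
    if node_ids is None:
        node_ids = [f"P{i:05d}" for i in range(n_nodes)]
    g = nx.relabel_nodes(g, dict(enumerate(node_ids)))

    if hub_ids is not None:
        unknown = set(hub_ids) - set(node_ids)
        if unknown:
            raise ConfigurationError(f"hub_ids not among node ids: {sorted(unknown)}")
        if len(hub_ids) != n_seed_hubs:
            raise ConfigurationError("hub_ids length must equal n_seed_hubs")
        hubs = list(hub_ids)
    else:
        hubs = [node_ids[i] for i in
                rng.choice(n_nodes, size=n_seed_hubs, replace=False)]

    degrees = np.array([d for _, d in g.degree()])
    target = int(2 * np.percentile(degrees, 90)) + 5
    others = np.array(node_ids)
    for hub in hubs:
        need = target - g.degree(hub)
        if need <= 0:
            continue
        candidates = [v for v in rng.permutation(others)
                      if v != hub and not g.has_edge(hub, v)]
        for v in candidates[:need]:
            g.add_edge(hub, v)

    q90 = np.percentile([d for _, d in g.degree()], 90)
    low = [h for h in hubs if g.degree(h) < q90]
    if low:  # unreachable for sane sizes; guard the planted-hub contract
        raise ConfigurationError(f"failed to plant hubs above 90th percentile: {low}")

    edges = sorted((min(a, b), max(a, b)) for a, b in g.edges())
    table = pd.DataFrame({"node_a": [a for a, _ in edges],
                          "interaction": "pp",
                          "node_b": [b for _, b in edges]})
    return table, GroundTruth(hub_seeds=sorted(hubs))


def simulate_pathways(genes: list[str], n_sets: int,
                      set_size_range: tuple[int, int],
                      enriched_set_fraction_of_signature: float,
                      seed: int,
                      signature: list[str] | None = None
                      ) -> tuple[dict[str, list[str]], str]:
    """Random gene sets plus one designated set enriched for a signature.

    The designated set (named ``planted_pathway``) contains
    ``round(fraction * len(signature))`` signature genes, topped up with
    random non-signature genes to a size within ``set_size_range``. Returns
    the GMT-writable collection and the designated set's name.
    """
    if not genes:
        raise ConfigurationError("gene list is empty")
    lo, hi = set_size_range
    if not 1 <= lo <= hi <= len(genes):
        raise ConfigurationError("set sizes must satisfy 1 <= lo <= hi <= n_genes")
    rng = np.random.default_rng(seed)
    gene_arr = np.array(genes)
    sets: dict[str, list[str]] = {}

    if signature is None:
        signature = []
    missing = set(signature) - set(genes)
    if missing:
        raise ConfigurationError(f"signature genes not in universe: {sorted(missing)}")

    enriched_name = "planted_pathway"
    if signature:
        n_from_sig = int(round(enriched_set_fraction_of_signature * len(signature)))
        sig_part = list(rng.choice(signature, size=n_from_sig, replace=False)) \
            if n_from_sig < len(signature) else list(signature)
        size = max(int(rng.integers(lo, hi + 1)), len(sig_part))
        pool = [g for g in genes if g not in set(sig_part)]
        filler = list(rng.choice(pool, size=size - len(sig_part), replace=False))
        sets[enriched_name] = sorted(sig_part + filler)

    for i in range(n_sets - (1 if signature else 0)):
        size = int(rng.integers(lo, hi + 1))
        sets[f"SET_{i + 1:04d}"] = sorted(rng.choice(gene_arr, size=size,
                                                     replace=False))
    return sets, (enriched_name if signature else "")


def simulate_survival(n: int, hazard_ratio: float, baseline_hazard: float = 0.02,
                      censor_rate: float = 0.2, seed: int = 0) -> pd.DataFrame:
    """Exponential survival with a group-dependent hazard and marker expression.

    Half the samples form a high-expression group whose event hazard is
    ``baseline_hazard * hazard_ratio``; the other half is the low group at
    the baseline hazard. Times are in months. Censoring times are independent
    exponentials calibrated so that the expected censored fraction is
    ``censor_rate``. Columns: sample, time, event, expression, true_group.
    """
    if n < 2:
        raise ConfigurationError("n must be >= 2")
    if hazard_ratio <= 0 or baseline_hazard <= 0:
        raise ConfigurationError("hazards must be positive")
    if not 0.0 <= censor_rate < 1.0:
        raise ConfigurationError("censor_rate must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    n_high = n // 2
    high = np.r_[np.zeros(n - n_high, dtype=bool), np.ones(n_high, dtype=bool)]
    hazard = np.where(high, baseline_hazard * hazard_ratio, baseline_hazard)
    event_time = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        # for T~Exp(l), C~Exp(m): P(censored) = m/(l+m)  =>  m = r/(1-r) * l
        censor_time = rng.exponential((1 - censor_rate)
                                      / (censor_rate * hazard))
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    else:
        time, event = event_time, np.ones(n, dtype=int)
    expression = np.where(high, rng.normal(7.0, 0.5, n), rng.normal(5.0, 0.5, n))
    return pd.DataFrame({
        "sample": [f"PT{i + 1:04d}" for i in range(n)],
        "time": np.maximum(time, 1e-6),
        "event": event,
        "expression": expression,
        "true_group": np.where(high, "high", "low"),
    })


def simulate_paired_proteomics(n_proteins: int, n_pairs: int,
                               shifted_proteins: int, shift: float,
                               noise_sd: float, seed: int,
                               protein_ids: list[str] | None = None,
                               shifted_ids: list[str] | None = None
                               ) -> tuple[pd.DataFrame, GroundTruth]:
    """Paired control/treated log2 abundance table with planted shifts.

    ``shifted_proteins`` proteins receive a treated-vs-control log2 shift of
    magnitude ``shift`` (direction split 50/50, +1 meaning up in treated).
    Columns: protein, control_1..k, treated_1..k. The truth maps protein id
    to its planted direction. ``shifted_ids`` forces specific proteins to be
    the shifted ones (e.g. to align the proteomics truth with planted network
    hubs).
    """
    if n_pairs < 2:
        raise ConfigurationError("n_pairs must be >= 2 (paired t undefined below)")
    if shifted_proteins > n_proteins:
        raise ConfigurationError("shifted_proteins must be <= n_proteins")
    if noise_sd <= 0:
        raise ConfigurationError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    if protein_ids is None:
        protein_ids = [f"PROT{i:05d}" for i in range(n_proteins)]
    elif len(protein_ids) != n_proteins:
        raise ConfigurationError("protein_ids length must equal n_proteins")

    base = rng.normal(25.0, 2.0, n_proteins)
    if shifted_ids is not None:
        if len(shifted_ids) != shifted_proteins:
            raise ConfigurationError("shifted_ids length must equal "
                                     "shifted_proteins")
        lookup = {p: i for i, p in enumerate(protein_ids)}
        unknown = [p for p in shifted_ids if p not in lookup]
        if unknown:
            raise ConfigurationError(f"shifted_ids not among proteins: "
                                     f"{unknown[:5]}")
        idx = np.array([lookup[p] for p in shifted_ids], dtype=int)
    else:
        idx = rng.choice(n_proteins, size=shifted_proteins, replace=False)
    directions = np.ones(shifted_proteins, dtype=int)
    directions[shifted_proteins // 2:] = -1
    effect = np.zeros(n_proteins)
    effect[idx] = directions * shift

    data = {"protein": protein_ids}
    for j in range(n_pairs):
        data[f"control_{j + 1}"] = base + rng.normal(0, noise_sd, n_proteins)
        data[f"treated_{j + 1}"] = base + effect + rng.normal(0, noise_sd, n_proteins)
    truth = GroundTruth(de_genes={protein_ids[i]: int(d)
                                  for i, d in zip(idx, directions)})
    return pd.DataFrame(data), truth
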