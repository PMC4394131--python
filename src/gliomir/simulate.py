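"""Synthetic inputs with planted ground truth for the whole pipeline.

The generator emulates the statistical structure of the study inputs:

* two prognosis cohorts on different platforms — a grade-III cohort
  profiled by small-RNA sequencing (negative-binomial counts, varying
  library sizes) and a GBM cohort on a log2-intensity microarray — with
  a planted set of prognostic microRNAs whose expression shifts by a
  concordant log2 fold change in the poor-prognosis group of *both*
  grades;
* replicate microRNA profiles for the eight oligodendrocyte-precursor
  differentiation stages (ESC, EB, NP, GP, OP1, OP2, OP3, OL) built
  from a common baseline plus stage-specific marker "bumps", so that
  consecutive-stage fold changes are non-trivial.  OP2 and OP3 are a
  designed expression plateau, so the per-transition filter finds too
  few changing microRNAs there and the transition is omitted — the
  degenerate case the analysis must handle;
* tumors as noisy convex mixtures of the stage mean profiles over the
  platform-shared microRNAs, with exponential survival whose log-hazard
  is ``hazard_beta`` times the tumor's realized OP1 similarity score;
* matched mRNA cohorts with a planted differentially expressed gene
  pool, three target-prediction tables with controlled overlap, and
  control-lineage fold-change vectors independent of everything else.

All randomness flows from a single seed through named
:class:`numpy.random.SeedSequence` streams, so each generator is
bit-reproducible and independent of the order in which the others run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .data import (
    COUNTS,
    GRADE_GBM,
    GRADE_GIIIA,
    GROUP_GOOD,
    GROUP_POOR,
    INTENSITY,
    ExpressionMatrix,
    InvalidConfigError,
    validate_annotation,
)
from .lineage import STAGE_ORDER, StageProfileSet, tumor_stage_correlations
from .targets import TargetTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohorts",
    "simulate_stage_profiles",
    "simulate_tumor_profiles",
    "simulate_mrna_cohorts",
    "simulate_target_databases",
    "simulate_control_contrasts",
    "simulate_all",
    "write_simulation",
]

# Named sub-streams split off the master seed (documented stream-splitting:
# stream k is SeedSequence(seed, spawn_key=(k,))).
_STREAMS = {
    "design": 0,
    "cohort": 1,
    "stage": 2,
    "tumor": 3,
    "mrna": 4,
    "targets": 5,
    "control": 6,
}

#: Marker blocks: stages at which the block peaks.  OP2/OP3 share one
#: plateau block so that transition carries almost no signal.
_BLOCKS = (
    ("ESC", (0,)),
    ("EB", (1,)),
    ("NP", (2,)),
    ("GP", (3,)),
    ("OP1", (4,)),
    ("OP23", (5, 6)),
    ("OL", (7,)),
)
_ADJACENT_LEVEL = 0.25


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with the cohort geometry of the
    emulated datasets as defaults.

    ``group_sizes`` is (GIIIA good, GIIIA poor, GBM good, GBM poor).
    ``effect_logfc`` is the planted log2 shift in poor-prognosis samples
    of both grades; ``hazard_beta`` the log-hazard per unit OP1
    similarity.  SDs are on the log2 scale.
    """

    seed: int = 0
    # cohort geometry
    n_mirna: int = 534
    n_shared_platform: int = 150
    group_sizes: tuple = (6, 10, 13, 14)
    n_prognostic: int = 50
    effect_logfc: float = 1.5
    # platform noise
    nb_dispersion: float = 0.2
    intensity_sd: float = 0.4
    # stage profiles
    n_stage_reps: int = 3
    stage_rep_sd: float = 0.25
    markers_per_block: int = 20
    trajectory_amplitude: float = 2.5
    n_monotone: int = 40
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 0.7
    # sequencing depth model
    seq_mean_count: float = 200.0
    seq_mean_log2_sd: float = 1.5
    # tumors + survival
    n_tumors: int = 597
    mixture_alpha: float = 0.2
    tumor_distortion_max: float = 0.9
    hazard_beta: float = 2.0
    baseline_hazard: float = 0.05
    censor_rate: float = 0.3
    # mRNA cohorts
    n_mrna: int = 4000
    n_de_mrna: int = 400
    mrna_effect_logfc: float = 1.5
    # target databases
    n_target_pairs: int = 3000
    target_overlap: float = 0.4
    # control lineages
    n_control_features: int = 139
    control_fc_sd: float = 1.2

    def __post_init__(self) -> None:
        counts = {
            "n_mirna": self.n_mirna,
            "n_shared_platform": self.n_shared_platform,
            "n_tumors": self.n_tumors,
            "n_mrna": self.n_mrna,
            "n_target_pairs": self.n_target_pairs,
        }
        for name, v in counts.items():
            if v <= 0:
                raise InvalidConfigError(f"{name} must be positive, got {v}")
        if len(self.group_sizes) != 4 or any(g < 2 for g in self.group_sizes):
            raise InvalidConfigError("group_sizes must be four counts >= 2")
        if self.n_shared_platform > self.n_mirna:
            raise InvalidConfigError("n_shared_platform must be <= n_mirna")
        if not (0 <= self.n_prognostic <= self.n_mirna):
            raise InvalidConfigError("n_prognostic must be in [0, n_mirna]")
        if self.nb_dispersion <= 0:
            raise InvalidConfigError("nb_dispersion must be positive")
        if self.intensity_sd < 0:
            raise InvalidConfigError("intensity_sd must be non-negative")
        if self.stage_rep_sd < 0:
            raise InvalidConfigError("stage_rep_sd must be non-negative")
        if self.n_stage_reps < 2:
            raise InvalidConfigError("n_stage_reps must be >= 2 (significance filter needs replicates)")
        if len(_BLOCKS) * self.markers_per_block > self.n_shared_platform:
            raise InvalidConfigError(
                "markers_per_block too large for n_shared_platform "
                f"({len(_BLOCKS)} blocks x {self.markers_per_block} > {self.n_shared_platform})"
            )
        if not (0.0 <= self.censor_rate < 1.0):
            raise InvalidConfigError("censor_rate must be in [0, 1)")
        if not (0.0 <= self.target_overlap <= 1.0):
            raise InvalidConfigError("target_overlap must be in [0, 1]")
        if self.baseline_hazard <= 0:
            raise InvalidConfigError("baseline_hazard must be positive")

    # -- YAML / JSON round-trip -------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["group_sizes"] = list(self.group_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "group_sizes" in d:
            d["group_sizes"] = tuple(d["group_sizes"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class GroundTruth:
    """Planted truth for recovery tests.  Fields are filled by whichever
    generator produced the object; unused ones stay None."""

    prognostic_mirna_ids: list | None = None
    true_logfc_per_grade: pd.DataFrame | None = None
    de_gene_ids: list | None = None
    stage_mixture_weights: pd.DataFrame | None = None
    op1_similarity: pd.Series | None = None
    true_hazard_beta: float | None = None

    def to_json_dict(self) -> dict:
        d: dict = {}
        if self.prognostic_mirna_ids is not None:
            d["prognostic_mirna_ids"] = list(self.prognostic_mirna_ids)
        if self.true_logfc_per_grade is not None:
            d["true_logfc_per_grade"] = {
                k: dict(v) for k, v in self.true_logfc_per_grade.to_dict().items()
            }
        if self.de_gene_ids is not None:
            d["de_gene_ids"] = list(self.de_gene_ids)
        if self.stage_mixture_weights is not None:
            d["stage_mixture_weights"] = {
                k: dict(v) for k, v in self.stage_mixture_weights.to_dict().items()
            }
        if self.op1_similarity is not None:
            d["op1_similarity"] = dict(self.op1_similarity)
        if self.true_hazard_beta is not None:
            d["true_hazard_beta"] = float(self.true_hazard_beta)
        return d


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(_STREAMS[stream],)))


# ---------------------------------------------------------------------------
# Deterministic study design (shared by all generators)


@dataclass
class _Design:
    feature_ids: pd.Index
    shared_ids: pd.Index
    baseline_log2: pd.Series
    seq_mean: pd.Series
    bump: pd.DataFrame           # features x stages, amplitude-scaled
    block_members: dict
    monotone_ids: pd.Index
    prognostic_signs: pd.Series  # +1 = up in poor prognosis


def _design(config: SimulationConfig) -> _Design:
    rng = _rng(config, "design")
    ids = pd.Index([f"mir-{i + 1:04d}" for i in range(config.n_mirna)], name="feature_id")
    shared_pos = np.sort(rng.choice(config.n_mirna, config.n_shared_platform, replace=False))
    shared = ids[shared_pos]

    baseline = pd.Series(
        rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_mirna),
        index=ids,
    )
    seq_mean = pd.Series(
        config.seq_mean_count
        * np.exp2(rng.normal(0.0, config.seq_mean_log2_sd, config.n_mirna)),
        index=ids,
    )

    # marker blocks live inside the shared feature set
    shuffled_shared = shared[rng.permutation(len(shared))]
    bump = pd.DataFrame(0.0, index=ids, columns=list(STAGE_ORDER))
    block_members: dict = {}
    pos = 0
    for block_name, peaks in _BLOCKS:
        members = shuffled_shared[pos : pos + config.markers_per_block]
        pos += config.markers_per_block
        block_members[block_name] = pd.Index(members)
        profile = np.zeros(len(STAGE_ORDER))
        for peak in peaks:
            profile[peak] = 1.0
        for peak in peaks:
            for adj in (peak - 1, peak + 1):
                if 0 <= adj < len(STAGE_ORDER) and profile[adj] == 0.0:
                    profile[adj] = _ADJACENT_LEVEL
        bump.loc[members, :] = np.tile(profile, (len(members), 1))

    # smooth monotone trajectories on non-shared features (background slopes)
    non_shared = ids.difference(shared)
    n_mono = min(config.n_monotone, len(non_shared))
    monotone = pd.Index(rng.choice(non_shared, n_mono, replace=False))
    ramp = np.linspace(0.0, 1.0, len(STAGE_ORDER))
    signs = rng.choice([-1.0, 1.0], n_mono)
    bump.loc[monotone, :] = np.outer(signs, ramp)
    bump *= config.trajectory_amplitude

    # planted prognostic microRNAs: the OP1 marker block first (up in poor),
    # the remainder drawn from plain features with random signs
    op1 = block_members["OP1"]
    take_op1 = op1[: min(len(op1), config.n_prognostic)]
    prog = {m: 1.0 for m in take_op1}
    n_extra = config.n_prognostic - len(take_op1)
    if n_extra > 0:
        in_block = pd.Index([]).append([block_members[b] for b, _ in _BLOCKS])
        plain = ids.difference(in_block).difference(monotone)
        extra = rng.choice(plain, n_extra, replace=False)
        for m, s in zip(extra, rng.choice([-1.0, 1.0], n_extra)):
            prog[m] = s
    prognostic = pd.Series(prog, dtype=float)
    return _Design(
        feature_ids=ids,
        shared_ids=shared,
        baseline_log2=baseline,
        seq_mean=seq_mean,
        bump=bump,
        block_members=block_members,
        monotone_ids=monotone,
        prognostic_signs=prognostic,
    )


def shared_feature_ids(config: SimulationConfig) -> pd.Index:
    """The microRNAs detected on every platform (sequencing, cohort array
    and stage-profile array) under this configuration."""
    return _design(config).shared_ids


# ---------------------------------------------------------------------------
# Cohorts (miRNA and mRNA share the machinery)


def _make_annotation(rng: np.random.Generator, group_sizes) -> pd.DataFrame:
    n3g, n3p, n4g, n4p = group_sizes
    rows = []
    for i in range(n3g):
        rows.append((f"GIIIA-G{i + 1:02d}", GRADE_GIIIA, GROUP_GOOD,
                     float(rng.uniform(49.0, 120.0)), False, "mut"))
    for i in range(n3p):
        idh = "mut" if i == 0 else "wt"
        rows.append((f"GIIIA-P{i + 1:02d}", GRADE_GIIIA, GROUP_POOR,
                     float(rng.uniform(2.0, 9.5)), True, idh))
    for i in range(n4g):
        rows.append((f"GBM-G{i + 1:02d}", GRADE_GBM, GROUP_GOOD,
                     float(rng.uniform(49.0, 120.0)), False, "wt"))
    for i in range(n4p):
        rows.append((f"GBM-P{i + 1:02d}", GRADE_GBM, GROUP_POOR,
                     float(rng.uniform(0.5, 3.9)), True, "wt"))
    ann = pd.DataFrame(
        rows,
        columns=["sample_id", "grade", "group", "survival_months", "event", "idh_status"],
    ).set_index("sample_id")
    return validate_annotation(ann)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def _library_sizes(rng: np.random.Generator, n: int, depth: float = 1e6) -> np.ndarray:
    """Library sizes spanning a >= 2-fold (up to 4-fold) range by stratified
    placement on the log2 scale."""
    spread = np.linspace(-1.0, 1.0, n) + rng.uniform(-0.05, 0.05, n)
    return depth * np.exp2(rng.permutation(spread))


def _two_platform_cohorts(
    rng: np.random.Generator,
    annotation: pd.DataFrame,
    baseline_log2: pd.Series,
    seq_mean: pd.Series,
    planted_signs: pd.Series,
    effect_logfc: float,
    nb_dispersion: float,
    intensity_sd: float,
):
    ids = baseline_log2.index
    delta = pd.DataFrame(0.0, index=ids, columns=annotation.index)
    poor = annotation.index[annotation["group"] == GROUP_POOR]
    for feat, sign in planted_signs.items():
        delta.loc[feat, poor] = sign * effect_logfc

    seq_samples = annotation.index[annotation["grade"] == GRADE_GIIIA]
    libs = _library_sizes(rng, len(seq_samples))
    mu = seq_mean.to_numpy()[:, None] * np.exp2(delta[seq_samples].to_numpy())
    frac = mu / mu.sum(axis=0, keepdims=True)
    counts = _nb_counts(rng, frac * libs[None, :], nb_dispersion)
    seq = ExpressionMatrix(
        pd.DataFrame(counts, index=ids, columns=seq_samples), COUNTS
    )

    arr_samples = annotation.index[annotation["grade"] == GRADE_GBM]
    vals = (
        baseline_log2.to_numpy()[:, None]
        + delta[arr_samples].to_numpy()
        + rng.normal(0.0, intensity_sd, (len(ids), len(arr_samples)))
    )
    array = ExpressionMatrix(
        pd.DataFrame(vals, index=ids, columns=arr_samples), INTENSITY
    )
    return seq, array


def simulate_cohorts(config: SimulationConfig):
    """Sequencing (GIIIA) and microarray (GBM) prognosis cohorts.

    Returns ``(seq_matrix, array_matrix, annotation, ground_truth)``.
    Planted microRNAs shift their mean by ``effect_logfc`` (log2, with a
    concordant per-feature sign) in the poor-prognosis samples of both
    grades.
    """
    if config.intensity_sd <= 0:
        raise InvalidConfigError("simulate_cohorts requires intensity_sd > 0")
    design = _design(config)
    rng = _rng(config, "cohort")
    annotation = _make_annotation(rng, config.group_sizes)
    seq, array = _two_platform_cohorts(
        rng,
        annotation,
        design.baseline_log2,
        design.seq_mean,
        design.prognostic_signs,
        config.effect_logfc,
        config.nb_dispersion,
        config.intensity_sd,
    )
    lfc = config.effect_logfc * design.prognostic_signs
    truth = GroundTruth(
        prognostic_mirna_ids=list(design.prognostic_signs.index),
        true_logfc_per_grade=pd.DataFrame({"logfc_III": lfc, "logfc_IV": lfc}),
    )
    return seq, array, annotation, truth


def simulate_mrna_cohorts(config: SimulationConfig, annotation: pd.DataFrame | None = None):
    """Matched mRNA cohorts (same patients) with a planted DE gene pool.

    Returns ``(seq_matrix, array_matrix, annotation, ground_truth)`` with
    ``ground_truth.de_gene_ids`` naming the planted genes.
    """
    if config.intensity_sd <= 0:
        raise InvalidConfigError("simulate_mrna_cohorts requires intensity_sd > 0")
    rng = _rng(config, "mrna")
    if annotation is None:
        annotation = _make_annotation(_rng(config, "cohort"), config.group_sizes)
    ids = pd.Index([f"gene-{i + 1:05d}" for i in range(config.n_mrna)], name="feature_id")
    baseline = pd.Series(rng.normal(8.0, 1.0, config.n_mrna), index=ids)
    seq_mean = pd.Series(50.0 * np.exp2(rng.normal(0.0, 1.5, config.n_mrna)), index=ids)
    de_genes = ids[np.sort(rng.choice(config.n_mrna, config.n_de_mrna, replace=False))]
    signs = pd.Series(rng.choice([-1.0, 1.0], config.n_de_mrna), index=de_genes)
    seq, array = _two_platform_cohorts(
        rng, annotation, baseline, seq_mean, signs,
        config.mrna_effect_logfc, config.nb_dispersion, config.intensity_sd,
    )
    return seq, array, annotation, GroundTruth(de_gene_ids=list(de_genes))


# ---------------------------------------------------------------------------
# Stage profiles and tumors


def simulate_stage_profiles(config: SimulationConfig) -> StageProfileSet:
    """Replicate log2 profiles for the 8 differentiation stages.

    Stage means are a per-feature baseline plus amplitude-scaled marker
    bumps (stage-peaked blocks, an OP2/OP3 plateau, monotone ramps);
    replicates add Gaussian noise with SD ``stage_rep_sd`` (0 allowed:
    replicates become identical and transition p-values degenerate).
    """
    design = _design(config)
    rng = _rng(config, "stage")
    means = design.bump.add(design.baseline_log2, axis=0)
    reps = {}
    for stage in STAGE_ORDER:
        noise = rng.normal(0.0, config.stage_rep_sd, (len(design.feature_ids), config.n_stage_reps)) \
            if config.stage_rep_sd > 0 else np.zeros((len(design.feature_ids), config.n_stage_reps))
        reps[stage] = pd.DataFrame(
            means[stage].to_numpy()[:, None] + noise,
            index=design.feature_ids,
            columns=[f"{stage}.{k + 1}" for k in range(config.n_stage_reps)],
        )
    return StageProfileSet(replicates=reps)


def simulate_tumor_profiles(
    config: SimulationConfig,
    stages: StageProfileSet,
    weights: pd.DataFrame | None = None,
):
    """Tumor profiles as noisy stage mixtures plus tied survival.

    Each tumor, restricted to the platform-shared microRNAs, is a convex
    mixture of the stage mean profiles, blended with a rank-scrambled
    copy of itself (per-tumor distortion, emulating variable tumor
    purity/quality) plus Gaussian noise.  Survival is exponential with
    log-hazard ``hazard_beta`` times the tumor's realized OP1 similarity
    (Spearman rho against the OP1 mean profile); a ``censor_rate``
    fraction is administratively censored.

    Returns ``(tumor_matrix, survival, ground_truth)``.
    """
    design = _design(config)
    rng = _rng(config, "tumor")
    shared = design.shared_ids
    means = stages.mean_profile.loc[shared]
    n = config.n_tumors
    if weights is None:
        w = rng.dirichlet(np.full(len(STAGE_ORDER), config.mixture_alpha), size=n)
        weights = pd.DataFrame(
            w, index=[f"T{i + 1:04d}" for i in range(n)], columns=list(STAGE_ORDER)
        )
    else:
        weights = weights[list(STAGE_ORDER)]
        n = len(weights)
    mix = means.to_numpy() @ weights.to_numpy().T  # features x tumors
    if config.tumor_distortion_max > 0:
        # bimodal tumor quality: most tumors are either strongly stage-like
        # or strongly scrambled, giving the similarity score a wide spread
        d = rng.beta(0.4, 0.4, n) * config.tumor_distortion_max
        scrambled = np.empty_like(mix)
        for j in range(n):
            scrambled[:, j] = rng.permutation(mix[:, j])
        mix = (1.0 - d[None, :]) * mix + d[None, :] * scrambled
    if config.intensity_sd > 0:
        mix = mix + rng.normal(0.0, config.intensity_sd, mix.shape)
    tumors = ExpressionMatrix(
        pd.DataFrame(mix, index=shared, columns=weights.index), INTENSITY
    )
    rho = tumor_stage_correlations(tumors, stages, shared).rho["OP1"]
    lp = config.hazard_beta * (rho - rho.mean())
    lam = config.baseline_hazard * np.exp(lp.to_numpy())
    times = rng.exponential(1.0 / lam)
    event = np.ones(n, dtype=bool)
    if config.censor_rate > 0:
        # independent uniform administrative censoring on (0, H], with the
        # horizon H chosen so a censor_rate fraction is censored on average
        # at the baseline hazard: solves (1 - exp(-r)) / r = censor_rate
        r = brentq(
            lambda x: (1.0 - np.exp(-x)) / x - config.censor_rate, 1e-9, 1e4
        )
        horizon = r / config.baseline_hazard
        cens = rng.uniform(0.0, horizon, n)
        event = times <= cens
        times = np.minimum(times, cens)
    survival = pd.DataFrame({"time": times, "event": event}, index=weights.index)
    truth = GroundTruth(
        stage_mixture_weights=weights,
        op1_similarity=rho,
        true_hazard_beta=config.hazard_beta,
    )
    return tumors, survival, truth


# ---------------------------------------------------------------------------
# Target databases and control lineages

_DB_NAMES = ("miranda", "pictar", "targetscan")


def simulate_target_databases(
    config: SimulationConfig,
    de_gene_pool,
    mirna_ids=None,
):
    """Three target-prediction tables with controlled pairwise overlap.

    A ``target_overlap`` fraction of the generated (microRNA, gene) pairs
    is written into >= 2 of the three tables; the rest appear in exactly
    one, so they cannot survive the agreement rule.
    """
    genes = list(de_gene_pool)
    if not genes:
        raise InvalidConfigError("de_gene_pool must be non-empty")
    if mirna_ids is None:
        mirna_ids = _design(config).feature_ids
    mirnas = list(mirna_ids)
    rng = _rng(config, "targets")
    total = len(mirnas) * len(genes)
    n_pairs = min(config.n_target_pairs, total)
    flat = rng.choice(total, n_pairs, replace=False)
    pairs = [(mirnas[k // len(genes)], genes[k % len(genes)]) for k in flat]
    members: dict = {name: [] for name in _DB_NAMES}
    for pair in pairs:
        if rng.uniform() < config.target_overlap:
            k = 2 if rng.uniform() < 0.5 else 3
            dbs = rng.choice(len(_DB_NAMES), k, replace=False)
        else:
            dbs = [rng.integers(len(_DB_NAMES))]
        for db in dbs:
            members[_DB_NAMES[int(db)]].append(pair)
    return tuple(TargetTable.from_pairs(name, members[name]) for name in _DB_NAMES)


_CONTROL_LABELS = ("ESC_to_HP", "NSC_to_NP")


def simulate_control_contrasts(config: SimulationConfig) -> dict:
    """Control-lineage fold-change vectors (non-oligodendrocyte
    differentiation), independent of every planted effect."""
    design = _design(config)
    rng = _rng(config, "control")
    out = {}
    n = min(config.n_control_features, config.n_mirna)
    for label in _CONTROL_LABELS:
        feats = pd.Index(rng.choice(design.feature_ids, n, replace=False))
        out[label] = pd.Series(rng.normal(0.0, config.control_fc_sd, n), index=feats, name=label)
    return out


# ---------------------------------------------------------------------------
# Bundles and disk I/O


def simulate_all(config: SimulationConfig) -> dict:
    """Generate every pipeline input; returns a dict bundle."""
    seq, array, annotation, mirna_truth = simulate_cohorts(config)
    mrna_seq, mrna_array, _, mrna_truth = simulate_mrna_cohorts(config, annotation)
    stages = simulate_stage_profiles(config)
    tumors, survival, tumor_truth = simulate_tumor_profiles(config, stages)
    tables = simulate_target_databases(config, mrna_truth.de_gene_ids)
    controls = simulate_control_contrasts(config)
    truth = GroundTruth(
        prognostic_mirna_ids=mirna_truth.prognostic_mirna_ids,
        true_logfc_per_grade=mirna_truth.true_logfc_per_grade,
        de_gene_ids=mrna_truth.de_gene_ids,
        stage_mixture_weights=tumor_truth.stage_mixture_weights,
        op1_similarity=tumor_truth.op1_similarity,
        true_hazard_beta=tumor_truth.true_hazard_beta,
    )
    return {
        "config": config,
        "mirna_seq": seq,
        "mirna_array": array,
        "annotation": annotation,
        "mrna_seq": mrna_seq,
        "mrna_array": mrna_array,
        "stages": stages,
        "tumors": tumors,
        "tumor_survival": survival,
        "target_tables": tables,
        "controls": controls,
        "truth": truth,
    }


def write_simulation(bundle: dict, outdir) -> None:
    """Write a simulated bundle as TSV inputs plus a ground-truth JSON
    sidecar and the generating config (YAML)."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["config"].write(out / "sim_config.yaml")
    bundle["mirna_seq"].write_tsv(out / "mirna_counts_GIIIA.tsv")
    bundle["mirna_array"].write_tsv(out / "mirna_intensity_GBM.tsv")
    bundle["mrna_seq"].write_tsv(out / "mrna_counts_GIIIA.tsv")
    bundle["mrna_array"].write_tsv(out / "mrna_intensity_GBM.tsv")
    ann = bundle["annotation"].copy()
    ann.index.name = "sample_id"
    ann.to_csv(out / "annotation.tsv", sep="\t")
    bundle["stages"].write_tsv(out / "stage_profiles.tsv")
    bundle["tumors"].write_tsv(out / "tumor_intensity.tsv")
    surv = bundle["tumor_survival"].copy()
    surv.index.name = "sample_id"
    surv.to_csv(out / "tumor_survival.tsv", sep="\t")
    for table in bundle["target_tables"]:
        table.write_tsv(out / f"targets_{table.db_name}.tsv")
    for label, fc in bundle["controls"].items():
        df = fc.rename("logfc").to_frame()
        df.index.name = "feature_id"
        df.to_csv(out / f"control_{label}.tsv", sep="\t")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(bundle["truth"].to_json_dict(), fh, indent=1, sort_keys=True)
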