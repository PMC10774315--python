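"""Synthetic single-cell and bulk-cohort generators with planted ground truth.

The generators emulate the statistical structure the downstream analysis
assumes: a negative-binomial single-cell count matrix with Bernoulli dropout
and cluster-specific marker shifts; multi-dataset bulk cohorts with Gaussian
log-scale expression, per-dataset location/scale batch effects, planted
rank-inverting gene pairs whose inversion probabilities are calibrated in
closed form (probit), Gleason grade correlated with the metastasis label,
and exponential progression-free survival with independent censoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GLEASON_LEVELS, BulkCohort, SimTruth, SingleCellMatrix

#: Baseline Gleason category frequencies (<=6, 7, 8, 9, 10).
GLEASON_BASE_PROBS = (0.25, 0.40, 0.20, 0.10, 0.05)

#: Tumor stage categories and frequencies.
STAGE_LEVELS = ("T1", "T2", "T3", "T4")
STAGE_PROBS = (0.15, 0.45, 0.30, 0.10)

#: Gaussian noise SD of bulk log expression; the probit calibration assumes it.
BULK_NOISE_SD = 1.0


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def default_planted_pairs(n_pairs: int = 13, start: int = 0) -> list[tuple[str, str]]:
    """Gene-disjoint (up, down) pairs over the default gene namespace."""
    return [
        (f"g{start + 2 * i:04d}", f"g{start + 2 * i + 1:04d}")
        for i in range(n_pairs)
    ]


@dataclass
class SimConfig:
    """Parameters of one simulated study.

    Defaults are the study conditions the pipeline is evaluated under:
    13 gene-disjoint planted pairs among 2,000 genes, per-class inversion
    probabilities 0.65/0.35, a 600-sample three-dataset bulk cohort with a
    35% metastasis prevalence, and the same 26 genes planted as up/down
    markers (ln-fold effect 1.0) in three stromal-like clusters.
    """

    n_genes: int = 2000
    clusters: list[tuple[str, int]] = field(
        default_factory=lambda: [("c5", 150), ("c6", 150), ("c7", 150), ("rest", 300)]
    )
    planted_markers: list[tuple[str, str, float]] = field(default_factory=list)
    nb_dispersion: float = 2.0
    dropout_rate: float = 0.3
    bulk_n_samples: int = 600
    bulk_n_datasets: int = 3
    met_prevalence: float = 0.35
    planted_pairs: list[tuple[str, str]] = field(default_factory=list)
    inversion_prob_met: float = 0.65
    inversion_prob_nonmet: float = 0.35
    pair_corr_sd: float = 2.0
    batch_shift_sd: float = 1.0
    batch_scale_sd: float = 0.25
    gleason_met_log_odds: float = 1.0
    surv_baseline_rate: float = 0.02
    surv_log_hr_signature: float = math.log(2.0)
    surv_log_hr_gleason: float = 0.3
    censor_rate: float = 0.01
    seed: int = 0

    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_genes)]

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        for p, name in [
            (self.dropout_rate, "dropout_rate"),
            (self.met_prevalence, "met_prevalence"),
            (self.inversion_prob_met, "inversion_prob_met"),
            (self.inversion_prob_nonmet, "inversion_prob_nonmet"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be a probability, got {p}")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if self.surv_baseline_rate <= 0:
            raise ConfigError("surv_baseline_rate must be positive")
        if self.censor_rate < 0:
            raise ConfigError("censor_rate must be non-negative")
        if self.batch_shift_sd < 0 or self.batch_scale_sd < 0:
            raise ConfigError("batch SDs must be non-negative")
        if self.pair_corr_sd < 0:
            raise ConfigError("pair_corr_sd must be non-negative")
        if self.bulk_n_datasets < 1:
            raise ConfigError("bulk_n_datasets must be >= 1")
        genes = set(self.gene_ids())
        for cluster, gene, _ in self.planted_markers:
            if gene not in genes:
                raise ConfigError(f"planted marker gene {gene!r} out of range")
            if cluster not in {c for c, _ in self.clusters}:
                raise ConfigError(f"planted marker cluster {cluster!r} unknown")
        seen: set[str] = set()
        for up, down in self.planted_pairs:
            if up == down:
                raise ConfigError(f"planted pair genes must be distinct ({up!r})")
            for g in (up, down):
                if g not in genes:
                    raise ConfigError(f"planted pair gene {g!r} out of range")
                if g in seen:
                    raise ConfigError(
                        f"gene {g!r} appears in more than one planted pair"
                    )
                seen.add(g)
        if (
            self.planted_pairs
            and self.inversion_prob_met < self.inversion_prob_nonmet
        ):
            raise ConfigError(
                "inversion_prob_met must be >= inversion_prob_nonmet "
                "when pairs are planted (equality = no signal)"
            )

    @classmethod
    def default_study(cls, seed: int = 0, **overrides) -> "SimConfig":
        """The planted-signal study: 13 pairs, markers mirrored per cluster.

        The 26 pair genes are planted as single-cell markers of the three
        stromal-like clusters (up genes positive, down genes negative, ln-fold
        effect 1.0 split across clusters round-robin), so the marker->mechanism
        ->classifier chain can recover the planted pairs end to end.
        """
        pairs = default_planted_pairs(13)
        cluster_ids = ["c5", "c6", "c7"]
        markers = []
        for i, (up, down) in enumerate(pairs):
            c = cluster_ids[i % len(cluster_ids)]
            markers.append((c, up, 1.0))
            markers.append((c, down, -1.0))
        cfg = cls(planted_pairs=pairs, planted_markers=markers, seed=seed)
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg

    @classmethod
    def null_study(cls, seed: int = 0, **overrides) -> "SimConfig":
        """Same marker structure, but no outcome signal in the bulk cohort.

        Planted pairs keep calibrated equal inversion probabilities in both
        classes (0.5/0.5) and the survival log-hazards are zero, so every
        downstream statistic should sit at its null.
        """
        cfg = cls.default_study(seed=seed)
        cfg.inversion_prob_met = 0.5
        cfg.inversion_prob_nonmet = 0.5
        cfg.surv_log_hr_signature = 0.0
        cfg.surv_log_hr_gleason = 0.0
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg


def simulate_single_cell(config: SimConfig) -> tuple[SingleCellMatrix, SimTruth]:
    """Draw a clustered negative-binomial count matrix with Bernoulli dropout.

    Each gene g has a base mean mu_g (log-normal across genes); a planted
    marker (cluster c, gene g, effect e) multiplies the mean by exp(e) in
    cluster c. Counts are NB(mean, shared dispersion) thinned by an
    independent keep-probability 1 - dropout_rate.
    """
    config.validate()
    if len(config.clusters) < 2:
        raise ConfigError("need at least 2 clusters")
    for cid, n in config.clusters:
        if n < 20:
            raise ConfigError(f"cluster {cid!r} needs >= 20 cells, got {n}")
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids()
    gene_pos = {g: i for i, g in enumerate(genes)}
    base_log_mean = rng.normal(loc=0.0, scale=1.0, size=config.n_genes)

    effects = np.zeros((config.n_genes, len(config.clusters)))
    cluster_index = {cid: j for j, (cid, _) in enumerate(config.clusters)}
    for cluster, gene, eff in config.planted_markers:
        effects[gene_pos[gene], cluster_index[cluster]] += eff

    blocks, labels, cell_ids = [], [], []
    r = config.nb_dispersion
    for j, (cid, n_cells) in enumerate(config.clusters):
        mu = np.exp(base_log_mean + effects[:, j])[:, None]  # genes x 1
        p = r / (r + mu)
        counts = rng.negative_binomial(r, np.broadcast_to(p, (config.n_genes, n_cells)))
        keep = rng.random((config.n_genes, n_cells)) >= config.dropout_rate
        blocks.append(counts * keep)
        labels.extend([cid] * n_cells)
        cell_ids.extend([f"{cid}_cell{i:04d}" for i in range(n_cells)])

    matrix = SingleCellMatrix(
        counts=np.concatenate(blocks, axis=1),
        gene_ids=genes,
        cell_ids=cell_ids,
        cluster_labels=np.array(labels),
    )
    truth = SimTruth(
        planted_markers=pd.DataFrame(
            [
                {
                    "cluster": c,
                    "gene": g,
                    "logfc_effect": e,
                    "base_mean": float(np.exp(base_log_mean[gene_pos[g]])),
                }
                for c, g, e in config.planted_markers
            ]
        ),
        planted_pairs=pd.DataFrame(
            [{"up_gene": u, "down_gene": d} for u, d in config.planted_pairs]
        ),
        seed=config.seed,
    )
    return matrix, truth


def _pair_offsets(config: SimConfig) -> tuple[float, float]:
    """Per-class mean offsets delta such that P(up > down) hits the target.

    With independent N(., sigma^2) noise on both genes, up - down is
    N(delta, 2 sigma^2), so delta = sqrt(2) * sigma * Phi^{-1}(target).
    """
    s = math.sqrt(2.0) * BULK_NOISE_SD
    return (
        s * stats.norm.ppf(config.inversion_prob_met),
        s * stats.norm.ppf(config.inversion_prob_nonmet),
    )


def _sample_gleason(rng: np.random.Generator, met: np.ndarray, log_odds: float) -> np.ndarray:
    """Proportional-odds draw of Gleason categories, tilted by metastasis."""
    cum = np.cumsum(GLEASON_BASE_PROBS)[:-1]
    thresholds = np.log(cum / (1.0 - cum))
    latent = rng.logistic(loc=log_odds * met, size=len(met))
    idx = (latent[:, None] > thresholds[None, :]).sum(axis=1)
    return np.asarray(GLEASON_LEVELS)[idx]


def simulate_bulk_cohort(config: SimConfig) -> tuple[BulkCohort, SimTruth]:
    """Draw a multi-dataset bulk cohort with planted rank-inverting pairs.

    Log-scale expression is Gaussian around per-gene base means; each planted
    (up, down) pair shares a base mean and receives a symmetric +-delta/2
    class-conditional offset calibrated so that P(up > down | class) equals
    the configured inversion probability on the batch-free scale. Each
    dataset then applies its own per-gene additive shift ~ N(0, shift_sd^2)
    and multiplicative scale ~ lognormal(0, scale_sd), removable by
    per-dataset gene-wise z-scoring.
    """
    config.validate()
    if config.met_prevalence in (0.0, 1.0):
        raise ConfigError("met_prevalence of exactly 0 or 1 gives a degenerate cohort")
    rng = np.random.default_rng(config.seed + 1)
    genes = config.gene_ids()
    gene_pos = {g: i for i, g in enumerate(genes)}
    n, g = config.bulk_n_samples, config.n_genes

    met = rng.binomial(1, config.met_prevalence, size=n)
    base_mean = rng.normal(0.0, 1.0, size=g)
    delta_met, delta_non = _pair_offsets(config)
    # Class-conditional mean offsets per gene (zero off the planted pairs).
    offset = np.zeros((2, g))  # rows: non-met, met
    for up, down in config.planted_pairs:
        iu, idn = gene_pos[up], gene_pos[down]
        base_mean[idn] = base_mean[iu]  # shared base so the offset is the whole story
        offset[1, iu], offset[1, idn] = +delta_met / 2.0, -delta_met / 2.0
        offset[0, iu], offset[0, idn] = +delta_non / 2.0, -delta_non / 2.0

    latent = (
        base_mean[None, :]
        + offset[met, :]
        + rng.normal(0.0, BULK_NOISE_SD, size=(n, g))
    )
    # The two genes of a planted pair are co-regulated: they share a
    # per-sample latent factor (within-pair correlation pair_corr_sd^2 /
    # (pair_corr_sd^2 + noise^2), ~0.8 at the defaults). The factor cancels
    # in the up-down difference, so the probit calibration is untouched,
    # while cross-pairings of genes from different pairs carry extra
    # variance and strictly smaller inversion-probability separation —
    # making the planted pairing itself identifiable.
    if config.pair_corr_sd > 0:
        for up, down in config.planted_pairs:
            shared = rng.normal(0.0, config.pair_corr_sd, size=n)
            latent[:, gene_pos[up]] += shared
            latent[:, gene_pos[down]] += shared

    dataset = np.array(
        [f"ds{1 + (i % config.bulk_n_datasets)}" for i in range(n)]
    )
    dataset = dataset[rng.permutation(n)]
    expr = np.empty_like(latent)
    for d in np.unique(dataset):
        rows = dataset == d
        shift = rng.normal(0.0, config.batch_shift_sd, size=g)
        scale = np.exp(rng.normal(0.0, config.batch_scale_sd, size=g))
        expr[rows] = latent[rows] * scale[None, :] + shift[None, :]

    sample_ids = [f"s{i:04d}" for i in range(n)]
    gleason = _sample_gleason(rng, met, config.gleason_met_log_odds)
    meta = pd.DataFrame(
        {
            "dataset": dataset,
            "met_event": met,
            "gleason": gleason,
            "age": np.clip(rng.normal(66.0, 7.0, size=n), 45.0, 90.0).round(1),
            "psa": np.exp(rng.normal(2.2, 0.7, size=n)).round(2),
            "stage": rng.choice(STAGE_LEVELS, size=n, p=STAGE_PROBS),
            "pfs_months": np.nan,
            "pfs_event": np.nan,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    cohort = BulkCohort(
        expr=pd.DataFrame(expr, index=meta.index, columns=genes), meta=meta
    )
    truth = SimTruth(
        planted_pairs=pd.DataFrame(
            [
                {
                    "up_gene": u,
                    "down_gene": d,
                    "delta_met": delta_met,
                    "delta_nonmet": delta_non,
                }
                for u, d in config.planted_pairs
            ]
        ),
        seed=config.seed,
    )
    return cohort, truth


def simulate_survival(cohort: BulkCohort, config: SimConfig) -> BulkCohort:
    """Attach exponential progression-free survival to a bulk cohort.

    The hazard is log-linear: baseline_rate * exp(beta * met + gamma * gleason
    index), with the metastasis label as the signature-linked signal and the
    Gleason category index (<=6 -> 0 ... 10 -> 4) as the clinical term.
    Censoring is an independent exponential clock; times are in months.
    """
    config.validate()
    if "met_event" not in cohort.meta or "gleason" not in cohort.meta:
        raise ValueError("cohort needs met_event and gleason columns")
    rng = np.random.default_rng(config.seed + 2)
    met = cohort.meta["met_event"].to_numpy(dtype=float)
    gleason_idx = (
        pd.Categorical(cohort.meta["gleason"], categories=list(GLEASON_LEVELS))
        .codes.astype(float)
    )
    hazard = config.surv_baseline_rate * np.exp(
        config.surv_log_hr_signature * met
        + config.surv_log_hr_gleason * gleason_idx
    )
    event_time = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        censor_time = rng.exponential(1.0 / config.censor_rate, size=len(met))
    else:
        censor_time = np.full(len(met), np.inf)
    meta = cohort.meta.copy()
    meta["pfs_months"] = np.minimum(event_time, censor_time)
    meta["pfs_event"] = (event_time <= censor_time).astype(int)
    return BulkCohort(expr=cohort.expr, meta=meta)
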