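"""Synthetic data with known planted truths for every pipeline stage.

Three generators emulate the study designs the pipeline consumes:

- a dual-luciferase reporter screen of a miRNA mimic library against one
  focal 3'UTR plus a panel of analog screens of unrelated 3'UTRs, with
  multiplicative (log-additive) noise and planted repression effects for
  a chosen set of targeting miRNAs;
- a tumor cohort with a latent MYCN-activity variable, a MYCN mRNA row,
  activity-driven genes, and a set of miRNAs with planted inverse
  coupling to MYCN;
- a qPCR Cq time course over two genotypes with planted per-genotype
  expression slopes.

All generators are deterministic given their seed, and zero-noise
configurations are constructed so downstream estimators recover the
planted truths exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

FOCAL_SCREEN = "focal"


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ScreenSimConfig:
    """Reporter-screen simulation parameters.

    ``effect_log2`` is the planted mean shift of the log2 Firefly/Renilla
    ratio for targeting miRNAs (negative = repression); ``noise_sd`` is
    the sd of additive Gaussian noise on the log ratio; ``bias_sd``
    optionally plants a per-miRNA bias shared by all screens to exercise
    the median-centering baseline.
    """

    n_mirnas: int = 470
    n_targeting: int = 29
    effect_log2: float = -3.0
    noise_sd: float = 0.2
    n_replicates: int = 2
    n_analog_screens: int = 36
    bias_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_mirnas <= 0 or self.n_replicates < 1 or self.n_analog_screens < 1:
            raise ConfigurationError("counts must be positive")
        if not 0 <= self.n_targeting <= self.n_mirnas:
            raise ConfigurationError("n_targeting must be in [0, n_mirnas]")
        if self.noise_sd < 0 or self.bias_sd < 0:
            raise ConfigurationError("noise_sd and bias_sd must be >= 0")


def generate_screen(config: ScreenSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate plate tables for the focal screen and its analog panel.

    Returns ``(plates, truth)``: one plate row per (screen, replicate,
    miRNA) with Firefly/Renilla readings, and a truth table flagging the
    planted targeting miRNAs.  Analog screens carry no planted focal
    effect (only the shared per-miRNA bias, if any).
    """
    rng = _rng(config.seed)
    mirnas = np.array([f"mir-{i:04d}" for i in range(1, config.n_mirnas + 1)])
    targeting = np.sort(
        rng.choice(mirnas, size=config.n_targeting, replace=False)
    )
    is_target = np.isin(mirnas, targeting)
    bias = (
        rng.normal(0.0, config.bias_sd, size=config.n_mirnas)
        if config.bias_sd > 0
        else np.zeros(config.n_mirnas)
    )

    screens = [(FOCAL_SCREEN, r + 1) for r in range(config.n_replicates)]
    screens += [
        (f"analog-{a:02d}", r + 1)
        for a in range(1, config.n_analog_screens + 1)
        for r in range(1)
    ]
    rows = []
    for screen_id, rep in screens:
        logratio = bias.copy()
        if screen_id == FOCAL_SCREEN:
            logratio = logratio + np.where(is_target, config.effect_log2, 0.0)
        if config.noise_sd > 0:
            logratio = logratio + rng.normal(0.0, config.noise_sd, config.n_mirnas)
        # common well scale cancels in the Firefly/Renilla ratio
        scale = rng.lognormal(0.0, 0.1, config.n_mirnas)
        renilla = 1e5 * scale
        firefly = renilla * np.exp2(logratio)
        rows.append(
            pd.DataFrame(
                {
                    "screen_id": screen_id,
                    "replicate": rep,
                    "mirna_id": mirnas,
                    "firefly": firefly,
                    "renilla": renilla,
                }
            )
        )
    plates = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame({"mirna_id": mirnas, "is_target": is_target})
    return plates, truth


@dataclass(frozen=True)
class CohortSimConfig:
    """Tumor-cohort simulation parameters.

    A latent per-sample activity variable drives a fraction of genes and
    the MYCN mRNA row; miRNAs in ``planted_inverse`` are coupled to MYCN
    with sample correlation magnitude ``coupling_r`` (negative sign).
    Non-planted miRNA rows and non-activity gene rows are pure
    ``noise_sd``-scaled noise, so a zero-noise cohort has no spurious
    correlation structure.
    """

    n_samples: int = 160
    n_mirnas: int = 200
    n_genes: int = 200
    planted_inverse: tuple[str, ...] = ()
    coupling_r: float = 0.6
    activity_gene_fraction: float = 0.25
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 4 or self.n_mirnas <= 0 or self.n_genes <= 0:
            raise ConfigurationError("invalid cohort dimensions")
        if not 0.0 <= self.coupling_r <= 1.0:
            raise ConfigurationError("coupling_r must be in [0, 1]")
        if not 0.0 <= self.activity_gene_fraction <= 1.0:
            raise ConfigurationError("activity_gene_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


def default_mirna_ids(n: int) -> list[str]:
    return [f"mir-{i:04d}" for i in range(1, n + 1)]


def generate_cohort(
    config: CohortSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate miRNA and mRNA expression matrices for a tumor cohort.

    Returns ``(mirna_matrix, mrna_matrix, truth)``; the mRNA matrix
    includes a ``MYCN`` row.  Planted miRNAs satisfy
    corr(miRNA, MYCN) = -coupling_r in population, exactly -1 when
    coupling_r = 1 (the coupling is built from the standardized MYCN
    row itself).  Truth labels flag planted miRNAs and activity genes.
    """
    rng = _rng(config.seed)
    samples = [f"sample-{i:03d}" for i in range(1, config.n_samples + 1)]
    mirnas = default_mirna_ids(config.n_mirnas)
    unknown = set(config.planted_inverse) - set(mirnas)
    if unknown:
        raise ConfigurationError(f"planted miRNAs not in matrix: {sorted(unknown)}")

    activity = rng.normal(size=config.n_samples)
    mycn = activity + config.noise_sd * rng.normal(size=config.n_samples)
    mycn_std = (mycn - mycn.mean()) / (mycn.std() if mycn.std() > 0 else 1.0)

    planted = set(config.planted_inverse)
    r = config.coupling_r
    mirna_rows = {}
    for m in mirnas:
        if m in planted:
            eps = rng.normal(size=config.n_samples)
            mirna_rows[m] = -r * mycn_std + np.sqrt(1 - r**2) * eps
        else:
            mirna_rows[m] = config.noise_sd * rng.normal(size=config.n_samples)
    mirna_matrix = pd.DataFrame(mirna_rows, index=samples).T

    n_activity = int(round(config.activity_gene_fraction * config.n_genes))
    genes = [f"gene-{i:04d}" for i in range(1, config.n_genes + 1)]
    gene_rows = {}
    for i, g in enumerate(genes):
        if i < n_activity:
            gene_rows[g] = activity + config.noise_sd * rng.normal(size=config.n_samples)
        else:
            gene_rows[g] = config.noise_sd * rng.normal(size=config.n_samples)
    mrna_matrix = pd.DataFrame(gene_rows, index=samples).T
    mrna_matrix.loc["MYCN"] = mycn

    truth = pd.DataFrame(
        {
            "feature": mirnas + genes,
            "kind": ["mirna"] * len(mirnas) + ["gene"] * len(genes),
            "planted_inverse": [m in planted for m in mirnas] + [False] * len(genes),
            "activity_driven": [False] * len(mirnas)
            + [i < n_activity for i in range(len(genes))],
        }
    )
    return mirna_matrix, mrna_matrix, truth


def make_activity_gene_sets(
    truth: pd.DataFrame, n_sets: int = 6, set_size: int = 25, seed: int = 0
) -> dict[str, list[str]]:
    """Gene sets of activity-driven genes, emulating MYC(N)-up collections."""
    rng = _rng(seed)
    pool = truth.loc[
        (truth["kind"] == "gene") & truth["activity_driven"], "feature"
    ].to_numpy()
    if pool.size == 0:
        raise ConfigurationError("no activity-driven genes in truth table")
    size = min(set_size, pool.size)
    return {
        f"ACTIVITY_UP_{k + 1}": sorted(rng.choice(pool, size=size, replace=False))
        for k in range(n_sets)
    }


@dataclass(frozen=True)
class TimecourseSimConfig:
    """Cq time-course simulation parameters.

    ``planted_slopes`` maps miRNA id to (slope_TG, slope_WT) in
    expression units per week; unlisted miRNAs get slope 0 in both
    genotypes.  Cq = cq_baseline - expression + noise, so lower Cq means
    higher expression.
    """

    timepoints: tuple[float, ...] = (1.0, 2.0, 6.0)
    n_per_group: int = 4
    n_mirnas: int = 50
    planted_slopes: dict = field(default_factory=dict)
    cq_noise_sd: float = 0.25
    cq_baseline: float = 25.0
    balance_panel: bool = True
    seed: int = 0

    def __post_init__(self):
        if len(set(self.timepoints)) < 2:
            raise ConfigurationError("need >=2 distinct timepoints")
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        if self.cq_noise_sd < 0:
            raise ConfigurationError("cq_noise_sd must be >= 0")


def generate_timecourse(
    config: TimecourseSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a Cq table over genotypes and timepoints.

    Returns ``(cq, annotations, truth)``: a miRNA x sample Cq matrix, a
    sample annotation table (genotype, time_weeks) and the planted
    per-genotype slopes.
    """
    rng = _rng(config.seed)
    mirnas = default_mirna_ids(config.n_mirnas)
    slopes = {
        m: config.planted_slopes.get(m, (0.0, 0.0)) for m in mirnas
    }
    unknown = set(config.planted_slopes) - set(mirnas)
    if unknown:
        raise ConfigurationError(f"planted miRNAs not simulated: {sorted(unknown)}")
    if config.balance_panel:
        # global mean normalization identifies expression relative to the
        # per-sample panel mean; a ballast assay absorbing the planted
        # drift keeps that mean stable so planted slopes are identifiable
        sum_tg = sum(s[0] for s in slopes.values())
        sum_wt = sum(s[1] for s in slopes.values())
        slopes["mir-ballast"] = (-sum_tg, -sum_wt)
        mirnas = mirnas + ["mir-ballast"]

    cols, ann_rows = [], []
    for geno in ("TG", "WT"):
        for t in config.timepoints:
            for i in range(config.n_per_group):
                sid = f"{geno}-w{t:g}-{i + 1}"
                cols.append(sid)
                ann_rows.append((sid, geno, float(t)))
    ann = pd.DataFrame(
        ann_rows, columns=["sample_id", "genotype", "time_weeks"]
    ).set_index("sample_id")

    data = np.empty((len(mirnas), len(cols)))
    for j, sid in enumerate(cols):
        geno, t = ann.at[sid, "genotype"], ann.at[sid, "time_weeks"]
        for i, m in enumerate(mirnas):
            s_tg, s_wt = slopes[m]
            expr = (s_tg if geno == "TG" else s_wt) * t
            data[i, j] = config.cq_baseline - expr
    if config.cq_noise_sd > 0:
        data = data + rng.normal(0.0, config.cq_noise_sd, size=data.shape)
    cq = pd.DataFrame(data, index=mirnas, columns=cols)
    truth = pd.DataFrame(
        {
            "mirna_id": mirnas,
            "slope_tg": [slopes[m][0] for m in mirnas],
            "slope_wt": [slopes[m][1] for m in mirnas],
            "is_ballast": [m == "mir-ballast" for m in mirnas],
        }
    ).set_index("mirna_id")
    return cq, ann, truth
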