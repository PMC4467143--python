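"""Dual-luciferase reporter-screen scoring.

Converts raw Firefly/Renilla well readings into per-miRNA interaction
scores and calls hits against a ROC-derived cutoff.  The score of a miRNA
is the robust z-score of its log2(Firefly/Renilla) ratio within a screen,
median-centered per miRNA against a panel of analogous screens of unrelated
3'UTRs so that systematic, sequence-independent effects of each mimic
cancel out.  More negative scores indicate stronger repression of the
reporter, i.e. stronger evidence that the miRNA targets the 3'UTR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

from .errors import DegenerateDistributionError, InvalidWellError

logger = logging.getLogger(__name__)

#: consistency constant making the MAD estimate the normal sd
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class RocCutoff:
    """Operating point chosen on the ROC curve of known interactions.

    ``cutoff`` separates interactions (score strictly below) from
    non-interactions; sensitivity/specificity/accuracy are the fractions
    achieved on the control sets used to derive it.
    """

    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float

    def __post_init__(self):
        for name in ("sensitivity", "specificity", "accuracy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def normalize_reporter(firefly: float, renilla: float) -> float:
    """log2 Firefly/Renilla ratio for a single well.

    Renilla is the co-transfected control; a non-positive reading means the
    well failed and raises :class:`InvalidWellError`.  A zero Firefly
    reading yields ``-inf``, which downstream steps treat as unusable.
    """
    if renilla <= 0:
        raise InvalidWellError(
            f"Renilla reading must be positive, got {renilla}"
        )
    if firefly < 0:
        raise InvalidWellError(
            f"Firefly reading must be non-negative, got {firefly}"
        )
    with np.errstate(divide="ignore"):
        return float(np.log2(firefly / renilla))


def robust_zscore(values) -> np.ndarray:
    """Robust z-scores: (x - median) / (1.4826 * MAD).

    Requires at least 3 finite values and a non-zero median absolute
    deviation; otherwise the scale is undefined and a
    :class:`DegenerateDistributionError` is raised.  NaNs are propagated.
    """
    x = np.asarray(values, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 3:
        raise DegenerateDistributionError(
            f"need >=3 finite values, got {finite.size}"
        )
    med = np.median(finite)
    mad = median_abs_deviation(finite)
    if mad == 0:
        raise DegenerateDistributionError("median absolute deviation is zero")
    return (x - med) / (MAD_SCALE * mad)


def _robust_z_with_fallback(values) -> np.ndarray:
    """Robust z for a whole screen; unit scale if the MAD degenerates.

    A screen in which more than half the log-ratios are identical (e.g. a
    noise-free simulation) has MAD 0; centering on the median with unit
    scale preserves effect sizes and keeps the pipeline defined.
    """
    x = np.asarray(values, dtype=float)
    try:
        return robust_zscore(x)
    except DegenerateDistributionError:
        finite = x[np.isfinite(x)]
        med = np.median(finite) if finite.size else np.nan
        logger.warning(
            "degenerate screen distribution (MAD=0); using unit scale"
        )
        return x - med


def median_center(focal_z: pd.Series, analog_z: pd.DataFrame) -> pd.Series:
    """Subtract each miRNA's median analog-screen z from its focal z.

    ``analog_z`` is a miRNA x analog-screen matrix of robust z-scores from
    screens of unrelated 3'UTRs.  A miRNA missing from the analog matrix,
    or with no finite analog value, is excluded with a warning rather than
    scored against an undefined baseline.
    """
    out = {}
    for mirna, z in focal_z.items():
        if mirna not in analog_z.index:
            logger.warning("miRNA %s missing from analog matrix; excluded", mirna)
            continue
        row = analog_z.loc[mirna].to_numpy(dtype=float)
        row = row[np.isfinite(row)]
        if row.size == 0:
            logger.warning("miRNA %s has no finite analog values; excluded", mirna)
            continue
        out[mirna] = z - float(np.median(row))
    return pd.Series(out, name=focal_z.name, dtype=float)


def combine_replicates(replicate_scores: list[pd.Series]) -> pd.DataFrame:
    """Average per-miRNA interaction scores over independent screens.

    Returns a frame with one ``score_rep<i>`` column per replicate, the
    arithmetic mean ``score_avg`` over the replicates in which the miRNA
    was scored, and ``n_reps`` recording that count (miRNAs absent from
    some replicate are averaged over the available ones).
    """
    if not replicate_scores:
        raise ValueError("at least one replicate score table is required")
    frame = pd.concat(
        {f"score_rep{i + 1}": s for i, s in enumerate(replicate_scores)},
        axis=1,
    )
    frame["score_avg"] = frame.mean(axis=1, skipna=True)
    frame["n_reps"] = frame.drop(columns="score_avg").notna().sum(axis=1)
    incomplete = frame.index[frame["n_reps"] < len(replicate_scores)]
    for mirna in incomplete:
        logger.warning(
            "miRNA %s scored in %d/%d replicates",
            mirna, frame.at[mirna, "n_reps"], len(replicate_scores),
        )
    return frame.sort_index()


def determine_cutoff(positive_scores, negative_scores) -> RocCutoff:
    """ROC analysis of validated vs negative-control interaction scores.

    Candidate thresholds are the midpoints between consecutive distinct
    pooled scores plus sentinels below the minimum and above the maximum.
    A score predicts "interaction" iff it lies strictly below the
    threshold.  The threshold maximizing accuracy = (TP+TN)/(P+N) is
    returned; ties are broken by higher specificity, then by the more
    negative threshold.
    """
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("positive and negative score sets must be non-empty")
    pooled = np.unique(np.concatenate([pos, neg]))
    candidates = np.concatenate(
        [[pooled[0] - 1.0], (pooled[:-1] + pooled[1:]) / 2.0, [pooled[-1] + 1.0]]
    )
    best = None
    for c in candidates:
        tp = int(np.sum(pos < c))
        tn = int(np.sum(neg >= c))
        acc = (tp + tn) / (pos.size + neg.size)
        sens = tp / pos.size
        spec = tn / neg.size
        # lexicographic: accuracy desc, specificity desc, cutoff asc
        key = (acc, spec, -c)
        if best is None or key > best[0]:
            best = (key, RocCutoff(float(c), sens, spec, acc))
    return best[1]


def call_hits(scores: pd.DataFrame, cutoff: float) -> list[str]:
    """miRNAs whose average interaction score is strictly below ``cutoff``.

    A score exactly equal to the cutoff is not a hit.
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    if len(scores) == 0:
        return []
    avg = scores["score_avg"]
    return sorted(avg.index[avg < cutoff].tolist())


def score_screens(
    plates: pd.DataFrame,
    focal_screen: str,
    cutoff: float | None = None,
) -> pd.DataFrame:
    """Full scoring pipeline from a raw plate table.

    ``plates`` has columns ``screen_id, replicate, mirna_id, firefly,
    renilla``.  Per (screen, replicate): log2 ratios then robust z across
    miRNAs.  All non-focal screens form the analog panel; each focal
    replicate is median-centered per miRNA against the pooled analog
    z-columns and the replicates are then averaged.  If ``cutoff`` is
    given a boolean ``hit`` column is added.
    """
    required = {"screen_id", "replicate", "mirna_id", "firefly", "renilla"}
    missing = required - set(plates.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    dup = plates.duplicated(subset=["screen_id", "replicate", "mirna_id"])
    if dup.any():
        raise ValueError("duplicate (screen_id, replicate, mirna_id) rows")

    zcols: dict[tuple[str, str], pd.Series] = {}
    for (screen, rep), grp in plates.groupby(["screen_id", "replicate"]):
        if (grp["renilla"] <= 0).any():
            raise InvalidWellError(
                f"non-positive Renilla reading in screen {screen} rep {rep}"
            )
        with np.errstate(divide="ignore"):
            lr = np.log2(grp["firefly"].to_numpy() / grp["renilla"].to_numpy())
        usable = np.isfinite(lr)
        if not usable.all():
            logger.warning(
                "%d unusable wells (zero Firefly) in screen %s rep %s",
                int((~usable).sum()), screen, rep,
            )
        lr = np.where(usable, lr, np.nan)
        z = _robust_z_with_fallback(lr)
        zcols[(screen, rep)] = pd.Series(z, index=grp["mirna_id"].to_numpy())

    analog = pd.DataFrame(
        {k: v for k, v in zcols.items() if k[0] != focal_screen}
    )
    if analog.shape[1] == 0:
        raise ValueError("no analog screens found for median centering")
    focal_keys = sorted(k for k in zcols if k[0] == focal_screen)
    if not focal_keys:
        raise ValueError(f"focal screen {focal_screen!r} not in plate table")
    centered = [median_center(zcols[k], analog) for k in focal_keys]
    table = combine_replicates(centered)
    if cutoff is not None:
        hits = set(call_hits(table, cutoff))
        table["hit"] = [m in hits for m in table.index]
    return table
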