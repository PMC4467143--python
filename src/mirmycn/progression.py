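"""Murine progression dynamics: Cq preprocessing, genotype x time
regression, signature scoring and two-group differential expression.

Expression profiling in the transgenic neuroblastoma progression model is
stem-loop RT-qPCR: quantification cycles (Cq) are kept only below 32,
normalized per sample by subtracting each value from the sample's global
mean Cq (so higher values mean higher expression and every sample is
centered at zero), and modelled per miRNA as a linear function of time
with a genotype-specific slope.  The transgenic-minus-wild-type slope
difference and its interaction-term p-value summarize how a miRNA's
expression trajectory changes under MYCN-driven tumor development;
pi = -log10(p) * delta-slope gives a signed significance for ranking and
cumulative-distribution comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .expression import bh_adjust, pi_value
from .seeds import KsResult, ks_two_sample

logger = logging.getLogger(__name__)

CQ_LIMIT = 32.0
Q_THRESHOLD = 0.05


def preprocess_cq(
    cq: pd.DataFrame, cq_limit: float = CQ_LIMIT
) -> pd.DataFrame:
    """Filter and global-mean-normalize a miRNA x sample Cq matrix.

    Cq values at or above ``cq_limit`` become missing.  Per sample,
    expression = mean(retained Cq) - Cq, so the mean of the retained,
    normalized values in every sample is exactly zero and lower Cq
    (higher abundance) maps to higher expression.  Samples with fewer
    than 2 retained values are dropped with a warning.
    """
    x = cq.astype(float).where(cq < cq_limit)
    keep = []
    for sample in x.columns:
        n_ret = int(x[sample].notna().sum())
        if n_ret < 2:
            logger.warning(
                "sample %s has %d retained Cq values; dropped", sample, n_ret
            )
        else:
            keep.append(sample)
    x = x[keep]
    return x.rsub(x.mean(axis=0), axis=1)


@dataclass(frozen=True)
class ProgressionRecord:
    """Per-miRNA genotype x time regression summary."""

    mirna_id: str
    slope_tg: float
    slope_wt: float
    delta_slope: float
    p: float
    q: float
    pi_value: float
    call: str        # down / up / n.s. / not-testable


def fit_genotype_time_regression(
    expression: pd.DataFrame,
    annotations: pd.DataFrame,
    q_threshold: float = Q_THRESHOLD,
) -> pd.DataFrame:
    """Fit expression ~ time * genotype per miRNA and test the interaction.

    ``annotations`` is indexed by sample with columns ``genotype`` (``TG``
    or ``WT``) and ``time_weeks`` (numeric).  One model per miRNA:
    intercept + time + genotype + time x genotype, with the interaction
    coefficient as the slope difference (TG - WT) and its two-sided
    t-test p-value, BH-corrected across testable miRNAs.  A miRNA with
    missing values leaving fewer than 6 observations or fewer than 2
    distinct timepoints in either genotype is flagged not-testable.
    """
    samples = [s for s in expression.columns if s in annotations.index]
    if not samples:
        raise ValueError("no annotated samples in expression matrix")
    ann = annotations.loc[samples]
    geno = (ann["genotype"] == "TG").to_numpy(dtype=float)
    if geno.all() or not geno.any():
        raise ValueError("both genotypes must be present")
    t = ann["time_weeks"].to_numpy(dtype=float)

    rows = []
    for mirna, row in expression[samples].iterrows():
        y = row.to_numpy(dtype=float)
        ok = np.isfinite(y)
        yy, tt, gg = y[ok], t[ok], geno[ok]
        enough = (
            ok.sum() >= 6
            and np.unique(tt[gg == 1]).size >= 2
            and np.unique(tt[gg == 0]).size >= 2
        )
        if not enough:
            rows.append((mirna, np.nan, np.nan, np.nan, np.nan, False))
            continue
        X = np.column_stack([np.ones_like(tt), tt, gg, tt * gg])
        fit = sm.OLS(yy, X).fit()
        delta = float(fit.params[3])
        p = float(fit.pvalues[3])
        if not np.isfinite(p):
            # zero-residual fit: interaction either exactly absent or exact
            p = 1.0 if delta == 0 else 0.0
        slope_wt = float(fit.params[1])
        rows.append((mirna, slope_wt + delta, slope_wt, delta, p, True))

    out = pd.DataFrame(
        rows,
        columns=["mirna_id", "slope_tg", "slope_wt", "delta_slope", "p", "testable"],
    ).set_index("mirna_id")
    out["q"] = np.nan
    testable = out.index[out["testable"]]
    if len(testable):
        out.loc[testable, "q"] = bh_adjust(out.loc[testable, "p"].to_numpy())
    out["pi_value"] = [
        pi_value(p, d) if np.isfinite(p) else np.nan
        for p, d in zip(out["p"], out["delta_slope"])
    ]
    call = []
    for mirna in out.index:
        if not out.at[mirna, "testable"]:
            call.append("not-testable")
        elif out.at[mirna, "q"] <= q_threshold and out.at[mirna, "delta_slope"] < 0:
            call.append("down")
        elif out.at[mirna, "q"] <= q_threshold and out.at[mirna, "delta_slope"] > 0:
            call.append("up")
        else:
            call.append("n.s.")
    out["call"] = call
    return out


def signature_score(
    expression: pd.DataFrame, signature: list[tuple[str, int]]
) -> pd.DataFrame:
    """Mean direction-signed z-score of signature miRNAs per sample.

    Each available signature miRNA is z-scored across all samples
    (population sd); the score of a sample is the mean over members of
    direction * z.  Members missing from the matrix or with zero
    variance are skipped; the covered fraction is reported alongside.
    """
    if not signature:
        raise ValueError("signature is empty")
    zrows = []
    used = 0
    for mirna, direction in signature:
        if mirna not in expression.index:
            continue
        x = expression.loc[mirna].to_numpy(dtype=float)
        sd = np.nanstd(x)
        if not np.isfinite(sd) or sd == 0:
            logger.warning("signature member %s has zero variance; skipped", mirna)
            continue
        zrows.append(direction * (x - np.nanmean(x)) / sd)
        used += 1
    if used == 0:
        raise ValueError("no signature miRNA with usable data in the matrix")
    scores = np.nanmean(np.vstack(zrows), axis=0)
    return pd.DataFrame(
        {"score": scores, "coverage": used / len(signature)},
        index=expression.columns,
    )


@dataclass(frozen=True)
class DiffExprRecord:
    """Two-group differential-expression summary for one miRNA."""

    mirna_id: str
    log2_fc: float
    p: float
    q: float
    call: str


def differential_expression(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    equal_var: bool = True,
    q_threshold: float = Q_THRESHOLD,
) -> pd.DataFrame:
    """Per-miRNA two-sample t-test between two sample groups.

    Expression is on a log2-like scale, so the effect is the plain mean
    difference (a - b).  Student's equal-variance t-test by default
    (``equal_var=False`` for Welch); BH across testable miRNAs.  miRNAs
    with zero variance in both groups are flagged not-testable.
    """
    if group_a.shape[1] < 2 or group_b.shape[1] < 2:
        raise ValueError("each group needs >=2 samples")
    shared = group_a.index.intersection(group_b.index)
    rows = []
    for mirna in shared:
        a = group_a.loc[mirna].to_numpy(dtype=float)
        b = group_b.loc[mirna].to_numpy(dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if a.size < 2 or b.size < 2:
            rows.append((mirna, np.nan, np.nan, False))
            continue
        fc = float(a.mean() - b.mean())
        if a.std() == 0 and b.std() == 0:
            rows.append((mirna, fc, np.nan, False))
            continue
        p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
        rows.append((mirna, fc, p, True))
    out = pd.DataFrame(
        rows, columns=["mirna_id", "log2_fc", "p", "testable"]
    ).set_index("mirna_id")
    out["q"] = np.nan
    testable = out.index[out["testable"]]
    if len(testable):
        out.loc[testable, "q"] = bh_adjust(out.loc[testable, "p"].to_numpy())
    call = []
    for mirna in out.index:
        if not out.at[mirna, "testable"]:
            call.append("not-testable")
        elif out.at[mirna, "q"] <= q_threshold:
            call.append("up" if out.at[mirna, "log2_fc"] > 0 else "down")
        else:
            call.append("n.s.")
    out["call"] = call
    return out


def compare_target_vs_nontarget_dynamics(
    pi_values: pd.Series, target_flags: pd.Series
) -> KsResult:
    """KS comparison of progression pi-values: targeting vs non-targeting."""
    flags = target_flags.reindex(pi_values.index).astype(bool)
    a = pi_values[flags].to_numpy(dtype=float)
    b = pi_values[~flags].to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    return ks_two_sample(a, b)
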