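"""Integration of screen hits with tumor expression data.

Per screen-hit miRNA, two independent lines of evidence are evaluated in
a MYCN non-amplified tumor cohort:

1. direct correlation between miRNA and MYCN mRNA expression
   (Spearman by default), BH-corrected, summarized by the signed
   significance pi-value = -log10(p) * coefficient;
2. correlation with MYCN *activity*: genes are ranked by their
   correlation with the miRNA and preranked GSEA against sets of
   MYC(N)-upregulated genes is run; negative enrichment (NES < -2,
   FDR < 0.25) of at least one set indicates inverse correlation with
   MYCN activity.

The final relevance call combines both axes and excludes miRNAs with
conflicting evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: floor applied to p-values inside -log10 so pi-values stay finite
PI_P_FLOOR = 1e-300

NES_THRESHOLD = 2.0
FDR_THRESHOLD = 0.25
Q_THRESHOLD = 0.05


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pi_value(p: float, effect: float) -> float:
    """Signed significance: -log10(p) times a signed effect size."""
    return float(-np.log10(max(p, PI_P_FLOOR)) * effect)


def correlate_to_mycn(
    mirna_matrix: pd.DataFrame,
    mycn: pd.Series,
    method: str = "spearman",
    q_threshold: float = Q_THRESHOLD,
) -> pd.DataFrame:
    """Correlate every miRNA row with MYCN expression across samples.

    Returns a frame indexed by miRNA with columns ``coefficient, p, q,
    pi_value, call, method, testable``.  ``call`` is "inverse"/"positive"
    when q <= threshold (by coefficient sign), else "n.s.".  Constant
    miRNA rows are flagged not testable and excluded from BH.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method: {method}")
    samples = [s for s in mirna_matrix.columns if s in mycn.index]
    if len(samples) < 4:
        raise ValueError("need >=4 shared samples")
    y = mycn.loc[samples].to_numpy(dtype=float)
    corr = stats.spearmanr if method == "spearman" else stats.pearsonr

    rows = []
    for mirna, row in mirna_matrix[samples].iterrows():
        x = row.to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((mirna, np.nan, np.nan, False))
            continue
        r, p = corr(x, y)
        rows.append((mirna, float(r), float(p), True))
    out = pd.DataFrame(
        rows, columns=["mirna_id", "coefficient", "p", "testable"]
    ).set_index("mirna_id")

    out["q"] = np.nan
    testable = out.index[out["testable"]]
    if len(testable):
        out.loc[testable, "q"] = bh_adjust(out.loc[testable, "p"].to_numpy())
    out["pi_value"] = [
        pi_value(p, r) if np.isfinite(p) else np.nan
        for p, r in zip(out["p"], out["coefficient"])
    ]
    call = []
    for mirna in out.index:
        q, r, ok = out.at[mirna, "q"], out.at[mirna, "coefficient"], out.at[mirna, "testable"]
        if not ok:
            call.append("not-testable")
        elif q <= q_threshold and r < 0:
            call.append("inverse")
        elif q <= q_threshold and r > 0:
            call.append("positive")
        else:
            call.append("n.s.")
    out["call"] = call
    out["method"] = method
    return out


def rank_genes_for_mirna(
    mirna_vector: pd.Series, mrna_matrix: pd.DataFrame
) -> pd.Series:
    """Genes ranked by decreasing Spearman correlation with the miRNA.

    Constant gene rows receive coefficient 0 (logged).  Ties are broken
    by lexicographic gene id so the ranking is deterministic.
    """
    samples = [s for s in mrna_matrix.columns if s in mirna_vector.index]
    if len(samples) < 4:
        raise ValueError("need >=4 shared samples")
    x = mirna_vector.loc[samples].to_numpy(dtype=float)
    stats_out = {}
    for gene, row in mrna_matrix[samples].iterrows():
        g = row.to_numpy(dtype=float)
        if np.ptp(g) == 0 or np.ptp(x) == 0:
            logger.debug("constant expression for %s; coefficient set to 0", gene)
            stats_out[gene] = 0.0
        else:
            stats_out[gene] = float(stats.spearmanr(g, x).statistic)
    s = pd.Series(stats_out, name="statistic")
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return s.loc[order]


@dataclass(frozen=True)
class GseaResult:
    """Preranked GSEA outcome for one gene set."""

    gene_set: str
    es: float
    nes: float
    p: float
    fdr: float
    n_permutations: int
    seed: int
    size: int
    mirna_id: str = ""


def _running_es(order_stats: np.ndarray, in_set: np.ndarray) -> float:
    """Weighted Kolmogorov-Smirnov-like running-sum enrichment score.

    Hits step up proportionally to |statistic| (weight exponent 1,
    normalized over in-set genes); misses step down by 1/(N - set size).
    The uniform fallback covers sets whose statistics are all zero.
    """
    n = order_stats.size
    nh = int(in_set.sum())
    w = np.abs(order_stats) * in_set
    total = w.sum()
    if total > 0:
        hit_steps = w / total
    else:
        hit_steps = in_set / nh
    steps = np.where(in_set, hit_steps, -1.0 / (n - nh))
    run = np.cumsum(steps)
    # extremum selected on the sum rounded to 12 decimals so that
    # 1-ulp accumulation noise cannot flip a tie between a positive
    # peak and a negative trough of equal magnitude
    return float(run[np.argmax(np.abs(np.round(run, 12)))])


def gsea_preranked(
    ranked: pd.Series,
    gene_set,
    n_permutations: int = 1000,
    seed: int = 0,
    gene_set_name: str = "",
    mirna_id: str = "",
) -> GseaResult:
    """Preranked GSEA of one gene set against a ranked gene list.

    ``ranked`` maps gene ids to ranking statistics, already sorted in
    decreasing order.  The null is built from ``n_permutations`` random
    gene sets of the same size drawn without replacement from the ranked
    genes with ``numpy.random.default_rng(seed)`` (one ``choice`` call
    per permutation, in order).  NES = ES / mean(|null ES| of matching
    sign); nominal p and FDR follow the matching-sign pooled-null
    convention.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    genes = ranked.index.to_numpy()
    statvals = ranked.to_numpy(dtype=float)
    members = set(gene_set)
    in_set = np.fromiter((g in members for g in genes), dtype=bool, count=genes.size)
    nh = int(in_set.sum())
    if nh == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if nh == genes.size:
        raise ValueError("gene set covers the entire ranked list")

    es = _running_es(statvals, in_set)

    rng = np.random.default_rng(seed)
    null_es = np.empty(n_permutations)
    for k in range(n_permutations):
        idx = rng.choice(genes.size, size=nh, replace=False)
        mask = np.zeros(genes.size, dtype=bool)
        mask[idx] = True
        null_es[k] = _running_es(statvals, mask)

    same_sign = null_es >= 0 if es >= 0 else null_es < 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        # no null ES on the observed side; fall back to the full null scale
        mean_abs = float(np.mean(np.abs(null_es)))
        nes = es / mean_abs if mean_abs > 0 else np.nan
        p = 1.0 / n_permutations
        fdr = p
    else:
        mean_abs = float(np.mean(np.abs(null_es[same_sign])))
        nes = es / mean_abs if mean_abs > 0 else np.nan
        extreme = np.abs(null_es[same_sign]) >= abs(es)
        p = float(extreme.sum()) / n_same
        null_nes = null_es[same_sign] / mean_abs
        fdr = float((np.abs(null_nes) >= abs(nes)).sum()) / n_same
    return GseaResult(
        gene_set_name, es, float(nes), min(p, 1.0), min(fdr, 1.0),
        n_permutations, seed, nh, mirna_id,
    )


def classify_activity_relation(
    results: list[GseaResult],
    nes_threshold: float = NES_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
) -> dict:
    """Call a miRNA's relation to MYCN activity from its GSEA results.

    "negative" iff any gene set has NES < -threshold and FDR below the
    FDR threshold; "positive" by the mirrored rule when no set qualifies
    negative; both directions qualifying is flagged ambiguous.
    """
    if not results:
        raise ValueError("at least one gene-set result is required")
    any_neg = any(
        r.nes < -nes_threshold and r.fdr < fdr_threshold for r in results
    )
    any_pos = any(
        r.nes > nes_threshold and r.fdr < fdr_threshold for r in results
    )
    if any_neg:
        call = "negative"
    elif any_pos:
        call = "positive"
    else:
        call = "none"
    return {"call": call, "ambiguous": any_neg and any_pos}


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction, 1 df) on a 2x2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("counts must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("all margins must be positive")
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class RelevanceCall:
    """Final per-hit classification combining both evidence axes."""

    mirna_id: str
    screen_hit: bool
    expression_call: str   # inverse / positive / n.s. / not-testable / no-data
    activity_call: str     # negative / positive / none / no-data
    final: str             # relevant / mycn-induced / conflicting-excluded /
                           # not-supported / no-data


def classify_relevance(
    hits: list[str],
    expression_calls: dict[str, str],
    activity_calls: dict[str, str],
) -> list[RelevanceCall]:
    """Combine correlation and activity evidence for every screen hit.

    A hit is "relevant" (a targeting miRNA supported in tumors) when
    either axis is inverse/negative and neither is positive; positive
    evidence without any inverse evidence makes it "mycn-induced";
    opposing axes are "conflicting-excluded"; a hit absent from the
    expression platform is "no-data".  Non-hits yield no call.
    """
    out = []
    for mirna in sorted(hits):
        e = expression_calls.get(mirna, "no-data")
        a = activity_calls.get(mirna, "no-data")
        has_inverse = e == "inverse" or a == "negative"
        has_positive = e == "positive" or a == "positive"
        if e in ("no-data",) and a in ("no-data",):
            final = "no-data"
        elif has_inverse and has_positive:
            final = "conflicting-excluded"
        elif has_inverse:
            final = "relevant"
        elif has_positive:
            final = "mycn-induced"
        else:
            final = "not-supported"
        out.append(RelevanceCall(mirna, True, e, a, final))
    return out
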