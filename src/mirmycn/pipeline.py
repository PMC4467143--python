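"""End-to-end orchestration of the screen / seed / expression /
progression stages, mirroring the integration accounting of the study
design: screened miRNAs -> interaction-score hits -> tumor-cohort
relevance calls -> murine progression calls.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import expression as expr
from . import progression as prog
from . import screen as scr
from . import seeds as seedmod
from .errors import StageError

logger = logging.getLogger(__name__)

VERSION = "0.1.0"


@dataclass
class PipelineConfig:
    """Thresholds and knobs for a full pipeline run."""

    cutoff: float = -1.94
    correlation_method: str = "spearman"
    q_threshold: float = 0.05
    nes_threshold: float = 2.0
    fdr_threshold: float = 0.25
    gsea_permutations: int = 500
    gsea_seed: int = 0
    focal_screen: str = "focal"
    equal_var: bool = True

    def __post_init__(self):
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must be in (0, 1)")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")
        if self.nes_threshold <= 0:
            raise ValueError("nes_threshold must be positive")
        if self.gsea_permutations < 100:
            raise ValueError("gsea_permutations must be >= 100")


@dataclass
class PipelineInputs:
    """In-memory inputs for a pipeline run; optional stages may be None."""

    plates: pd.DataFrame
    mirna_matrix: pd.DataFrame | None = None
    mrna_matrix: pd.DataFrame | None = None
    gene_sets: dict[str, list[str]] | None = None
    cq: pd.DataFrame | None = None
    annotations: pd.DataFrame | None = None
    mapping: dict[str, str] | None = None
    utr: str | None = None
    mirna_seqs: dict[str, str] | None = None
    induction_a: pd.DataFrame | None = None
    induction_b: pd.DataFrame | None = None
    signature: list[tuple[str, int]] | None = None


def _spearman_rank_matrix(
    mirna_matrix: pd.DataFrame, mrna_matrix: pd.DataFrame
) -> pd.DataFrame:
    """All-pairs Spearman coefficients (genes x miRNAs), vectorized.

    Identical to per-pair ``scipy.stats.spearmanr`` (Pearson on average
    ranks); constant rows get coefficient 0.
    """
    samples = [s for s in mrna_matrix.columns if s in mirna_matrix.columns]
    if len(samples) < 4:
        raise ValueError("need >=4 shared samples")

    def standardized_ranks(mat: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        x = mat[samples].to_numpy(dtype=float)
        r = np.apply_along_axis(rankdata, 1, x)
        r = r - r.mean(axis=1, keepdims=True)
        norm = np.sqrt((r**2).sum(axis=1))
        ok = norm > 0
        r[ok] = r[ok] / norm[ok][:, None]
        r[~ok] = 0.0
        return r, ok

    rg, _ = standardized_ranks(mrna_matrix)
    rm, _ = standardized_ranks(mirna_matrix)
    return pd.DataFrame(
        rg @ rm.T, index=mrna_matrix.index, columns=mirna_matrix.index
    )


def gsea_all_mirnas(
    mirna_matrix: pd.DataFrame,
    mrna_matrix: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    n_permutations: int = 500,
    seed: int = 0,
    nes_threshold: float = 2.0,
    fdr_threshold: float = 0.25,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Preranked GSEA of every gene set against every miRNA's ranked list.

    Per miRNA, genes are ranked by decreasing Spearman correlation with
    the miRNA (ties broken lexicographically) and all gene sets are
    scored; random-set null ES values are shared across gene sets of the
    same size within a miRNA (one seeded draw block per miRNA x size).
    Returns the result table and the per-miRNA activity call.
    """
    corr = _spearman_rank_matrix(mirna_matrix, mrna_matrix)
    gene_index = mrna_matrix.index
    rows = []
    calls: dict[str, str] = {}
    for mi, mirna in enumerate(mirna_matrix.index):
        c = corr[mirna]
        order = sorted(gene_index, key=lambda g: (-c[g], g))
        statvals = c.loc[order].to_numpy(dtype=float)
        genes = np.asarray(order)
        n = genes.size
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, mi])
        )
        null_cache: dict[int, np.ndarray] = {}
        results = []
        for name, members in gene_sets.items():
            mem = set(members)
            in_set = np.fromiter((g in mem for g in genes), dtype=bool, count=n)
            nh = int(in_set.sum())
            if nh == 0 or nh == n:
                continue
            es = expr._running_es(statvals, in_set)
            if nh not in null_cache:
                null_cache[nh] = _batch_null_es(statvals, nh, n_permutations, rng)
            null_es = null_cache[nh]
            same = null_es >= 0 if es >= 0 else null_es < 0
            n_same = int(same.sum())
            if n_same == 0:
                mean_abs = float(np.mean(np.abs(null_es))) or np.nan
                nes, p, fdr = es / mean_abs, 1.0 / n_permutations, 1.0 / n_permutations
            else:
                mean_abs = float(np.mean(np.abs(null_es[same])))
                nes = es / mean_abs if mean_abs > 0 else np.nan
                p = float((np.abs(null_es[same]) >= abs(es)).sum()) / n_same
                fdr = p
            results.append(
                expr.GseaResult(
                    name, es, float(nes), min(p, 1.0), min(fdr, 1.0),
                    n_permutations, seed, nh, mirna,
                )
            )
        for r in results:
            rows.append(asdict(r))
        if results:
            calls[mirna] = expr.classify_activity_relation(
                results, nes_threshold, fdr_threshold
            )["call"]
        else:
            calls[mirna] = "no-data"
    table = pd.DataFrame(rows)
    return table, calls


def _batch_null_es(
    statvals: np.ndarray, nh: int, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized random-gene-set null ES values (same scoring kernel)."""
    n = statvals.size
    u = rng.random((n_permutations, n))
    idx = np.argpartition(u, nh - 1, axis=1)[:, :nh]
    mask = np.zeros((n_permutations, n), dtype=bool)
    np.put_along_axis(mask, idx, True, axis=1)
    w = np.abs(statvals)[None, :] * mask
    totals = w.sum(axis=1)
    hit = np.where(
        totals[:, None] > 0, w / np.where(totals == 0, 1, totals)[:, None],
        mask / nh,
    )
    steps = np.where(mask, hit, -1.0 / (n - nh))
    run = np.cumsum(steps, axis=1)
    pick = np.argmax(np.abs(np.round(run, 12)), axis=1)
    return run[np.arange(n_permutations), pick]


@dataclass
class IntegrationSummary:
    """Counts at each pipeline stage (the integration flowchart)."""

    screened: int
    hits: int
    with_expression_data: int
    relevant: int
    mycn_induced: int
    conflicting: int
    not_supported: int
    no_data: int
    mouse_down: int | None = None
    mouse_up: int | None = None
    induction_down: int | None = None
    induction_up: int | None = None

    def __post_init__(self):
        if self.hits > self.screened:
            raise ValueError("hits cannot exceed screened")
        parts = (
            self.relevant + self.mycn_induced + self.conflicting
            + self.not_supported + self.no_data
        )
        if parts != self.hits:
            raise ValueError(
                f"relevance categories ({parts}) must partition hits ({self.hits})"
            )


def run_pipeline(
    inputs: PipelineInputs, config: PipelineConfig | None = None
) -> dict:
    """Run all configured stages and assemble the integration summary.

    Returns a dict with the ``summary`` (:class:`IntegrationSummary`)
    and every stage's output table.  Stages without inputs are skipped
    and marked not run.
    """
    config = config or PipelineConfig()
    out: dict = {"config": config}

    # --- screen scoring -------------------------------------------------
    try:
        scores = scr.score_screens(
            inputs.plates, config.focal_screen, cutoff=config.cutoff
        )
    except Exception as e:  # noqa: BLE001 - stage tagging
        raise StageError("screen_scoring", str(e)) from e
    hits = sorted(scores.index[scores["hit"]])
    out["scores"] = scores
    out["hits"] = hits

    # --- seed-match analysis (optional) ---------------------------------
    if inputs.utr is not None and inputs.mirna_seqs:
        try:
            classes = {
                m: seedmod.best_seed_class(
                    seedmod.find_seed_matches(inputs.utr, s, m)
                )
                for m, s in inputs.mirna_seqs.items()
            }
            out["seed_classes"] = classes
            out["seed_enrichment"] = seedmod.seed_class_enrichment(
                scores["score_avg"].to_dict(), classes
            )
        except Exception as e:  # noqa: BLE001
            raise StageError("seed_analysis", str(e)) from e

    # --- expression integration (optional) ------------------------------
    expr_calls: dict[str, str] = {}
    activity_calls: dict[str, str] = {}
    if inputs.mirna_matrix is not None and inputs.mrna_matrix is not None:
        try:
            if "MYCN" not in inputs.mrna_matrix.index:
                raise ValueError("mRNA matrix lacks a MYCN row")
            corr_table = expr.correlate_to_mycn(
                inputs.mirna_matrix,
                inputs.mrna_matrix.loc["MYCN"],
                method=config.correlation_method,
                q_threshold=config.q_threshold,
            )
            out["correlation"] = corr_table
            expr_calls = corr_table["call"].to_dict()
            if inputs.gene_sets:
                gsea_table, activity_calls = gsea_all_mirnas(
                    inputs.mirna_matrix,
                    inputs.mrna_matrix,
                    inputs.gene_sets,
                    n_permutations=config.gsea_permutations,
                    seed=config.gsea_seed,
                    nes_threshold=config.nes_threshold,
                    fdr_threshold=config.fdr_threshold,
                )
                out["gsea"] = gsea_table
                out["activity_calls"] = activity_calls
                # contingency: negative enrichment among hits vs others
                hit_set = set(hits)
                neg_hit = sum(
                    1 for m, c in activity_calls.items()
                    if m in hit_set and c == "negative"
                )
                neg_other = sum(
                    1 for m, c in activity_calls.items()
                    if m not in hit_set and c == "negative"
                )
                n_hit = sum(1 for m in activity_calls if m in hit_set)
                n_other = len(activity_calls) - n_hit
                table = [
                    [neg_hit, n_hit - neg_hit],
                    [neg_other, n_other - neg_other],
                ]
                try:
                    stat, p = expr.chi_square_2x2(table)
                    out["enrichment_contingency"] = {
                        "table": table, "statistic": stat, "p": p,
                    }
                except ValueError:
                    out["enrichment_contingency"] = {"table": table}
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("expression_integration", str(e)) from e

    relevance = expr.classify_relevance(hits, expr_calls, activity_calls)
    out["relevance"] = relevance
    finals = pd.Series({r.mirna_id: r.final for r in relevance})
    relevant = sorted(finals.index[finals == "relevant"])
    induced = sorted(finals.index[finals == "mycn-induced"])

    # --- murine progression (optional) ----------------------------------
    mouse_down = mouse_up = None
    if inputs.cq is not None and inputs.annotations is not None:
        try:
            norm = prog.preprocess_cq(inputs.cq)
            if inputs.mapping:
                norm = norm.rename(index=inputs.mapping)
            records = prog.fit_genotype_time_regression(
                norm, inputs.annotations, q_threshold=config.q_threshold
            )
            out["progression"] = records
            rel_in = [m for m in relevant if m in records.index]
            mouse_down = int((records.loc[rel_in, "call"] == "down").sum())
            ind_in = [m for m in induced if m in records.index]
            mouse_up = int((records.loc[ind_in, "call"] == "up").sum())
            testable = records[records["testable"]]
            flags = pd.Series(
                [m in set(relevant) for m in testable.index], index=testable.index
            )
            if flags.any() and (~flags).any():
                out["dynamics_ks"] = prog.compare_target_vs_nontarget_dynamics(
                    testable["pi_value"], flags
                )
            if inputs.signature:
                out["signature"] = prog.signature_score(norm, inputs.signature)
        except Exception as e:  # noqa: BLE001
            raise StageError("progression_dynamics", str(e)) from e

    # --- induction model (optional) -------------------------------------
    induction_down = induction_up = None
    if inputs.induction_a is not None and inputs.induction_b is not None:
        try:
            de = prog.differential_expression(
                inputs.induction_a, inputs.induction_b,
                equal_var=config.equal_var, q_threshold=config.q_threshold,
            )
            out["induction"] = de
            rel_in = [m for m in relevant if m in de.index]
            induction_down = int((de.loc[rel_in, "call"] == "down").sum())
            ind_in = [m for m in induced if m in de.index]
            induction_up = int((de.loc[ind_in, "call"] == "up").sum())
        except Exception as e:  # noqa: BLE001
            raise StageError("induction_model", str(e)) from e

    screened = int(scores.index.nunique())
    counts = finals.value_counts() if len(finals) else pd.Series(dtype=int)
    out["summary"] = IntegrationSummary(
        screened=screened,
        hits=len(hits),
        with_expression_data=len(hits) - int(counts.get("no-data", 0)),
        relevant=len(relevant),
        mycn_induced=len(induced),
        conflicting=int(counts.get("conflicting-excluded", 0)),
        not_supported=int(counts.get("not-supported", 0)),
        no_data=int(counts.get("no-data", 0)),
        mouse_down=mouse_down,
        mouse_up=mouse_up,
        induction_down=induction_down,
        induction_up=induction_up,
    )
    return out


def write_report(outputs: dict, out_dir, seed: int | None = None) -> list[str]:
    """Write all stage outputs as TSV/JSON under ``out_dir``.

    Every file carries a header comment with version, config hash and
    seed; optional stages that did not run are marked as such in the
    summary JSON.  Returns the list of files written.
    """
    from pathlib import Path

    from . import io as mio

    if not any(k in outputs for k in ("scores", "progression", "induction")):
        raise ValueError("no stage outputs to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = outputs.get("config")
    chash = mio.config_hash(asdict(config)) if config is not None else "none"
    header = f"mirmycn {VERSION} | config {chash} | seed {seed}"
    written = []

    def emit(df: pd.DataFrame, name: str):
        path = out_dir / name
        mio.write_matrix(df, path, header=header)
        written.append(str(path))

    if "scores" in outputs:
        emit(outputs["scores"], "interaction_scores.tsv")
    if "correlation" in outputs:
        emit(outputs["correlation"], "mycn_correlation.tsv")
    if "gsea" in outputs and len(outputs["gsea"]):
        emit(outputs["gsea"].set_index("mirna_id"), "gsea_results.tsv")
    if "progression" in outputs:
        emit(outputs["progression"], "progression_records.tsv")
    if "induction" in outputs:
        emit(outputs["induction"], "induction_diffexpr.tsv")
    if "signature" in outputs:
        emit(outputs["signature"], "signature_scores.tsv")
    if "relevance" in outputs:
        emit(
            pd.DataFrame([asdict(r) for r in outputs["relevance"]]).set_index(
                "mirna_id"
            ),
            "relevance_calls.tsv",
        )

    summary = outputs.get("summary")
    payload = asdict(summary) if summary is not None else {}
    for key, label in [
        ("mouse_down", "progression"),
        ("induction_down", "induction"),
    ]:
        if payload.get(key) is None:
            payload.setdefault("stages_not_run", []).append(label)
    path = out_dir / "integration_summary.json"
    mio.write_json(
        payload, path, version=VERSION, config_hash=chash, seed=seed
    )
    written.append(str(path))
    return written
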