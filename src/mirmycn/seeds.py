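"""miRNA seed-match scanning of a 3'UTR and seed-class score enrichment.

Canonical site taxonomy: the seed is miRNA nucleotides 2-7 (6mer) or 2-8
(extended).  A UTR site is the Watson-Crick reverse complement of the
seed, optionally with an adenosine in the UTR opposite miRNA position 1:

- 6mer     : match to nt 2-7
- 7mer-m8  : match to nt 2-8
- 7mer-A1  : match to nt 2-7 with an A opposite nt 1
- 8mer     : match to nt 2-8 with an A opposite nt 1

Reported site types collapse the two 7mer variants into "7mer"; each site
is reported once with its longest applicable type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import kolmogorov
from scipy.stats import ks_2samp

#: numerical floor for asymptotic p-values
P_FLOOR = 2.2e-16

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G", "N": "N"}
SITE_TYPES = ("6mer", "7mer", "8mer")


@dataclass(frozen=True)
class SeedSite:
    """A single seed-match site on the UTR (1-based coordinates)."""

    mirna_id: str
    utr_start: int
    site_type: str        # 6mer / 7mer / 8mer
    site_sequence: str
    subtype: str = ""     # 7mer-m8 / 7mer-A1 for the 7mer class


@dataclass(frozen=True)
class KsResult:
    """Two-sample Kolmogorov-Smirnov comparison."""

    statistic: float
    p_value: float
    n_a: int
    n_b: int


def _normalize_rna(seq: str, what: str) -> str:
    s = str(seq).upper().replace("T", "U")
    bad = set(s) - set("ACGUN")
    if bad:
        raise ValueError(f"invalid characters in {what}: {sorted(bad)}")
    if not s:
        raise ValueError(f"{what} sequence is empty")
    return s


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def find_seed_matches(utr: str, mirna: str, mirna_id: str = "") -> list[SeedSite]:
    """Scan a 3'UTR (5'->3') for seed-match sites of one mature miRNA.

    Overlapping sites are allowed; each match of the 6mer core is reported
    once, upgraded to 7mer/8mer where the flanking positions qualify.
    """
    u = _normalize_rna(utr, "UTR")
    m = _normalize_rna(mirna, "miRNA")
    if len(m) < 8:
        raise ValueError(f"mature miRNA must be >=8 nt, got {len(m)}")
    core6 = _revcomp(m[1:7])          # match to seed nt 2-7
    m8_base = _COMPLEMENT[m[7]]       # UTR base pairing miRNA nt 8
    sites: list[SeedSite] = []
    start = u.find(core6)
    while start != -1:
        has_m8 = start > 0 and u[start - 1] == m8_base
        has_a1 = start + 6 < len(u) and u[start + 6] == "A"
        if has_m8 and has_a1:
            stype, sub, s0, length = "8mer", "", start - 1, 8
        elif has_m8:
            stype, sub, s0, length = "7mer", "7mer-m8", start - 1, 7
        elif has_a1:
            stype, sub, s0, length = "7mer", "7mer-A1", start, 7
        else:
            stype, sub, s0, length = "6mer", "", start, 6
        sites.append(
            SeedSite(mirna_id, s0 + 1, stype, u[s0:s0 + length], sub)
        )
        start = u.find(core6, start + 1)
    return sites


def best_seed_class(sites: list[SeedSite]) -> str:
    """Longest site type present, or "none" when there are no sites."""
    if not sites:
        return "none"
    return max(sites, key=lambda s: SITE_TYPES.index(s.site_type)).site_type


def ks_two_sample(group_a, group_b) -> KsResult:
    """Two-sample KS test with an asymptotic p-value.

    D is the supremum ECDF distance; the p-value comes from the Kolmogorov
    distribution at effective size n_a*n_b/(n_a+n_b), with the Stephens
    small-sample refinement of the argument, floored at 2.2e-16.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >=2 finite values")
    d = float(ks_2samp(a, b).statistic)
    en = a.size * b.size / (a.size + b.size)
    arg = (np.sqrt(en) + 0.12 + 0.11 / np.sqrt(en)) * d
    p = float(np.clip(kolmogorov(arg), P_FLOOR, 1.0))
    return KsResult(d, p, int(a.size), int(b.size))


def seed_class_enrichment(
    scores: dict[str, float] | "pd.Series",
    classes: dict[str, str],
) -> dict:
    """Compare interaction scores of each seed class to the no-site group.

    ``classes`` maps miRNA id to its best seed class ("6mer"/"7mer"/
    "8mer"/"none").  Returns per-class KS results against the "none"
    group (``None`` where a class is empty / not testable) and ECDF
    tables for plotting cumulative distributions.
    """
    import pandas as pd

    s = pd.Series(dict(scores), dtype=float)
    groups = {c: [] for c in ("none",) + SITE_TYPES}
    for mirna, score in s.items():
        groups.setdefault(classes.get(mirna, "none"), []).append(score)

    ecdfs = {}
    for cls, vals in groups.items():
        if vals:
            x = np.sort(np.asarray(vals, dtype=float))
            ecdfs[cls] = pd.DataFrame(
                {"score": x, "ecdf": np.arange(1, x.size + 1) / x.size}
            )

    results: dict[str, KsResult | None] = {}
    none_scores = groups["none"]
    for cls in SITE_TYPES:
        vals = groups[cls]
        if len(vals) < 2 or len(none_scores) < 2:
            results[cls] = None
        else:
            results[cls] = ks_two_sample(vals, none_scores)
    return {"ks": results, "ecdf": ecdfs, "group_sizes": {c: len(v) for c, v in groups.items()}}
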