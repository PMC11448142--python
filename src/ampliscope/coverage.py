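"""Per-group primer and primer-pair coverage, and primer categorisation.

Coverage of a primer for a group is the fraction of that group's sequences
carrying at least one qualifying binding site (3'-intact, mismatch count at
or below the threshold); it is reported at mismatch thresholds 0-3.  The
denominator is every sequence of the group in the chosen database variant,
including entries too truncated to contain the site -- which is exactly why
edge primers (binding within the terminal 60 bp of the gene) are evaluated
against the full-length-only variant.

Specificity is read off the same table as the coverage of non-target
groups.  ``categorize_primer`` turns the four group fractions at the
>=3-mismatch threshold into one of the categories used for degenerate
Cu-mmoA primer panels: general Cu-mmoA, general comammox, clade A- or
clade B-specific, or phylotype-specific.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import pandas as pd

from .amplicon import DEFAULT_MAX_PRODUCT_LEN, predict_amplicons
from .binding import SearchParams, find_binding_sites
from .refdb import GROUPS, PairSpec, Primer, ReferenceDB

__all__ = [
    "COVERAGE_COLUMNS",
    "primer_coverage",
    "pair_coverage",
    "coverage_matrix",
    "categorize_primer",
]

COVERAGE_COLUMNS = [
    "primer_or_pair", "group", "mm_threshold",
    "n_group", "n_covered", "fraction", "db_variant",
]

DEFAULT_THRESHOLDS = (0, 1, 2, 3)


def _rows_from_min_mm(
    name: str,
    per_group_min_mm: dict[str, list[Optional[int]]],
    thresholds: Sequence[int],
    db_variant: str,
) -> pd.DataFrame:
    rows = []
    for group in GROUPS:
        mms = per_group_min_mm.get(group)
        if not mms:  # groups with no sequences are omitted
            continue
        n_group = len(mms)
        for t in thresholds:
            n_cov = sum(1 for m in mms if m is not None and m <= t)
            rows.append(
                {
                    "primer_or_pair": name,
                    "group": group,
                    "mm_threshold": t,
                    "n_group": n_group,
                    "n_covered": n_cov,
                    "fraction": n_cov / n_group,
                    "db_variant": db_variant,
                }
            )
    return pd.DataFrame(rows, columns=COVERAGE_COLUMNS)


def primer_coverage(
    db: ReferenceDB,
    primer: Primer,
    params: SearchParams = SearchParams(),
    mm_thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    full_length_db: Optional[ReferenceDB] = None,
) -> pd.DataFrame:
    """Coverage table of one primer per group and mismatch threshold.

    A sequence counts as covered at threshold ``t`` iff it has at least one
    qualifying site with ``mm_count <= t``.  Edge primers are evaluated
    against ``full_length_db`` (the full-length-only variant), which must
    then be provided.
    """
    if primer.edge_primer:
        if full_length_db is None:
            raise ValueError(
                f"primer {primer.name} is an edge primer: a full-length-only "
                "database variant is required"
            )
        use_db, variant = full_length_db, "full_length_only"
    else:
        use_db, variant = db, "full"
    if len(use_db) == 0:
        raise ValueError("empty reference database")

    per_group: dict[str, list[Optional[int]]] = {}
    for rec in use_db:
        sites = find_binding_sites(primer, rec, params)
        best = min((s.mm_count for s in sites), default=None)
        per_group.setdefault(rec.group, []).append(best)
    return _rows_from_min_mm(primer.name, per_group, mm_thresholds, variant)


def pair_coverage(
    db: ReferenceDB,
    pair: PairSpec,
    primers: dict[str, Primer],
    params: SearchParams = SearchParams(),
    mm_thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    max_product_len: int = DEFAULT_MAX_PRODUCT_LEN,
) -> pd.DataFrame:
    """Coverage of a primer pair: a sequence is covered at threshold ``t``
    iff it yields at least one predicted amplicon whose forward and reverse
    sites each have ``mm_count <= t``.  A template with several qualifying
    amplicons still counts once."""
    if len(db) == 0:
        raise ValueError("empty reference database")
    per_group: dict[str, list[Optional[int]]] = {}
    for rec in db:
        amps = predict_amplicons(pair, rec, primers, params, max_product_len)
        best = min(
            (max(a.forward_site.mm_count, a.reverse_site.mm_count) for a in amps),
            default=None,
        )
        per_group.setdefault(rec.group, []).append(best)
    return _rows_from_min_mm(pair.name, per_group, mm_thresholds, "full")


def coverage_matrix(table: pd.DataFrame, mm_threshold: int = 3) -> pd.DataFrame:
    """Wide primer x group fraction matrix at one mismatch threshold."""
    sub = table[table["mm_threshold"] == mm_threshold]
    return sub.pivot(index="primer_or_pair", columns="group", values="fraction")


def categorize_primer(
    coverage_rows: pd.DataFrame,
    target_high: float = 0.7,
    off_target_low: float = 0.1,
    mm_threshold: int = 3,
) -> tuple[str, dict[str, float]]:
    """Deterministic category from the four group fractions at
    ``mm_threshold``.

    Rules (first match wins), with ``hi = target_high``, ``lo =
    off_target_low``:

    * both clades and at least one non-comammox group >= hi -> cu_mmo_general
    * both clades >= hi, non-comammox groups < lo       -> comammox_general
    * one clade >= hi, everything else < lo             -> cladeA / cladeB
    * some clade coverage below hi, everything else < lo -> phylotype
    * otherwise -> unclassified
    """
    sub = coverage_rows[coverage_rows["mm_threshold"] == mm_threshold]
    frac = {g: None for g in GROUPS}
    for _, row in sub.iterrows():
        frac[row["group"]] = row["fraction"]
    missing = [g for g, v in frac.items() if v is None]
    if missing:
        raise ValueError(f"missing coverage rows for groups: {missing}")
    a, b = frac["cladeA"], frac["cladeB"]
    aob, oth = frac["AOB"], frac["other_cu_mmo"]
    hi, lo = target_high, off_target_low

    if a >= hi and b >= hi and (aob >= hi or oth >= hi):
        cat = "cu_mmo_general"
    elif a >= hi and b >= hi and aob < lo and oth < lo:
        cat = "comammox_general"
    elif a >= hi and b < lo and aob < lo and oth < lo:
        cat = "cladeA"
    elif b >= hi and a < lo and aob < lo and oth < lo:
        cat = "cladeB"
    elif (0 < a < hi or 0 < b < hi) and aob < lo and oth < lo:
        cat = "phylotype"
    else:
        cat = "unclassified"
    return cat, {g: float(v) for g, v in frac.items()}
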