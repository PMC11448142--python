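"""ASV affiliation against a reference database and community summaries.

Amplicon sequence variants (ASVs) are compared to the labelled reference
set by local (Smith-Waterman, affine-gap) alignment and affiliated to their
highest-bitscore reference using fixed identity/coverage thresholds:

* best hit covering < 33% of the expected amplicon length (or no hit at
  all) -> ``unaligned``;
* coverage >= 66% and nucleotide identity >= 75% -> the reference group
  (cladeA / cladeB / AOB / other_cu_mmo);
* additionally identity >= 90% (at >= 66% coverage) -> the ASV is also
  *aggregated* to that genomic reference, pooling read counts of near-
  identical variants;
* anything in between (coverage in [33%, 66%) or identity < 75%) ->
  ``unknown``.

"Expected amplicon length" is the assay product length minus the two primer
footprints, because reads are primer-trimmed before denoising.  Community
summaries include per-sample relative abundances by category and the
clade A : clade B read ratio, the headline statistic for comparing how
comammox-targeting primer pairs skew the apparent community.

Scoring mimics common nucleotide-BLAST defaults (match +2, mismatch -3,
gap open 5, gap extend 2; bitscore = (lambda*S - ln K)/ln 2 with
lambda = 0.625, K = 0.41) but identity/coverage threshold semantics, not
score parity with any particular aligner, are the contract.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .refdb import ReferenceDB

__all__ = [
    "Scoring",
    "Thresholds",
    "AlignmentHit",
    "AffiliationResult",
    "local_align",
    "classify_asv",
    "classify_all",
    "clade_ratio",
    "summarize_groups",
]


@dataclass(frozen=True)
class Scoring:
    """Local-alignment scoring.  Gap costs follow the BLAST convention:
    a gap of length k costs ``gap_open + gap_extend * k``."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    lam: float = 0.625
    K: float = 0.41

    def bitscore(self, score: float) -> float:
        return (self.lam * score - math.log(self.K)) / math.log(2)

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.match_score = self.match
        a.mismatch_score = self.mismatch
        # Biopython charges open_gap_score for the first gapped position,
        # so open+extend here reproduces gap_open + k*gap_extend
        a.open_gap_score = -(self.gap_open + self.gap_extend)
        a.extend_gap_score = -self.gap_extend
        return a


@dataclass(frozen=True)
class Thresholds:
    """Affiliation/aggregation cutoffs as fractions."""

    affil_id: float = 0.75
    affil_cov: float = 0.66
    unaligned_cov: float = 0.33
    aggregate_id: float = 0.90
    aggregate_cov: float = 0.66


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    identity: float       # matches / alignment columns, in [0, 1]
    align_len: int        # alignment columns including gaps
    score: int
    bitscore: float
    query_cover_fraction: float  # align_len / expected amplicon length


@dataclass(frozen=True)
class AffiliationResult:
    asv_id: str
    category: str  # cladeA | cladeB | AOB | other_cu_mmo | unknown | unaligned
    best_ref: Optional[str]
    identity: float
    cover_fraction: float
    bitscore: float
    aggregated_ref: Optional[str]


def local_align(
    query_id: str,
    query: str,
    subject_id: str,
    subject: str,
    scoring: Scoring = Scoring(),
    expected_len: Optional[int] = None,
    _aligner: Optional[Align.PairwiseAligner] = None,
) -> AlignmentHit:
    """Best local alignment of ``query`` against ``subject``.

    Identity is matches over alignment columns (gap columns included);
    coverage is alignment columns over ``expected_len`` (defaults to the
    query length)."""
    if not query or not subject:
        raise ValueError("empty sequence")
    aligner = _aligner or scoring.aligner()
    alignments = aligner.align(query.upper(), subject.upper())
    expected = expected_len if expected_len is not None else len(query)
    try:
        aln = alignments[0]
    except IndexError:
        return AlignmentHit(query_id, subject_id, 0.0, 0, 0, scoring.bitscore(0), 0.0)
    counts = aln.counts()
    align_len = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / align_len if align_len else 0.0
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        identity=identity,
        align_len=int(align_len),
        score=int(aln.score),
        bitscore=scoring.bitscore(aln.score),
        query_cover_fraction=align_len / expected if expected else 0.0,
    )


def classify_asv(
    asv_id: str,
    asv_seq: str,
    refdb: ReferenceDB,
    expected_len: int,
    thresholds: Thresholds = Thresholds(),
    scoring: Scoring = Scoring(),
) -> AffiliationResult:
    """Affiliate one ASV to its best reference hit.

    References are ranked by bitscore, ties broken by higher identity and
    then lexicographically smaller reference id, so runs are reproducible.
    """
    if len(refdb) == 0:
        raise ValueError("empty reference database")
    if expected_len <= 0:
        raise ValueError("expected_len must be positive")
    aligner = scoring.aligner()
    hits = [
        local_align(asv_id, asv_seq, rec.id, rec.sequence, scoring,
                    expected_len=expected_len, _aligner=aligner)
        for rec in refdb
    ]
    best = max(hits, key=lambda h: (h.bitscore, h.identity, _NegStr(h.subject_id)))
    t = thresholds
    if best.align_len == 0 or best.query_cover_fraction < t.unaligned_cov:
        return AffiliationResult(asv_id, "unaligned", None, 0.0, 0.0, 0.0, None)
    if best.query_cover_fraction >= t.affil_cov and best.identity >= t.affil_id:
        category = refdb.get(best.subject_id).group
        aggregated = (
            best.subject_id
            if best.identity >= t.aggregate_id
            and best.query_cover_fraction >= t.aggregate_cov
            else None
        )
        return AffiliationResult(
            asv_id, category, best.subject_id, best.identity,
            best.query_cover_fraction, best.bitscore, aggregated,
        )
    return AffiliationResult(
        asv_id, "unknown", best.subject_id, best.identity,
        best.query_cover_fraction, best.bitscore, None,
    )


class _NegStr(str):
    """Reverses string ordering so smaller ids win under max()."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):  # pragma: no cover - trivial
        return str.__lt__(self, other)


def classify_all(
    asvs: Iterable[tuple[str, str]],
    refdb: ReferenceDB,
    expected_len: int,
    thresholds: Thresholds = Thresholds(),
    scoring: Scoring = Scoring(),
) -> pd.DataFrame:
    """Classify (asv_id, sequence) pairs; returns a long-format table."""
    results = [
        classify_asv(aid, seq, refdb, expected_len, thresholds, scoring)
        for aid, seq in asvs
    ]
    return pd.DataFrame(
        [
            {
                "asv_id": r.asv_id,
                "category": r.category,
                "best_ref": r.best_ref,
                "identity": r.identity,
                "cover_fraction": r.cover_fraction,
                "bitscore": r.bitscore,
                "aggregated_ref": r.aggregated_ref,
            }
            for r in results
        ],
        columns=[
            "asv_id", "category", "best_ref", "identity",
            "cover_fraction", "bitscore", "aggregated_ref",
        ],
    )


def _join_categories(abundance: pd.DataFrame, affiliations: pd.DataFrame) -> pd.DataFrame:
    cats = affiliations.set_index("asv_id")["category"]
    out = abundance.copy()
    out["category"] = out["asv_id"].map(cats)
    missing = out["category"].isna()
    if missing.any():
        bad = sorted(out.loc[missing, "asv_id"].unique())
        raise ValueError(f"ASVs without affiliation: {bad}")
    return out


def clade_ratio(
    abundance: pd.DataFrame, affiliations: pd.DataFrame
) -> tuple[pd.Series, float]:
    """Per-sample clade A : clade B read ratio and its arithmetic mean.

    ``abundance`` has columns (sample_id, asv_id, read_count).  Samples with
    zero clade B reads get an infinite ratio and are excluded from the mean
    with a warning.
    """
    joined = _join_categories(abundance, affiliations)
    ratios = {}
    for sample, grp in joined.groupby("sample_id", sort=True):
        a = grp.loc[grp["category"] == "cladeA", "read_count"].sum()
        b = grp.loc[grp["category"] == "cladeB", "read_count"].sum()
        ratios[sample] = a / b if b > 0 else math.inf
    series = pd.Series(ratios, name="cladeA_to_cladeB")
    finite = series[np.isfinite(series)]
    if len(finite) < len(series):
        warnings.warn(
            f"{len(series) - len(finite)} sample(s) with zero clade B reads "
            "excluded from the mean ratio"
        )
    mean = float(finite.mean()) if len(finite) else math.nan
    return series, mean


def summarize_groups(
    abundance: pd.DataFrame, affiliations: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample relative read abundance by category (rows sum to 1) and
    unique-ASV counts per category."""
    joined = _join_categories(abundance, affiliations)
    totals = joined.groupby("sample_id")["read_count"].sum()
    rel = (
        joined.groupby(["sample_id", "category"])["read_count"].sum()
        .unstack(fill_value=0)
        .div(totals, axis=0)
    )
    asv_counts = affiliations.groupby("category")["asv_id"].nunique()
    return rel, asv_counts
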