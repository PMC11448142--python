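"""Degenerate-primer binding-site search.

The engine scans a primer (written 5'->3' in IUPAC nucleotide code) along a
template sequence without gaps and reports every placement that satisfies
three rules commonly used for in-silico PCR evaluation of functional marker
primers:

1. the on-template (aligned) length is at least ``min_match_len`` bases
   (default 11 bp);
2. the number of primer-template mismatches does not exceed ``max_mm``
   (default 3);
3. the primer's terminal ``min_3prime_consecutive`` 3' positions (default 2)
   all lie on the template and match it -- mismatches at the extension end
   of a primer abolish amplification far more strongly than internal ones,
   so sites failing this rule are not reported at all.

A primer base matches a template base when their IUPAC expansion sets
intersect (R = {A,G} matches A, G, R, D, ...).  Forward primers are compared
directly against the sense strand; reverse primers are reverse-complemented
first, but mismatch positions are always reported in the primer's own
coordinates counted from the 3' end (1 = terminal 3' base), because all
rules are 3'-anchored.

Coordinates are 0-based half-open on the sense strand throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "IUPAC_SETS",
    "IUPAC_COMPLEMENT",
    "SearchParams",
    "BindingSite",
    "base_compatible",
    "reverse_complement",
    "find_binding_sites",
    "best_site",
    "min_mismatch",
]

# IUPAC nucleotide one-letter codes and their expansion sets.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

# Bitmask encoding: one bit per concrete base; two codes are compatible iff
# their masks intersect.
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_MASK: dict[str, int] = {
    code: sum(_BASE_BIT[b] for b in bases) for code, bases in IUPAC_SETS.items()
}


def _validate(seq: str, what: str = "sequence") -> None:
    for pos, ch in enumerate(seq):
        if ch not in IUPAC_SETS:
            raise ValueError(
                f"non-IUPAC character {ch!r} at position {pos} in {what}"
            )


def base_compatible(primer_base: str, template_base: str) -> bool:
    """True iff the IUPAC expansion sets of the two codes intersect."""
    try:
        pm = _MASK[primer_base]
    except KeyError:
        raise ValueError(f"non-IUPAC character {primer_base!r} at position 0 in primer base") from None
    try:
        tm = _MASK[template_base]
    except KeyError:
        raise ValueError(f"non-IUPAC character {template_base!r} at position 0 in template base") from None
    return bool(pm & tm)


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string (ambiguity-aware)."""
    _validate(seq)
    return "".join(IUPAC_COMPLEMENT[ch] for ch in reversed(seq))


@dataclass(frozen=True)
class SearchParams:
    """Binding-site qualification rules.

    min_match_len
        minimum on-template aligned length in bp (default 11).
    max_mm
        maximum tolerated mismatches (default 3).
    min_3prime_consecutive
        number of terminal 3' primer positions that must be on-template
        matches (default 2).
    allow_5prime_overhang
        permit the primer 5' end to hang over the template edge; overhanging
        positions neither match nor mismatch and do not count toward the
        aligned length.  The 3' end may never overhang.
    max_sites_per_template
        cap on reported sites per template (None = unlimited).
    strict_template
        when True, ambiguity codes in the template are counted as mismatches
        instead of being resolved by set intersection.
    """

    min_match_len: int = 11
    max_mm: int = 3
    min_3prime_consecutive: int = 2
    allow_5prime_overhang: bool = True
    max_sites_per_template: Optional[int] = None
    strict_template: bool = False

    def __post_init__(self) -> None:
        if not (self.min_match_len >= self.min_3prime_consecutive >= 1):
            raise ValueError(
                "require min_match_len >= min_3prime_consecutive >= 1, got "
                f"{self.min_match_len} / {self.min_3prime_consecutive}"
            )
        if self.max_mm < 0:
            raise ValueError("max_mm must be >= 0")


@dataclass(frozen=True)
class BindingSite:
    """One qualifying primer placement on one template.

    ``start``/``end`` are 0-based half-open sense-strand coordinates of the
    on-template footprint; ``mm_positions`` are primer positions counted from
    the 3' end (1 = terminal 3' base), sorted ascending.
    """

    ref_id: str
    primer_name: str
    strand: str  # '+' forward primer, '-' reverse primer
    start: int
    end: int
    aligned_len: int
    mm_count: int
    mm_positions: tuple[int, ...]
    three_prime_intact: bool

    def __post_init__(self) -> None:
        assert self.end - self.start == self.aligned_len
        assert self.mm_count == len(self.mm_positions)


def _seq_and_name(obj, default_name: str) -> tuple[str, str]:
    if isinstance(obj, str):
        return obj, default_name
    seq = getattr(obj, "sequence")
    name = getattr(obj, "name", None) or getattr(obj, "id", default_name)
    return seq, name


def _orientation(primer) -> str:
    return getattr(primer, "orientation", "forward")


def _encode(seq: str, strict: bool) -> np.ndarray:
    if strict:
        # ambiguous template bases never match anything
        return np.array(
            [_MASK[ch] if ch in _BASE_BIT else 0 for ch in seq], dtype=np.uint8
        )
    return np.array([_MASK[ch] for ch in seq], dtype=np.uint8)


def find_binding_sites(primer, template, params: SearchParams = SearchParams()):
    """Ungapped scan of every placement of ``primer`` on ``template``.

    ``primer`` is a :class:`~ampliscope.refdb.Primer` (or a plain string,
    treated as a forward primer); ``template`` is a
    :class:`~ampliscope.refdb.ReferenceRecord` or plain string (the sense
    strand).  Returns qualifying :class:`BindingSite` objects sorted by
    ``(start, strand)``.
    """
    pseq, pname = _seq_and_name(primer, "primer")
    tseq, tname = _seq_and_name(template, "template")
    pseq = pseq.upper().replace("U", "T")
    tseq = tseq.upper().replace("U", "T")
    _validate(pseq, f"primer {pname}")
    _validate(tseq, f"template {tname}")
    orientation = _orientation(primer)
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"unknown primer orientation {orientation!r}")

    k = len(pseq)
    L = len(tseq)
    c = params.min_3prime_consecutive
    scan = pseq if orientation == "forward" else reverse_complement(pseq)
    strand = "+" if orientation == "forward" else "-"

    pm = np.array([_MASK[ch] for ch in scan], dtype=np.uint8)
    tm = _encode(tseq, params.strict_template)

    sites: list[BindingSite] = []

    def to_3prime_index(scan_col: int) -> int:
        # scan column -> primer position counted from the 3' end (1-based)
        if orientation == "forward":
            return k - scan_col
        return scan_col + 1

    def add_site(offset: int, cols: np.ndarray, mism: np.ndarray) -> None:
        aligned_len = len(cols)
        if aligned_len < params.min_match_len:
            return
        mm_idx = cols[mism]
        if len(mm_idx) > params.max_mm:
            return
        # 3' rule: the terminal c primer positions must be on-template matches
        if orientation == "forward":
            three_cols = range(k - c, k)
        else:
            three_cols = range(0, c)
        colset = set(cols.tolist())
        mmset = set(mm_idx.tolist())
        for col in three_cols:
            if col not in colset or col in mmset:
                return
        mm_positions = tuple(sorted(to_3prime_index(int(col)) for col in mm_idx))
        start = offset + int(cols[0])
        sites.append(
            BindingSite(
                ref_id=tname,
                primer_name=pname,
                strand=strand,
                start=start,
                end=start + aligned_len,
                aligned_len=aligned_len,
                mm_count=len(mm_positions),
                mm_positions=mm_positions,
                three_prime_intact=all(p > c for p in mm_positions),
            )
        )

    all_cols = np.arange(k)
    # interior placements, vectorised
    if L >= k:
        windows = np.lib.stride_tricks.sliding_window_view(tm, k)
        mism_mat = (windows & pm) == 0  # (L-k+1, k) True where mismatch
        mm_counts = mism_mat.sum(axis=1)
        if orientation == "forward":
            three_ok = ~mism_mat[:, k - c:].any(axis=1)
        else:
            three_ok = ~mism_mat[:, :c].any(axis=1)
        candidates = np.flatnonzero((mm_counts <= params.max_mm) & three_ok)
        for off in candidates:
            add_site(int(off), all_cols, mism_mat[off])

    # edge placements with a 5' overhang beyond the template boundary
    if params.allow_5prime_overhang and k > 1:
        if orientation == "forward":
            # 5' end hangs off the left edge: offsets -1 .. -(k-1)
            offsets = range(-1, -k, -1)
        else:
            # primer 5' end is the right end of the scan string; the 3' end
            # (scan column 0) may never overhang, so offsets stay >= 0
            offsets = range(max(L - k + 1, 0), L)
        for off in offsets:
            cols = np.array(
                [i for i in range(k) if 0 <= off + i < L], dtype=np.intp
            )
            if len(cols) == 0:
                continue
            mism = (tm[off + cols] & pm[cols]) == 0
            add_site(off, cols, mism)

    sites.sort(key=lambda s: (s.start, s.strand))
    if params.max_sites_per_template is not None:
        sites = sites[: params.max_sites_per_template]
    return sites


def best_site(sites: Sequence[BindingSite]) -> Optional[BindingSite]:
    """Site with minimal mismatch count; ties broken by larger aligned
    length, then smallest start.  None for an empty list."""
    if not sites:
        return None
    return min(sites, key=lambda s: (s.mm_count, -s.aligned_len, s.start))


def min_mismatch(primer, template, params: SearchParams = SearchParams()) -> Optional[int]:
    """Mismatch count of the best qualifying site, or None if none qualifies."""
    site = best_site(find_binding_sites(primer, template, params))
    return None if site is None else site.mm_count
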