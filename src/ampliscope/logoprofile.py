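"""Primer binding-region extraction and position-frequency matrices.

Given a multiple sequence alignment of target genes and the alignment-column
interval covering a primer's binding region, this module extracts the
per-sequence slices (reverse-complementing them for reverse primers so that
matrix position 1 always corresponds to the primer's 5' base) and summarises
them as a position-frequency matrix plus a degeneracy-aware per-position
mismatch rate.  The matrix is exported as TSV or a TRANSFAC-style block for
external logo renderers; drawing graphics is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .binding import IUPAC_SETS, base_compatible, IUPAC_COMPLEMENT
from .refdb import Primer

__all__ = ["PositionFrequencyMatrix", "extract_binding_regions", "build_pfm"]

SYMBOLS = ("A", "C", "G", "T", "gap", "other")


def _revcomp_gapped(s: str) -> str:
    # gaps mirror position but have no complement
    return "".join("-" if ch == "-" else IUPAC_COMPLEMENT[ch] for ch in reversed(s))


def extract_binding_regions(
    aligned_seqs: Sequence[tuple[str, str]] | Sequence[str],
    region: tuple[int, int],
    primer: Primer,
) -> list[str]:
    """Per-sequence alignment-column slices of the primer binding region.

    ``aligned_seqs`` is a list of aligned sequences (or (id, sequence)
    pairs) of equal column count; ``region`` is a 0-based half-open column
    interval.  For reverse primers every slice is reverse-complemented, so
    position 1 of the result corresponds to the primer's 5' base.  Gap
    characters are preserved (their positions mirror on reverse
    complementation).
    """
    seqs = [s[1] if isinstance(s, tuple) else s for s in aligned_seqs]
    if not seqs:
        return []
    ncol = len(seqs[0])
    if any(len(s) != ncol for s in seqs):
        raise ValueError("aligned sequences differ in column count")
    start, end = region
    if not (0 <= start < end <= ncol):
        raise ValueError(f"region {region} out of bounds for {ncol} columns")
    slices = [s[start:end].upper().replace("U", "T") for s in seqs]
    if primer.orientation == "reverse":
        slices = [_revcomp_gapped(s) for s in slices]
    return slices


@dataclass
class PositionFrequencyMatrix:
    """Counts and frequencies over primer positions (1..L, 5'->3').

    ``counts`` holds per-position tallies of A/C/G/T/gap/other;
    ``frequencies`` are normalised per position over non-gap symbols;
    ``mismatch_rate[i]`` is the fraction of non-gap target bases at primer
    position i+1 that are incompatible with the primer's IUPAC code there
    (a template R under a primer A counts as compatible, set-intersection
    semantics)."""

    primer_name: str
    primer_sequence: str
    counts: pd.DataFrame       # index 1..L, columns SYMBOLS
    frequencies: pd.DataFrame  # index 1..L, columns SYMBOLS (gap freq 0)
    mismatch_rate: np.ndarray  # length L
    n_sequences: int

    def to_tsv(self, path) -> None:
        out = self.counts.add_prefix("count_").join(
            self.frequencies[["A", "C", "G", "T", "other"]].add_prefix("freq_")
        )
        out["mismatch_rate"] = self.mismatch_rate
        out.insert(0, "primer_base", list(self.primer_sequence))
        out.to_csv(path, sep="\t", index_label="position")

    def to_transfac(self) -> str:
        lines = [f"ID {self.primer_name}", f"BF {self.primer_name}", "P0\tA\tC\tG\tT"]
        for pos in self.counts.index:
            row = self.counts.loc[pos]
            lines.append(
                f"{pos:02d}\t{int(row['A'])}\t{int(row['C'])}\t{int(row['G'])}\t{int(row['T'])}"
            )
        lines.append("XX")
        lines.append("//")
        return "\n".join(lines)


def _drop_gap_columns(slices: list[str], target_len: int) -> list[str]:
    """Drop columns gapped in >= 50% of slices until primer length is
    reached; columns with the highest gap fraction go first."""
    ncol = len(slices[0])
    if ncol == target_len:
        return slices
    arr = np.array([list(s) for s in slices])
    gap_frac = (arr == "-").mean(axis=0)
    order = sorted(range(ncol), key=lambda i: (-gap_frac[i], i))
    to_drop: set[int] = set()
    for col in order:
        if ncol - len(to_drop) <= target_len or gap_frac[col] < 0.5:
            break
        to_drop.add(col)
    keep = [i for i in range(ncol) if i not in to_drop]
    return ["".join(s[i] for i in keep) for s in slices]


def _reanchor(seq: str, primer_seq: str) -> str:
    """Fallback for slices whose ungapped length disagrees with the primer:
    best ungapped offset alignment against the primer, padded with gaps."""
    s = seq.replace("-", "")
    L = len(primer_seq)
    if len(s) >= L:
        best_off, best_mm = 0, L + 1
        for off in range(len(s) - L + 1):
            mm = sum(
                0 if base_compatible(p, t) else 1
                for p, t in zip(primer_seq, s[off:off + L])
            )
            if mm < best_mm:
                best_off, best_mm = off, mm
        return s[best_off:best_off + L]
    best_off, best_mm = 0, L + 1
    for off in range(L - len(s) + 1):
        mm = sum(
            0 if base_compatible(p, t) else 1
            for p, t in zip(primer_seq[off:off + len(s)], s)
        )
        if mm < best_mm:
            best_off, best_mm = off, mm
    return "-" * best_off + s + "-" * (L - len(s) - best_off)


def build_pfm(slices: Sequence[str], primer: Primer) -> PositionFrequencyMatrix:
    """Position-frequency matrix of binding-region slices against a primer.

    Slices longer than the primer are first reduced by dropping columns
    that are gaps in at least half of the slices; any slice still not
    matching the primer length is re-anchored against the primer by best
    ungapped offset.
    """
    if not slices:
        raise ValueError("empty slice list")
    L = len(primer.sequence)
    slices = _drop_gap_columns(list(slices), L)
    slices = [s if len(s) == L else _reanchor(s, primer.sequence) for s in slices]

    n = len(slices)
    counts = pd.DataFrame(0, index=range(1, L + 1), columns=list(SYMBOLS))
    # per-position raw character tallies kept for degeneracy-aware rates
    char_counts: list[dict[str, int]] = [dict() for _ in range(L)]
    for s in slices:
        for i, ch in enumerate(s):
            pos = i + 1
            if ch == "-":
                counts.loc[pos, "gap"] += 1
                continue
            if ch in "ACGT":
                counts.loc[pos, ch] += 1
            else:
                counts.loc[pos, "other"] += 1
            char_counts[i][ch] = char_counts[i].get(ch, 0) + 1

    frequencies = counts.astype(float).copy()
    mismatch_rate = np.zeros(L)
    for i in range(L):
        pos = i + 1
        nongap = n - counts.loc[pos, "gap"]
        if nongap > 0:
            frequencies.loc[pos] = counts.loc[pos] / nongap
            frequencies.loc[pos, "gap"] = 0.0
            incompatible = sum(
                cnt for ch, cnt in char_counts[i].items()
                if not base_compatible(primer.sequence[i], ch)
            )
            mismatch_rate[i] = incompatible / nongap
        else:
            frequencies.loc[pos] = 0.0
    return PositionFrequencyMatrix(
        primer_name=primer.name,
        primer_sequence=primer.sequence,
        counts=counts,
        frequencies=frequencies,
        mismatch_rate=mismatch_rate,
        n_sequences=n,
    )
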