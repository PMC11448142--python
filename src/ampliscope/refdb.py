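"""Reference database and primer-set handling.

A reference database is an ordered collection of labelled nucleotide
sequences -- here the target space of a functional marker gene survey:
comammox *Nitrospira* amoA clade A and clade B, betaproteobacterial AOB
amoA, and other copper-dependent monooxygenase (Cu-mmoA) homologs that form
the off-target space.  Labels come from a two-column TSV (``id<TAB>group``)
and are validated against that closed vocabulary.

The module also defines the curation filters applied before primer
evaluation: a minimum-length cut (default 700 bp for Cu-mmoA), exact
deduplication, and a full-length screen (start codon at the 5' end, stop
codon at the 3' end, length divisible by three).  Primers that bind within
the first or last 60 bp of the gene are flagged ``edge_primer`` and are
evaluated only against the full-length subset, because truncated database
entries systematically lack those regions.
"""

from __future__ import annotations

import csv
import gzip
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .binding import IUPAC_SETS

__all__ = [
    "GROUPS",
    "TARGET_GROUPS",
    "Primer",
    "ReferenceRecord",
    "ReferenceDB",
    "PairSpec",
    "read_reference_db",
    "write_reference_db",
    "read_primers",
    "read_pairs",
    "filter_min_length",
    "deduplicate",
    "filter_full_length",
    "write_filter_report",
]

GROUPS = ("cladeA", "cladeB", "AOB", "other_cu_mmo")
TARGET_GROUPS = ("cu_mmo_general", "comammox_general", "cladeA", "cladeB", "phylotype")

START_CODONS = frozenset({"ATG", "GTG", "TTG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_IUPAC = frozenset(IUPAC_SETS)


def _clean_seq(seq: str, what: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = [(i, ch) for i, ch in enumerate(seq) if ch not in _IUPAC]
    if bad:
        i, ch = bad[0]
        raise ValueError(f"non-IUPAC character {ch!r} at position {i} in {what}")
    return seq


@dataclass(frozen=True)
class Primer:
    """A named IUPAC-degenerate oligo, written 5'->3'."""

    name: str
    sequence: str
    orientation: str  # 'forward' | 'reverse'
    target_group: str = "comammox_general"
    edge_primer: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"primer {self.name}: empty sequence")
        object.__setattr__(self, "sequence", _clean_seq(self.sequence, f"primer {self.name}"))
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"primer {self.name}: bad orientation {self.orientation!r}")
        if self.target_group not in TARGET_GROUPS:
            raise ValueError(f"primer {self.name}: unknown target group {self.target_group!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReferenceRecord:
    id: str
    sequence: str
    group: str
    source: str = ""
    full_length: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id}: empty sequence")
        object.__setattr__(self, "sequence", _clean_seq(self.sequence, f"record {self.id}"))
        if self.group not in GROUPS:
            raise ValueError(f"record {self.id}: unknown group {self.group!r}")

    def __len__(self) -> int:
        return len(self.sequence)


class ReferenceDB:
    """Ordered, uniquely-identified collection of labelled references."""

    def __init__(self, records: Iterable[ReferenceRecord], provenance: str = ""):
        self.records: list[ReferenceRecord] = list(records)
        self.provenance = provenance
        self._index: dict[str, ReferenceRecord] = {}
        for rec in self.records:
            if rec.id in self._index:
                raise ValueError(f"duplicate record id {rec.id!r}")
            self._index[rec.id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ReferenceRecord]:
        return iter(self.records)

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self._index

    def get(self, ref_id: str) -> ReferenceRecord:
        return self._index[ref_id]

    def group_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            counts[rec.group] = counts.get(rec.group, 0) + 1
        return counts

    def by_group(self, group: str) -> list[ReferenceRecord]:
        return [rec for rec in self.records if rec.group == group]


@dataclass(frozen=True)
class PairSpec:
    """A forward/reverse primer pairing with its assay metadata.

    ``forward`` may name several primers used as an equimolar mix.
    ``min_match_len`` is the pair-level minimum on-template match length
    applied to both primers during amplicon prediction.
    """

    name: str
    forward: tuple[str, ...]
    reverse: str
    abbreviation: str = ""
    expected_product_length: int = 0
    annealing_temp: Optional[float] = None
    min_match_len: int = 13

    def __post_init__(self) -> None:
        if isinstance(self.forward, str):
            object.__setattr__(self, "forward", (self.forward,))
        else:
            object.__setattr__(self, "forward", tuple(self.forward))
        if not self.forward:
            raise ValueError(f"pair {self.name}: no forward primers")
        if self.min_match_len < 2:
            raise ValueError(f"pair {self.name}: min_match_len must be >= 2")

    def expected_amplicon_length(self, primers: dict[str, Primer]) -> int:
        """Expected primer-trimmed amplicon length: product length minus the
        footprints of the two primers (forward mixes are assumed equal
        length; the first listed is used)."""
        flen = len(primers[self.forward[0]])
        rlen = len(primers[self.reverse])
        return self.expected_product_length - flen - rlen


# ---------------------------------------------------------------------------
# I/O


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _read_labels(labels_path) -> dict[str, str]:
    labels: dict[str, str] = {}
    with _open_text(labels_path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for i, row in enumerate(reader):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"labels line {i + 1}: expected 'id<TAB>group'")
            rid, group = row[0].strip(), row[1].strip()
            if i == 0 and group not in GROUPS and rid.lower() in ("id", "sequence_id"):
                continue  # header line
            if group not in GROUPS:
                raise ValueError(
                    f"labels line {i + 1}: unknown group {group!r} (expected one of {GROUPS})"
                )
            labels[rid] = group
    return labels


def read_reference_db(fasta_path, labels_path, provenance: str = "") -> ReferenceDB:
    """Read a FASTA + labels TSV into a :class:`ReferenceDB`.

    FASTA order is preserved; sequences are uppercased with U->T.  Every
    FASTA id must be labelled; unlabelled or duplicate ids are hard errors.
    """
    labels = _read_labels(labels_path)
    records: list[ReferenceRecord] = []
    seen: set[str] = set()
    unlabeled: list[str] = []
    with _open_text(fasta_path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r} in {fasta_path}")
            seen.add(rec.id)
            group = labels.get(rec.id)
            if group is None:
                unlabeled.append(rec.id)
                continue
            records.append(
                ReferenceRecord(
                    id=rec.id,
                    sequence=str(rec.seq),
                    group=group,
                    source=rec.description[len(rec.id):].strip(),
                )
            )
    if unlabeled:
        raise ValueError(f"unlabeled sequence ids: {', '.join(unlabeled)}")
    return ReferenceDB(records, provenance=provenance or str(fasta_path))


def write_reference_db(db: ReferenceDB, fasta_path, labels_path=None) -> None:
    recs = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description=rec.source)
        for rec in db
    ]
    with open(fasta_path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")
    if labels_path is not None:
        with open(labels_path, "w") as fh:
            for rec in db:
                fh.write(f"{rec.id}\t{rec.group}\n")


def read_primers(tsv_path) -> dict[str, Primer]:
    """Read a primer TSV: name, sequence, orientation, target_group
    [, edge_primer].  Header row optional.  Names must be unique."""
    primers: dict[str, Primer] = {}
    with _open_text(tsv_path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for i, row in enumerate(reader):
            if not row or row[0].startswith("#"):
                continue
            if i == 0 and row[0].lower() in ("name", "primer"):
                continue
            if len(row) < 4:
                raise ValueError(f"primers line {i + 1}: need >= 4 columns")
            edge = len(row) > 4 and row[4].strip().lower() in ("1", "true", "yes")
            p = Primer(row[0].strip(), row[1].strip(), row[2].strip(), row[3].strip(), edge)
            if p.name in primers:
                raise ValueError(f"duplicate primer name {p.name!r}")
            primers[p.name] = p
    return primers


def read_pairs(tsv_path) -> list[PairSpec]:
    """Read a pairs TSV: name, forward (``+``-joined for mixes), reverse,
    abbreviation, product_length, annealing_temp, min_match_len."""
    pairs: list[PairSpec] = []
    with _open_text(tsv_path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for i, row in enumerate(reader):
            if not row or row[0].startswith("#"):
                continue
            if i == 0 and row[0].lower() in ("name", "pair"):
                continue
            pairs.append(
                PairSpec(
                    name=row[0].strip(),
                    forward=tuple(row[1].split("+")),
                    reverse=row[2].strip(),
                    abbreviation=row[3].strip() if len(row) > 3 else "",
                    expected_product_length=int(row[4]) if len(row) > 4 and row[4] else 0,
                    annealing_temp=float(row[5]) if len(row) > 5 and row[5] else None,
                    min_match_len=int(row[6]) if len(row) > 6 and row[6] else 13,
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# Curation filters.  Each returns (filtered_db, report_dict); the input db is
# never modified.


def filter_min_length(db: ReferenceDB, min_len: int = 700):
    """Retain records of length >= ``min_len`` (inclusive)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = [rec for rec in db if len(rec) >= min_len]
    removed = [rec.id for rec in db if len(rec) < min_len]
    report = {
        "rule": "min_length",
        "min_len": min_len,
        "input_n": len(db),
        "retained_n": len(kept),
        "removed_ids": removed,
    }
    return ReferenceDB(kept, provenance=db.provenance), report


def deduplicate(db: ReferenceDB):
    """Drop byte-identical sequences, keeping the first in input order.

    Exact same-strand matching only: reverse-complement duplicates are kept.
    """
    seen: dict[str, str] = {}
    kept: list[ReferenceRecord] = []
    removed_to_kept: dict[str, str] = {}
    for rec in db:
        first = seen.get(rec.sequence)
        if first is None:
            seen[rec.sequence] = rec.id
            kept.append(rec)
        else:
            removed_to_kept[rec.id] = first
    report = {
        "rule": "deduplicate",
        "input_n": len(db),
        "retained_n": len(kept),
        "removed_ids": sorted(removed_to_kept),
        "removed_to_kept": removed_to_kept,
    }
    return ReferenceDB(kept, provenance=db.provenance), report


def _has_internal_stop(seq: str, stop_codons: frozenset[str]) -> bool:
    return any(seq[i:i + 3] in stop_codons for i in range(0, len(seq) - 3, 3))


def filter_full_length(
    db: ReferenceDB,
    start_codons: Iterable[str] = START_CODONS,
    stop_codons: Iterable[str] = STOP_CODONS,
    check_internal_stops: bool = False,
):
    """Retain records that look like complete genes in frame 1: length
    divisible by 3, first codon a start codon, last codon a stop codon
    (bacterial translation table 11 defaults).  Records whose first or last
    codon contains an ambiguity code are excluded and reported as
    indeterminate.  Retained records get ``full_length=True``."""
    starts = frozenset(c.upper() for c in start_codons)
    stops = frozenset(c.upper() for c in stop_codons)
    if not starts or not stops:
        raise ValueError("codon sets must be non-empty")
    kept: list[ReferenceRecord] = []
    removed: list[str] = []
    indeterminate: list[str] = []
    for rec in db:
        seq = rec.sequence
        if len(seq) % 3 != 0 or len(seq) < 6:
            removed.append(rec.id)
            continue
        first, last = seq[:3], seq[-3:]
        if any(ch not in "ACGT" for ch in first + last):
            indeterminate.append(rec.id)
            removed.append(rec.id)
            continue
        if first not in starts or last not in stops:
            removed.append(rec.id)
            continue
        if check_internal_stops and _has_internal_stop(seq, stops):
            removed.append(rec.id)
            continue
        kept.append(replace(rec, full_length=True))
    report = {
        "rule": "full_length",
        "input_n": len(db),
        "retained_n": len(kept),
        "removed_ids": removed,
        "indeterminate_ids": indeterminate,
    }
    return ReferenceDB(kept, provenance=db.provenance), report


def write_filter_report(reports: Sequence[dict], path) -> None:
    """Write a JSON filter report: input/retained counts and removed ids by
    rule, in application order."""
    input_n = reports[0]["input_n"] if reports else 0
    retained_n = reports[-1]["retained_n"] if reports else 0
    payload = {
        "input_n": input_n,
        "retained_n": retained_n,
        "removed_ids": {r["rule"]: r["removed_ids"] for r in reports},
        "stages": list(reports),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
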