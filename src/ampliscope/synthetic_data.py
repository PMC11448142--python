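"""Synthetic reference databases, planted primer sites, and derived ASVs.

Every pipeline stage in this package is testable without downloads because
this module generates grouped reference sets (clade A / clade B / AOB /
other Cu-mmoA) whose primer binding sites are *planted* with controlled
mismatch counts and 3'-indexed mismatch positions, together with a truth
table stating, per sequence, which sites exist and, per group x primer x
threshold, the exact coverage fraction the pipeline must recover.

Background sequence is uniform random (GC configurable); it is rejection-
sampled so that no accidental qualifying site for any planted primer
exists -- checked with the binding engine itself, which is acceptable here
because the engine is independently verified against a brute-force oracle.
Planted sites are realised by writing a concrete (degeneracy-resolved) copy
of the primer into the template, with substitutions at the requested
3'-indexed positions that are incompatible with the primer's IUPAC code.

ASVs are derived from chosen references as slices of controlled length
(coverage fraction of the expected amplicon length) carrying evenly spaced
substitutions to hit a target nucleotide identity exactly.  Substitutions
are kept >= 2 bases from the slice ends and >= 3 bases apart, so under
match +2 / mismatch -3 scoring the full-length ungapped alignment is the
unique local optimum and the measured identity equals the planted one.

Sequencing error profiles, chimeras, and amplification bias are not
simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .binding import IUPAC_SETS, SearchParams, find_binding_sites, reverse_complement
from .refdb import GROUPS, PairSpec, Primer, ReferenceDB, ReferenceRecord

__all__ = [
    "PlantSpec",
    "PairPlant",
    "AsvPlan",
    "SynthSpec",
    "TruthTable",
    "generate_reference_set",
    "generate_asvs",
    "example_primer_panel",
]

_MAX_TRIES = 200


class _PlacementConflict(Exception):
    """Planted footprints collided; resample and retry."""


@dataclass(frozen=True)
class PlantSpec:
    """Plant a single-primer site in ``fraction`` of a group's sequences
    with ``mm_count`` substitutions at the given 3'-indexed positions."""

    group: str
    primer: str
    fraction: float
    mm_count: int = 0
    mm_positions: tuple[int, ...] = ()
    position: Optional[int] = None  # sense-strand footprint start; None = random

    def __post_init__(self) -> None:
        if self.mm_count != len(self.mm_positions):
            raise ValueError("mm_count must equal len(mm_positions)")


@dataclass(frozen=True)
class PairPlant:
    """Plant a complete forward+reverse amplicon of ``product_length`` bp in
    ``fraction`` of a group's sequences."""

    group: str
    pair: str
    fraction: float
    product_length: int
    f_mm_positions: tuple[int, ...] = ()
    r_mm_positions: tuple[int, ...] = ()
    forward_choice: int = 0  # index into the pair's forward mix


@dataclass(frozen=True)
class AsvPlan:
    """Derive one ASV from ``source_ref`` at a target identity and coverage
    (fraction of the expected amplicon length), with per-sample reads."""

    source_ref: str
    identity: float
    cover: float
    reads: dict[str, int]

    def __post_init__(self) -> None:
        if self.identity < 0.5:
            raise ValueError("identity targets below 0.5 are outside the model")


@dataclass
class SynthSpec:
    seed: int
    groups: dict[str, int]
    seq_len: tuple[int, int] = (700, 900)
    plants: list[PlantSpec] = field(default_factory=list)
    pair_plants: list[PairPlant] = field(default_factory=list)
    n_duplicate_pairs: int = 0
    n_short: int = 0
    short_len: int = 300
    gc: float = 0.5


@dataclass
class TruthTable:
    """Ground truth emitted alongside a synthetic database."""

    # ref_id -> list of planted sites (primer, start, mm_count, mm_positions)
    sites: dict[str, list[dict]] = field(default_factory=dict)
    # (primer, group, threshold) -> exact expected coverage fraction
    coverage: dict[tuple[str, str, int], float] = field(default_factory=dict)
    # (pair, group, threshold) -> exact expected pair coverage fraction
    pair_coverage: dict[tuple[str, str, int], float] = field(default_factory=dict)
    # (pair, ref_id) -> planted product length
    product_length: dict[tuple[str, str], int] = field(default_factory=dict)
    duplicates: dict[str, str] = field(default_factory=dict)  # removed -> kept
    short_ids: list[str] = field(default_factory=list)
    # asv_id -> dict(source, identity, cover, category, aggregated_ref)
    asvs: dict[str, dict] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# helpers


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def _realize_primer(rng: np.random.Generator, primer: Primer) -> str:
    """Concrete ACGT string compatible with the primer at every position."""
    return "".join(rng.choice(sorted(IUPAC_SETS[ch])) for ch in primer.sequence)


def _mismatch_base(rng: np.random.Generator, code: str) -> str:
    options = sorted(set("ACGT") - IUPAC_SETS[code])
    if not options:
        raise ValueError(f"cannot plant a mismatch against primer base {code!r} (N)")
    return rng.choice(options)


def _planted_footprint(
    rng: np.random.Generator, primer: Primer, mm_positions: Sequence[int]
) -> str:
    """Sense-strand footprint of a planted site with the given 3'-indexed
    mismatch positions."""
    k = len(primer.sequence)
    site = list(_realize_primer(rng, primer))
    for p in mm_positions:
        if not 1 <= p <= k:
            raise ValueError(f"mismatch position {p} outside primer of length {k}")
        i = k - p  # 3'-indexed -> 0-based 5'-indexed
        site[i] = _mismatch_base(rng, primer.sequence[i])
    s = "".join(site)
    return s if primer.orientation == "forward" else reverse_complement(s)


def _free_position(
    rng: np.random.Generator,
    seq_len: int,
    width: int,
    occupied: list[tuple[int, int]],
    fixed: Optional[int],
) -> int:
    if fixed is not None:
        start = fixed
        if start < 0 or start + width > seq_len:
            raise ValueError("fixed plant position outside sequence")
        if any(start < e and s < start + width for s, e in occupied):
            raise _PlacementConflict(
                "fixed plant position overlaps another planted site"
            )
        return start
    for _ in range(_MAX_TRIES):
        start = int(rng.integers(0, seq_len - width + 1))
        if not any(start < e and s < start + width for s, e in occupied):
            return start
    raise _PlacementConflict("could not place planted site without overlap")


def _qualifies(mm_count: int, mm_positions: Sequence[int], t: int, params: SearchParams) -> bool:
    return mm_count <= t and all(p > params.min_3prime_consecutive for p in mm_positions)


# ---------------------------------------------------------------------------
# reference generation


def generate_reference_set(
    spec: SynthSpec,
    primers: dict[str, Primer],
    pairs: Optional[dict[str, PairSpec]] = None,
    params: SearchParams = SearchParams(),
) -> tuple[ReferenceDB, TruthTable]:
    """Generate a labelled reference database with planted sites and its
    truth table.  Deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    pairs = pairs or {}
    for plant in spec.plants:
        if len(primers[plant.primer]) > spec.seq_len[0]:
            raise ValueError(f"primer {plant.primer} longer than shortest sequence")
    for pp in spec.pair_plants:
        if pp.product_length > spec.seq_len[0]:
            raise ValueError(f"pair {pp.pair}: product longer than shortest sequence")

    watched = {p.primer for p in spec.plants}
    for pp in spec.pair_plants:
        pair = pairs[pp.pair]
        watched.update(pair.forward)
        watched.add(pair.reverse)
    watch_primers = [primers[name] for name in sorted(watched)]

    truth = TruthTable()
    records: list[ReferenceRecord] = []

    # per group: which sequence indices receive which plants (disjoint,
    # assigned in plan order so fractions are exact)
    plan_by_group: dict[str, list[tuple[object, list[int]]]] = {g: [] for g in spec.groups}
    # fractions are disjoint per (group, primer) and per (group, pair);
    # different primers/pairs may share sequences
    for g, n in spec.groups.items():
        cursors: dict[str, int] = {}
        for plant in [p for p in spec.plants if p.group == g]:
            count = round(plant.fraction * n)
            start = cursors.get(plant.primer, 0)
            if start + count > n:
                raise ValueError(f"group {g}: fractions for {plant.primer} exceed 1")
            plan_by_group[g].append((plant, list(range(start, start + count))))
            cursors[plant.primer] = start + count
        pcursors: dict[str, int] = {}
        for pp in [p for p in spec.pair_plants if p.group == g]:
            count = round(pp.fraction * n)
            start = pcursors.get(pp.pair, 0)
            if start + count > n:
                raise ValueError(f"group {g}: fractions for pair {pp.pair} exceed 1")
            plan_by_group[g].append((pp, list(range(start, start + count))))
            pcursors[pp.pair] = start + count

    for g, n in spec.groups.items():
        assignments: dict[int, list] = {i: [] for i in range(n)}
        for plant, idxs in plan_by_group[g]:
            for i in idxs:
                assignments[i].append(plant)
        for i in range(n):
            rid = f"{g}_{i:04d}"
            seq, planted = _build_sequence(rng, spec, primers, pairs, params,
                                           assignments[i], watch_primers, rid)
            records.append(ReferenceRecord(id=rid, sequence=seq, group=g, source="synthetic"))
            truth.sites[rid] = planted
            for site in planted:
                if site.get("pair"):
                    truth.product_length[(site["pair"], rid)] = site["product_length"]

    _fill_coverage_truth(truth, spec, pairs, params)

    # injections for filter tests (appended after the planted records; they
    # are not part of the coverage truth)
    for d in range(spec.n_duplicate_pairs):
        src = records[d % len(records)]
        dup_id = f"dup_{d:03d}_{src.id}"
        records.append(ReferenceRecord(id=dup_id, sequence=src.sequence,
                                       group=src.group, source="synthetic duplicate"))
        truth.duplicates[dup_id] = src.id
    for s in range(spec.n_short):
        sid = f"short_{s:03d}"
        group = next(iter(spec.groups))
        records.append(ReferenceRecord(id=sid, sequence=_random_seq(rng, spec.short_len, spec.gc),
                                       group=group, source="synthetic short"))
        truth.short_ids.append(sid)

    db = ReferenceDB(records, provenance=f"synthetic seed={spec.seed}")
    return db, truth


def _build_sequence(rng, spec, primers, pairs, params, plants, watch_primers, rid):
    length = int(rng.integers(spec.seq_len[0], spec.seq_len[1] + 1))
    for _ in range(_MAX_TRIES):
        seq = list(_random_seq(rng, length, spec.gc))
        occupied: list[tuple[int, int]] = []
        planted: list[dict] = []
        ok = True
        try:
            for plant in plants:
                if isinstance(plant, PlantSpec):
                    primer = primers[plant.primer]
                    k = len(primer)
                    start = _free_position(rng, length, k, occupied, plant.position)
                    seq[start:start + k] = _planted_footprint(rng, primer, plant.mm_positions)
                    occupied.append((start, start + k))
                    planted.append({
                        "primer": plant.primer, "start": start,
                        "mm_count": plant.mm_count,
                        "mm_positions": tuple(sorted(plant.mm_positions)),
                        "pair": None,
                    })
                else:  # PairPlant
                    pair = pairs[plant.pair]
                    fprimer = primers[pair.forward[plant.forward_choice]]
                    rprimer = primers[pair.reverse]
                    plen = plant.product_length
                    if plen > length:
                        raise ValueError(f"{rid}: product does not fit")
                    fstart = _free_position(rng, length - plen + 1, 1, [], None)
                    rstart = fstart + plen - len(rprimer)
                    if rstart < fstart + len(fprimer):
                        raise ValueError(f"pair {plant.pair}: primers would overlap")
                    for s0, primer, mmpos in (
                        (fstart, fprimer, plant.f_mm_positions),
                        (rstart, rprimer, plant.r_mm_positions),
                    ):
                        w = len(primer)
                        if any(s0 < e and s < s0 + w for s, e in occupied):
                            raise _PlacementConflict(rid)
                        seq[s0:s0 + w] = _planted_footprint(rng, primer, mmpos)
                        occupied.append((s0, s0 + w))
                    planted.append({
                        "primer": fprimer.name, "start": fstart,
                        "mm_count": len(plant.f_mm_positions),
                        "mm_positions": tuple(sorted(plant.f_mm_positions)),
                        "pair": plant.pair, "product_length": plen,
                    })
                    planted.append({
                        "primer": rprimer.name, "start": rstart,
                        "mm_count": len(plant.r_mm_positions),
                        "mm_positions": tuple(sorted(plant.r_mm_positions)),
                        "pair": plant.pair, "product_length": plen,
                    })
        except _PlacementConflict:
            continue
        sseq = "".join(seq)
        # rejection check: the engine must find exactly the planted sites,
        # with exactly the planted mismatch counts, and nothing else
        for primer in watch_primers:
            found = find_binding_sites(primer, sseq, params)
            exp = [p for p in planted if p["primer"] == primer.name
                   and _qualifies(p["mm_count"], p["mm_positions"], params.max_mm, params)]
            if len(found) != len(exp):
                ok = False
                break
            for site, p in zip(sorted(found, key=lambda s: s.start),
                               sorted(exp, key=lambda q: q["start"])):
                if site.start != p["start"] or site.mm_count != p["mm_count"]:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return sseq, planted
    raise RuntimeError(f"{rid}: could not generate clean background in {_MAX_TRIES} tries")


def _fill_coverage_truth(truth: TruthTable, spec: SynthSpec, pairs, params: SearchParams):
    thresholds = range(0, params.max_mm + 1)
    primer_names = {p.primer for p in spec.plants}
    for pp in spec.pair_plants:
        pair = pairs[pp.pair]
        primer_names.update(pair.forward)
        primer_names.add(pair.reverse)
    for g, n in spec.groups.items():
        ids = [f"{g}_{i:04d}" for i in range(n)]
        for pname in primer_names:
            for t in thresholds:
                covered = sum(
                    1 for rid in ids
                    if any(p["primer"] == pname and _qualifies(p["mm_count"], p["mm_positions"], t, params)
                           for p in truth.sites.get(rid, []))
                )
                truth.coverage[(pname, g, t)] = covered / n if n else 0.0
        for pp_name in {p.pair for p in spec.pair_plants}:
            for t in thresholds:
                covered = 0
                for rid in ids:
                    sites = [p for p in truth.sites.get(rid, []) if p["pair"] == pp_name]
                    if sites and all(
                        _qualifies(p["mm_count"], p["mm_positions"], t, params) for p in sites
                    ):
                        covered += 1
                truth.pair_coverage[(pp_name, g, t)] = covered / n if n else 0.0


# ---------------------------------------------------------------------------
# ASV generation


def generate_asvs(
    db: ReferenceDB,
    plan: Sequence[AsvPlan],
    seed: int,
    expected_len: int,
    truth: Optional[TruthTable] = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame, TruthTable]:
    """Derive ASVs from references per plan; returns (asvs, abundance
    table, truth).  Each ASV is a slice of its source of length
    ``round(cover * expected_len)`` with evenly spaced substitutions
    realising the identity target to within one substitution."""
    rng = np.random.default_rng(seed)
    truth = truth or TruthTable()
    asvs: list[tuple[str, str]] = []
    abundance_rows: list[dict] = []
    for i, item in enumerate(plan):
        src = db.get(item.source_ref)
        slice_len = round(item.cover * expected_len)
        if slice_len < 10:
            raise ValueError("ASV slice shorter than 10 bp")
        if slice_len > len(src):
            raise ValueError(f"ASV slice longer than source {src.id}")
        start = int(rng.integers(0, len(src) - slice_len + 1))
        sl = list(src.sequence[start:start + slice_len])
        n_sub = round((1 - item.identity) * slice_len)
        positions = _even_positions(slice_len, n_sub)
        for pos in positions:
            sl[pos] = rng.choice(sorted(set("ACGT") - {sl[pos]}))
        asv_seq = "".join(sl)
        asv_id = f"asv_{i:04d}"
        asvs.append((asv_id, asv_seq))
        realized_id = 1 - n_sub / slice_len
        realized_cover = slice_len / expected_len
        truth.asvs[asv_id] = {
            "source": src.id,
            "identity": realized_id,
            "cover": realized_cover,
            "category": _expected_category(src.group, realized_id, realized_cover),
            "aggregated_ref": src.id
            if realized_id >= 0.90 and realized_cover >= 0.66 else None,
        }
        for sample, count in item.reads.items():
            abundance_rows.append(
                {"sample_id": sample, "asv_id": asv_id, "read_count": count}
            )
    abundance = pd.DataFrame(abundance_rows,
                             columns=["sample_id", "asv_id", "read_count"])
    return asvs, abundance, truth


def _even_positions(length: int, n_sub: int) -> list[int]:
    """Evenly spaced substitution positions >= 2 bases from both slice ends
    and >= 3 bases apart, so that under match +2 / mismatch -3 scoring no
    end-trim of the local alignment can raise the score and the measured
    identity equals the planted one exactly."""
    if n_sub == 0:
        return []
    if (length - 5) / n_sub < 3:
        raise ValueError(
            "identity target too low for safe substitution spacing "
            f"({n_sub} substitutions in {length} bp)"
        )
    positions: list[int] = []
    prev = -3
    for j in range(n_sub):
        p = 2 + int((j + 0.5) * (length - 5) / n_sub)
        p = max(p, 2, prev + 3)
        if p > length - 3:
            raise ValueError("cannot place substitutions with safe spacing")
        positions.append(p)
        prev = p
    return positions


def _expected_category(group: str, identity: float, cover: float) -> str:
    if cover < 0.33:
        return "unaligned"
    if cover >= 0.66 and identity >= 0.75:
        return group
    return "unknown"


# ---------------------------------------------------------------------------
# a ready-made primer panel mirroring the structure of a comammox amoA assay
# panel: clade-specific long/short pairs, a general comammox pair, an
# equimolar two-forward mix, and one edge primer.  All sequences are
# synthetic; the pair metadata (product lengths 415/198/235 bp, annealing
# temperatures, and pair-level minimum match lengths 13/17/15 bp) mirrors
# the assay panel this package was built to evaluate.


def example_primer_panel() -> tuple[dict[str, Primer], dict[str, PairSpec]]:
    primers = {
        "cladeA_244F": Primer("cladeA_244F", "TACGGTCRAACGTAGCT", "forward", "cladeA"),
        "cladeA_659R": Primer("cladeA_659R", "GATCCATKGTGCTTCCA", "reverse", "cladeA"),
        "comx_162F": Primer("comx_162F", "CCTGGTTAYCACGGATTCA", "forward", "comammox_general"),
        "comx_359R": Primer("comx_359R", "GGTAACGTCMTTACCAGCG", "reverse", "comammox_general"),
        "mixA_377F": Primer("mixA_377F", "TTCACGATWGGCTTCGC", "forward", "cladeA"),
        "mixB_377F": Primer("mixB_377F", "AAGCCGTYGATCTGACG", "forward", "cladeB"),
        "shared_576R": Primer("shared_576R", "CGTTCAGRTAGACCGGA", "reverse", "comammox_general"),
        "edge_1F": Primer("edge_1F", "ATGAGYACAGCCATTGG", "forward", "cladeA", edge_primer=True),
    }
    pairs = {
        "cladeA_long": PairSpec("cladeA_long", ("cladeA_244F",), "cladeA_659R",
                                abbreviation="A.P", expected_product_length=415,
                                annealing_temp=52, min_match_len=13),
        "comx_pair": PairSpec("comx_pair", ("comx_162F",), "comx_359R",
                              abbreviation="AB.F", expected_product_length=198,
                              annealing_temp=48, min_match_len=17),
        "cladeA_short": PairSpec("cladeA_short", ("mixA_377F",), "shared_576R",
                                 abbreviation="A.J", expected_product_length=235,
                                 annealing_temp=55, min_match_len=15),
        "cladeB_short": PairSpec("cladeB_short", ("mixB_377F",), "shared_576R",
                                 abbreviation="B.J", expected_product_length=235,
                                 annealing_temp=55, min_match_len=15),
        "mix_short": PairSpec("mix_short", ("mixA_377F", "mixB_377F"), "shared_576R",
                              abbreviation="AB.J", expected_product_length=235,
                              annealing_temp=55, min_match_len=15),
    }
    return primers, pairs
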