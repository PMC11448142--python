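"""Paired-primer amplicon prediction and fragment extraction.

A predicted amplicon is a forward binding site and a reverse binding site on
the same template, in proper orientation (forward footprint entirely
upstream of the reverse footprint), spanning at most ``max_product_len``.
Both sites must individually satisfy the pair-level qualification rules;
pair evaluation typically tightens the minimum match length (e.g. 13-17 bp
instead of the single-primer 11 bp).  Product lengths include both primer
footprints, matching how assay product sizes are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .binding import BindingSite, SearchParams, find_binding_sites
from .refdb import PairSpec, Primer, ReferenceDB, ReferenceRecord

__all__ = ["AmpliconPrediction", "predict_amplicons", "extract_fragments", "amplicon_table"]

DEFAULT_MAX_PRODUCT_LEN = 2000


@dataclass(frozen=True)
class AmpliconPrediction:
    ref_id: str
    pair_name: str
    forward_site: BindingSite
    reverse_site: BindingSite
    start: int
    end: int
    length: int
    sequence: str

    def __post_init__(self) -> None:
        assert self.length == self.end - self.start


def _pair_params(pair: PairSpec, params: SearchParams) -> SearchParams:
    if pair.min_match_len == params.min_match_len:
        return params
    return replace(params, min_match_len=pair.min_match_len)


def predict_amplicons(
    pair: PairSpec,
    template: ReferenceRecord,
    primers: dict[str, Primer],
    params: SearchParams = SearchParams(),
    max_product_len: int = DEFAULT_MAX_PRODUCT_LEN,
) -> list[AmpliconPrediction]:
    """All qualifying forward x reverse site combinations on ``template``.

    For multi-primer forward mixes the union over forward primers is
    returned, with the contributing primer recorded on the forward site.
    Returns an empty list (never an error) when either primer lacks a site.
    """
    p = _pair_params(pair, params)
    rprimer = primers[pair.reverse]
    if rprimer.orientation != "reverse":
        raise ValueError(f"pair {pair.name}: {rprimer.name} is not a reverse primer")
    rsites = find_binding_sites(rprimer, template, p)
    if not rsites:
        return []
    out: list[AmpliconPrediction] = []
    for fname in pair.forward:
        fprimer = primers[fname]
        if fprimer.orientation != "forward":
            raise ValueError(f"pair {pair.name}: {fname} is not a forward primer")
        for fsite in find_binding_sites(fprimer, template, p):
            for rsite in rsites:
                # proper orientation: forward footprint fully upstream of the
                # reverse footprint (implies the 3' ends are ordered)
                if fsite.end > rsite.start:
                    continue
                length = rsite.end - fsite.start
                if not (0 < length <= max_product_len):
                    continue
                out.append(
                    AmpliconPrediction(
                        ref_id=template.id,
                        pair_name=pair.name,
                        forward_site=fsite,
                        reverse_site=rsite,
                        start=fsite.start,
                        end=rsite.end,
                        length=length,
                        sequence=template.sequence[fsite.start:rsite.end],
                    )
                )
    out.sort(key=lambda a: (a.start, a.end, a.forward_site.primer_name))
    return out


def extract_fragments(
    db: ReferenceDB,
    pair: PairSpec,
    primers: dict[str, Primer],
    params: SearchParams = SearchParams(),
    max_product_len: int = DEFAULT_MAX_PRODUCT_LEN,
) -> list[SeqRecord]:
    """One FASTA record per predicted amplicon, ordered by (ref_id, start);
    ids follow ``{ref_id}|{pair_name}|{start}-{end}``."""
    frags: list[SeqRecord] = []
    for rec in db:
        for amp in predict_amplicons(pair, rec, primers, params, max_product_len):
            frags.append(
                SeqRecord(
                    Seq(amp.sequence),
                    id=f"{amp.ref_id}|{amp.pair_name}|{amp.start}-{amp.end}",
                    description="",
                )
            )
    frags.sort(key=lambda r: (r.id.split("|")[0], int(r.id.rsplit("|", 1)[1].split("-")[0])))
    return frags


def amplicon_table(amplicons: Iterable[AmpliconPrediction]) -> pd.DataFrame:
    """Long-format amplicon table (ref_id, pair, primers, coordinates,
    length, per-primer mismatch counts)."""
    rows = [
        {
            "ref_id": a.ref_id,
            "pair": a.pair_name,
            "forward_primer": a.forward_site.primer_name,
            "reverse_primer": a.reverse_site.primer_name,
            "start": a.start,
            "end": a.end,
            "length": a.length,
            "F_mm": a.forward_site.mm_count,
            "R_mm": a.reverse_site.mm_count,
        }
        for a in amplicons
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "ref_id", "pair", "forward_primer", "reverse_primer",
            "start", "end", "length", "F_mm", "R_mm",
        ],
    )
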