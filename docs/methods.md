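# Methods

## Problem setting

PCR-based surveys of complete ammonia oxidisers (comammox *Nitrospira*)
rely on degenerate primers targeting the *amoA* gene, a member of the
copper-dependent membrane-bound monooxygenase (Cu-MMO) subunit A family.
Because the off-target space — betaproteobacterial AOB *amoA* and other
Cu-*mmoA* homologs — is sequence-similar, the practical questions about any
published primer are (i) what fraction of each target clade it can bind
(coverage), (ii) how much of the non-target space it also binds
(specificity), and (iii) what the resulting amplicon data do to apparent
community composition, summarised by the clade A : clade B read ratio.
`ampliscope` implements this evaluation as a reusable, fully tested
pipeline, plus the downstream affiliation of amplicon sequence variants
(ASVs) back to the reference set.

## Binding model

A binding site is an ungapped placement of a primer (5'→3', IUPAC
alphabet) on the sense strand of a reference; reverse primers are
reverse-complemented before scanning. A primer base matches a template
base when the IUPAC expansion sets intersect. A placement qualifies iff

1. its on-template aligned length ≥ `min_match_len` (default 11 bp),
2. its mismatch count ≤ `max_mm` (default 3),
3. the primer's terminal `min_3prime_consecutive` 3' positions (default 2)
   are on the template and match it.

Rule 3 is the 3'-anchor: a mismatch at the extension end of a primer is
far more disruptive to amplification than an internal one, so such
placements are treated as non-binding rather than as high-mismatch sites.
Mismatch positions are reported indexed from the primer's 3' end
(1 = terminal base) because every rule of interest is 3'-anchored.

Design choices that were genuinely open:

* **Ungapped matching.** Indels within a ~15–20 nt primer footprint are
  treated as non-binding. This is standard in-silico PCR practice; a
  gapped model would require an indel penalty scheme that the coverage
  statistic does not need.
* **"Match length" is aligned length, not identical bases.** The
  `min_match_len` threshold counts on-template positions; the mismatch
  budget is governed solely by `max_mm`. Both are configurable.
* **5' overhangs.** A primer may hang over the template edge with its 5'
  end (overhanging positions neither match nor mismatch and do not count
  toward the aligned length); the 3' end may never overhang. A flag
  (`allow_5prime_overhang`) records the choice because edge behaviour of
  binding-site tools is not standardised.
* **Template ambiguity codes** match by set intersection (an N in a
  reference matches everything). `strict_template=True` instead counts
  every ambiguous template position as a mismatch.

Coordinates are 0-based half-open on the sense strand everywhere in the
API; conversions happen only in output layers.

The engine (vectorised mask-intersection scan) is verified against an
independent brute-force oracle that enumerates every offset with
dict-of-sets IUPAC semantics; acceptance runs 4,000 random
primer × template instances and requires byte-identical site lists
(coordinates, mismatch counts, 3'-indexed positions).

## Coverage and specificity

Coverage of a primer for a group at threshold *t* is the fraction of the
group's sequences with ≥1 qualifying site of ≤ *t* mismatches; it is
reported at *t* = 0…3, and is monotone in *t* by construction. The
denominator is **all** sequences of the group in the selected database
variant, including entries too truncated to contain the site. Primers
binding within the terminal 60 bp of the gene (`edge_primer=True`) are
therefore evaluated against the full-length-only variant (start codon,
stop codon, length divisible by three), since truncated database entries
systematically lack the gene termini; the table records which variant was
used. Start/stop codon sets default to bacterial translation table 11
({ATG, GTG, TTG} / {TAA, TAG, TGA}) and are configurable; internal-stop
screening exists but is off by default.

Pair coverage requires a predicted amplicon whose forward and reverse
sites *both* satisfy the pair-level rules (the minimum match length is
tightened per assay: 13 bp for the long clade-specific pairs, 17 bp for
the general pair, 15 bp for the short clade-specific pairs) with both
mismatch counts ≤ *t*, in proper orientation, with product length ≤
`max_product_len` (default 2,000 bp — the cap only exists to stop pairing
distant spurious sites). Product lengths include both primer footprints,
matching how assay product sizes (415 / 198 / 235 bp) are quoted.
Templates with several qualifying amplicons count once.

Primer categorisation (general Cu-mmoA / general comammox / clade A /
clade B / phylotype-specific) is a deterministic cascade on the four group
fractions at *t* = 3 with configurable cutoffs, default target-high ≥ 0.7
and off-target-low < 0.1. The cutoffs are this package's own
operationalisation of an otherwise visual assignment and are recorded in
the output.

## Binding-region profiles

Given an MSA of target genes and the column interval of a binding region,
per-sequence slices are extracted (reverse-complemented for reverse
primers, gap positions mirroring) and summarised as a position-frequency
matrix with a degeneracy-aware per-position mismatch rate: 1 minus the
summed frequency of bases compatible with the primer's IUPAC code at that
position, over non-gap symbols. Columns gapped in ≥50 % of slices are
dropped to reach primer length; slices still disagreeing in length are
re-anchored by best ungapped offset against the primer. Graphical logo
rendering is deliberately out of scope; TSV and TRANSFAC-style exports
feed external tools.

## ASV affiliation and community summaries

ASVs are compared to the labelled reference set by local (Smith–Waterman,
affine-gap) alignment, provided by Biopython's `PairwiseAligner` with
BLAST-like scoring (match +2, mismatch −3, gap open 5, gap extend 2;
bitscore = (λ·S − ln K)/ln 2, λ = 0.625, K = 0.41). Identity is matches
over alignment columns; coverage is alignment columns over the *expected
amplicon length*, defined as assay product length minus both primer
footprints (reads are primer-trimmed upstream). Score parity with any
particular BLAST build is a non-goal; the contract is the threshold
semantics:

| best-hit condition | outcome |
|---|---|
| coverage < 0.33 (or no alignment) | `unaligned` |
| coverage ≥ 0.66 and identity ≥ 0.75 | group of the best reference |
| … and identity ≥ 0.90 | additionally aggregated to that reference |
| otherwise (0.33 ≤ coverage < 0.66, or identity < 0.75) | `unknown` |

All boundaries are inclusive on the ≥ side. References are ranked by
bitscore with deterministic tie-breaks (higher identity, then smaller
reference id). The `unknown` band is reported explicitly rather than
folded into either neighbour.

Community summaries are per-sample relative read abundances by category
(closing to 1), unique-ASV counts per category, and the per-sample
clade A : clade B read ratio with its arithmetic mean; samples with zero
clade B reads yield an infinite ratio, are excluded from the mean, and
trigger a warning. The tests and acceptance script verify end-to-end
recovery of planted mean ratios of 4.00 (mixed-forward short pair
scenario) and 0.57 (general pair scenario) — the exactness here is a
check of the pipeline's bookkeeping, not a claim about real communities.

## Synthetic data: what it emulates, and what it does not

The generator emulates the statistical structure the pipeline consumes:
grouped reference sets (clade A / clade B / AOB / other Cu-mmoA; default
lengths 700–900 bp, GC 50 %, both configurable), planted primer binding
sites with exact mismatch counts at chosen 3'-indexed positions, planted
forward+reverse amplicons at chosen product lengths, injected duplicates
and sub-length sequences for the curation filters, and ASVs derived from
references at exact identity and coverage targets with planted per-sample
read counts.

Background sequence is rejection-sampled until the binding engine finds
exactly the planted sites and nothing else; using the engine for the
rejection check is acceptable because the engine is itself verified
against the independent brute-force oracle. Planted ASVs realise identity
targets with evenly spaced substitutions kept ≥2 bases from slice ends
and ≥3 bases apart; under +2/−3 scoring no local-alignment end-trim can
then raise the score, so measured identity equals the planted value
exactly and truth-table recovery can be asserted without tolerance (this
construction requires identity targets ≥ ~0.67; the generator refuses
anything below 0.5 outright).

Not emulated: sequencing error profiles, chimeras, PCR amplification
bias, real phylogenetic correlation structure between groups, and
conserved-motif background similar to a primer site. Passing tests
therefore demonstrate that the *rules* are implemented exactly as stated,
not that any particular real primer achieves a particular real coverage —
real-database results depend entirely on the reference FASTA and labels
supplied by the user.

## Problem sizes and numerics

The default verification runs at desk scale: 4,000 engine-oracle
instances on 60 nt templates with 15 nt primers, planted databases of
30–40 sequences of 700–860 bp, and ASV sets of a dozen variants; the full
suite and the acceptance script each complete in a few seconds on one
core. Coverage fractions are exact rational counts (no floating-point
accumulation); the only approximate comparisons in the test suite are
explicit `pytest.approx` checks on frequencies. Degenerate inputs are
defined throughout: empty site lists are legal (never errors), a primer
longer than its template yields no sites, empty reference databases are
hard errors where a denominator would be needed, and zero-denominator
clade ratios are infinite-and-excluded rather than NaN.

## Known limitations

* Binding is thermodynamics-free: no melting temperature, ΔG, or
  primer-dimer model; a 0-mismatch site 3 °C below the annealing optimum
  and a perfect site are indistinguishable.
* The ungapped model cannot represent bulge-tolerant binding.
* The internal aligner mimics BLASTN's default scoring but is not
  bit-for-bit BLASTN; extremely gappy best alignments could rank
  differently near the bitscore tie boundary.
* Expected amplicon length for mixed-forward pairs assumes equal-length
  forward primers (the first listed is used).
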