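# Methods

This note documents the models, conventions and design choices behind
`barcodegap`, in the order data flows through the pipeline.

## Scope

The package evaluates how well the complete fungal ITS region and its
ITS1/ITS2 sub-regions discriminate species within a genus. It does **not**
download sequences: input is a FASTA of complete ITS sequences plus a
tab-separated metadata table (accession, genus, species, voucher, country),
optionally enriched from a second table by filling empty fields only. The
original survey's snapshot-dependent counts (tens of thousands of GenBank
records, subphylum compositions) are outside what a desk-scale re-run can
reproduce; the packaged 113-genus printed PCI/group tables and seeded
synthetic data stand in as the quantitative surface.

## Synthetic data generator

The simulator exists to give every downstream stage a known ground truth,
not to be a realistic model of ITS evolution.

**Sequence model.** Per genus, an ancestor is drawn uniformly over
{A,C,G,T} for ITS1 (default 220 bp) and ITS2 (default 240 bp) and carries a
fixed 158-bp synthetic 5.8S core (a packaged constant, not any organism's
sequence). Mutation is i.i.d. per-site substitution to a uniformly random
*different* base; there are no indels, so every pairwise p-distance has an
enumerable ground truth and the generated regions tile the sequence
exactly.

**Divergence parametrization.** `intra_div` is the per-site divergence of an
individual from its species consensus; `inter_div` is the *total*
per-lineage (root-to-tip) divergence governing between-species comparisons.
Internally the species branch mutates at `inter_div − intra_div` and the
individual branch at `intra_div`. This nesting is deliberate: with
`inter_div == intra_div` the species branch collapses to zero, so
intraspecific and interspecific distances are drawn from the same process
and no barcode gap exists — the natural "null" dataset. With
`inter_div ≫ intra_div` the gap is clear and PCI is 100% by construction.
The 5.8S mutates at `s58_div` (default 0) so the extraction anchors stay
exact on clean data. Divergence defaults (`inter_div` 0.10, `intra_div`
0.01) are free knobs of the simulator, not estimates of any real genus.

**Sampling design.** Default 5 species × 4 sequences per genus (≥ 3
sequences per species required); localities are assigned round-robin from a
pool of country names (default 6) so every clean species spans ≥ 3 distinct
localities and survives the locality filter. Voucher ids and pseudo-Latin
epithets are generated deterministically.

**Seeding.** One master seed; every genus, species, individual and defect
channel draws from a substream keyed by CRC-32 hashes of its textual path
(`numpy SeedSequence(entropy=[seed, crc32(key), ...])`). Adding a genus or a
channel never perturbs another's draws, and identical (config, seed) yield
byte-identical FASTA/TSV output.

**Defect channels.** Five independent Bernoulli channels mirror the
curation filters: an IUPAC ambiguity code replaces one base; the voucher is
blanked; the organism name gains an inconclusive token (`sp.`, `aff.`,
`cf.`, `uncultured`); the sequence is truncated below 400 bp or padded above
800 bp; the locality is blanked. The length corruption deliberately
preserves both 5.8S anchors (truncation keeps a non-empty ITS2 stub;
padding appends to the 3′ end), so a length-corrupted record fails the
*length* filter rather than region extraction — this is what makes exact
per-stage bookkeeping possible. Channels are applied in the order length →
ambiguity → voucher/name/locality so the injected ambiguous base cannot be
truncated away.

**What the simulator does not model** — and hence what passing tests do not
show about real data: rate heterogeneity across sites, indels and length
variation within a genus, coalescent structure, chimeras, sequencing error
profiles, and misidentified (cryptic) species. Real ITS alignments are
harder than the simulated ones; results on synthetic data validate the
pipeline's logic, not the markers themselves.

## Curation cascade

Filters run in a fixed order (voucher → ambiguity → names → ITS
completeness → lengths → localities → min species), each a pure function
with per-stage in/out counts and removed accessions recorded.

* The name filter matches tokens after splitting on whitespace and
  stripping trailing periods, case-insensitively — `cf` inside an epithet
  like *crassifolia* is not a hit. Records without a concrete epithet are
  also removed.
* The length interval is **inclusive**: 400 ≤ len(ITS1+5.8S+ITS2) ≤ 800,
  and ITS1, ITS2 each ≥ 100 bp. (The upstream description of the window is
  internally inconsistent about strictness; the inclusive reading matches
  its stated intent of excluding sequences *outside* the interval.)
* The locality filter first drops records with no locality, then removes
  every record of species spanning fewer than 3 distinct localities
  (exact string equality after trimming and case-folding, country-level).
  Whether unlocated records should count toward the span is genuinely
  ambiguous upstream; dropping them first is the declared choice here.
* Group filters (localities, min species per genus) are the only stages
  where the fate of one record depends on others; the property tests pin
  down exactly this: record-level filters are monotone and idempotent,
  group filters may cascade.

## Region extraction

A deliberately simple, exactly testable stand-in for profile-HMM ITS
extractors: the 5.8S is located by its first and last 20 bases, matched by
sliding-window Hamming distance with a budget of 2 mismatches. Best hit =
fewest mismatches, then leftmost; two equally good *non-overlapping* hits
make the split ambiguous. Failure (missing/ambiguous anchor, empty part) is
a `None` value, not an exception — in curation it is a removal. Coordinates
are 0-based half-open everywhere. This is adequate for curated complete-ITS
inputs; it is not a general rDNA annotator and has no sensitivity target on
degraded real data.

## Distances

Pairwise Needleman–Wunsch global alignment with match +1, mismatch −1,
linear gap −2; ties in the traceback prefer diagonal, then up, making every
alignment deterministic. Scores are declared here because the original
workflow delegated them to an external aligner's defaults; per-genus MSA
quality is not what is being evaluated, and independent pairwise alignments
are oracle-checkable (the test suite enumerates all alignments of short
pairs). A `prealigned` mode ingests an external multiple alignment instead
and applies only the p-distance column rules, for users who prefer MUSCLE
or MAFFT.

Uncorrected p-distance = mismatches / columns where both sequences have a
base (pairwise deletion, the common convention; complete deletion is a
switch on the matrix builder). A pair with no comparable column is an
error, not a zero. The inner DP loop is JIT-compiled with numba when
available; the pure-Python path is semantically identical.

## PCI and gap classification

* Identification is **strict**: `min_inter > max_intra`; a tie fails.
* Species with one sequence are excluded from PCI scoring (no intraspecific
  distance exists) but remain as interspecific partners; attrition during
  curation can produce such singletons even though the ≥ 3-locality rule
  makes them rare.
* The PCI denominator is the number of scorable species.
* Boxplots: quartiles by linear interpolation (numpy default), whiskers at
  the most extreme data within 1.5·IQR of the box, outliers beyond. Both
  conventions are the plotting-software defaults the original analysis
  leaned on, and are configurable in spirit (box_stats is a pure function).
* Classification order: poor (intra Q3 ≥ inter Q1, or median(intra) ≥
  median(inter)) → intermediate (intra upper whisker ≥ inter lower whisker)
  → good. "Intraspecific values superior to interspecific" is
  operationalized as the median comparison — boxplot-native, since no
  statistic was specified upstream; box overlap is one-sided because intra
  is expected below inter. The original classifications were made by visual
  inspection, so exact reproduction of every published group assignment is
  not claimed; the thresholds here are a declared, deterministic
  operationalization.
* Groups: 1 = all three good; 4 = all three poor; 2 = at least one good
  (recommended markers = the good ones); 3 = the rest. The 2-vs-3 boundary
  is formalized as presence of any good marker; all 27 class combinations
  map to exactly one group.
* Two distance pools are kept deliberately distinct: PCI uses per-species
  extrema (max intra, min inter), while the boxplots pool *all* pairwise
  distances.

## Published-table reproduction

The fixtures are verbatim transcriptions of the printed survey tables
(113 genera; group sizes 54/24/24/11). Recomputed from them: the
strictly-above-mean fractions are exactly 60/113 (53.1%), 52/113 (46.0%)
and 55/113 (48.7%), and the tie-corrected Spearman correlations match the
published 0.8825 / 0.9102 / 0.8158 to four decimals — strong evidence the
transcription is faithful. The recomputed column means (64.47 / 60.21 /
58.99) sit about a point above the published 63 / 59 / 58 because the
published means were averaged from unrounded per-genus PCIs while the
printed table holds integers; the reproduction report therefore compares
means at printed-integer precision, where each delta is exactly 1 point.

## Problem sizes and numerical choices

The test suite and the acceptance script use desk-scale sizes chosen as the
package's own defaults: 50 genera per synthetic-recovery condition at
4 species × 3 sequences (clear gap: intra 0.01 / inter 0.25; null: both
0.15), a 1,000-record defect dataset (50 genera × 4 species × 5 sequences)
for curation bookkeeping, and 100 random genera of ≤ 12 sequences for
brute-force oracle equivalence. Distances are exact rationals represented
in double precision; no tolerance is needed anywhere except the ±0.01 band
on Spearman correlations and ±1 point on rounded means in the reproduction
report.

## Known limitations

* The gap classification thresholds are a formalization of a visual
  procedure; borderline genera can legitimately land differently.
* Pairwise alignment can differ from an MSA-based distance for gappy, hard
  to align genera; use the prealigned path when that matters.
* The simulator's no-indel assumption means the aligner's gap handling is
  exercised only by the unit tests, not by the synthetic pipeline runs.
* Locality equality is string equality; no gazetteer normalization.
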