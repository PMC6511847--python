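# Methods

## Problem and approach

The package locates candidate RiPP precursor-peptide genes near a designated
RiPP tailoring enzyme (RTE). Precursor genes are short (here 20–120 aa), often
unannotated, and share no sequence family across RiPP classes, so the search
is anchored on the tailoring enzyme instead: every short ORF in the enzyme's
neighbourhood is scored for coding potential, filtered against existing
annotation, and retrieved by a top-N-plus-threshold rule; peptides outside the
retrieval window are rescued when they carry a known precursor-domain
signature. Retrieved peptides from many regions are then grouped into
similarity networks, whose larger components flag recurrent (hence likely
authentic) precursor families.

All coordinates are 0-based half-open internally; GenBank conversion happens
only at the file boundary. An ORF span includes its stop codon, so a span of
`n` nt encodes `n/3 − 1` residues.

## Coding-potential score

The published workflow obtains its gene-likeness score from a modified
Prodigal build. This package uses its own documented scorer with the same
contract (higher = more gene-like, comparable against a fixed threshold),
self-trained per region:

- **Hexamer component.** In-frame (codon-phase) 6-mer counts over annotated
  CDS ≥ 300 nt versus all overlapping 6-mers of both strands of the region;
  log-odds with add-one smoothing over the 4096 keys; hexamers containing N
  contribute 0. A candidate's coding score is the mean log-odds over its span
  (stop codon excluded) × peptide length × 0.55.
- **RBS component.** (6-mer, spacer-bin) weights from the 21 nt upstream of
  training-gene starts against the background 6-mer frequency, spacers 3–15 nt
  in four bins; a candidate scores the best upstream match × 2.2, floored at 0.
- **Start component.** Smoothed ATG/GTG/TTG usage of the training genes
  against a uniform prior, × 1.0.

With fewer than 3 training genes the model is returned untrained (all-zero
tables, logged, flagged in candidate notes). The three multipliers are the
fixed calibration, committed as constants in `orf_caller.py` and never fitted
at run time. They were chosen once against the seeded synthetic-region suite
so that planted authentic genes typically score above the default retrieval
threshold of 7.5 (fixture median ≈ 8, ≈ 13 after the same-strand reward) while
random intergenic ORFs fall well below it (fixture median ≈ −8). The absolute
scale of the thresholds (7.5 default, 15 for stringent analyses) therefore has
meaning only relative to this calibration, which is the package's own.

Candidates sharing a stop codon: every in-frame upstream start is emitted as a
distinct candidate and selection is purely score-based downstream. One
consequence is visible in the distant bucket, which applies no score
selection: a rescued precursor can appear once per upstream start when the
domain core lies downstream of all of them.

## Retrieval rules

- Overlap filter: strand-blind interval intersection ≤ 20 nt with every
  annotated gene.
- Peptide size window: 20–120 aa for unannotated candidates. Annotated genes
  encoding ≤ 120 aa join the pool, bypassing the overlap filter and the lower
  bound (they are the annotation); the RTE itself is excluded — it anchors the
  search. The same-strand reward (+5, applied exactly once, idempotence
  guarded) applies to annotated and unannotated items alike.
- Distance: gap between half-open intervals; overlap or abutment = 0.
- Selection within ±8 kb: top `fastaOutputLimit` (3) by score, ties broken by
  smaller distance then lower start (deterministic; the rule's source is
  silent on ties), plus all further items ≥ `prodigalScoreThresh`;
  deduplicated by (source accession, start, end, strand) so identical peptide
  sequences at different loci are all kept.
- Distant rescue: every non-retrieved candidate (no distance or score
  threshold) with ≥ 1 profile hit.

## Domain scanning

Profiles are per-position score tables over the 20-residue alphabet with a
per-profile reporting threshold, scanned ungapped at every offset; the best
window per profile is reported iff it reaches the threshold. Non-standard
residues score 0, making the scan invariant to X-padding. This replaces
profile-HMM search behind a small interface; it preserves the rescue contract
(a binary domain-present decision at a per-profile cutoff) without a profile
database. Real HMM gathering-cutoff semantics, glocal alignment, and E-values
are not modelled.

## Networking

All-vs-all Smith–Waterman under BLOSUM62 with affine gaps; a gap of length k
costs 11 + k (BLAST's convention for "open 11, extend 1"). Identity is counted
over alignment columns including gap columns; coverage is the aligned span of
the shorter peptide over its length. E-values use the Karlin–Altschul form
bit = (λ·S − ln K)/ln 2, E = m·n·2^(−bit) with fixed gapped constants
λ = 0.267, K = 0.041; with the E ≤ 10 cutoff the network topology is dominated
by the identity (≥ 40%), coverage (≥ 35%) and length (≥ 15 aa) thresholds, so
this approximation carries little risk. Edges are computed once per unordered
pair (symmetric); components are ranked by size, ties by smallest member id;
singletons are reported separately. Dereplication is greedy, longest first,
at ≥ 99% global identity over alignment columns (terminal gaps included).

## Mass arithmetic

Neutral mass = Σ residue monoisotopic masses + H₂O, then +42.010565 per
N-acetyl, +15.977156 (S − O) per backbone thioamide, −2.015650 per
desaturation; [M+zH]z⁺ = (M + z·1.007276)/z. The thioamide is modelled purely
as the O→S substitution on a specified inter-residue bond; the dehydro delta
is position-agnostic because −H₂ does not depend on the bond modified. The
H₂S neutral-loss screen reports fragment (and precursor–fragment) pairs whose
difference is within a Da tolerance (inclusive, default 0.01) of 33.987721.
Comparative feature matching uses |Δm/z| ≤ 100 mDa, |Δrt| ≤ 0.1 min and an
intensity floor of 100,000; a feature is unique to a group iff present in all
of that group's replicates and matched in none of the others' — the
all-replicates consensus rule is this package's own choice, as vendor
matching semantics vary.

## Synthetic regions

`RegionSpec` defaults define the study conditions: 25 kb contigs at 65% GC
with 10 annotated genes (one deliberately short, 85–110 aa), a centered
tailoring enzyme of 400–600 codons, AGGAGG RBS at 5–9 nt spacers, and planted
unannotated precursors (20–120 aa) at exact distances/strands from the RTE.
Genes and precursors share a GC-weighted codon-usage table; intergenic
background is random at the GC target with a stop codon injected roughly
every 16 frame-0 codons to damp accidental long ORFs. Distant domain-bearing
precursors embed a fixed 15-residue toy consensus matched by
`toy_profiles()` (a synthetic stand-in for characterized precursor-domain
models). Everything is deterministic per seed.

The peptide-family generator grows families from random 50-aa ancestors by
per-site substitution. At rate 0.15 members share ≈ 72% pairwise identity
(well above the 40% edge threshold); unrelated random peptides fall below the
thresholds *with high probability*, not always: occasionally a random pair
passes all four edge criteria at the boundary (e.g. a 20-column local hit at
exactly 40.0% identity), attaching a singleton to a family — the same chance
behaviour a BLAST-based network shows. Fixture tests therefore pin seeds, and
the family-recovery checks additionally assert that each recovered network is
label-pure.

What passing fixture tests shows: the enumeration, scoring, filtering,
selection, rescue and networking logic behave as specified under realistic
compositional contrast. What it does not show: recovery rates on real
genomes, where codon usage is taxon-specific, annotation is imperfect, and
precursor domains come from real HMM libraries.

## Numerical and degenerate-input choices

- Scores are written with 3 decimals in tables; rows sort by (source
  accession, distance, start) — re-runs are byte-identical.
- Compound (join) CDS locations are rejected with a clear error; target
  inputs are single-span bacterial CDS.
- Window extraction clips silently at contig ends (logged); partially
  overlapping features are kept with clipped coordinates and a "partial"
  note, and the CDS frame invariant is not asserted for them.
- RTE designation: `/ripper_rte` qualifier > explicit identifier > CDS
  nearest the record midpoint (fallback, logged).
- Tolerances on masses and feature matching are inclusive (≤).
- An all-region-failure aborts a run; individual failing regions are logged
  and skipped.

## Problem sizes used in the test suite

Oracle-equivalence suites use 500 random sequences ≤ 1 kb (ORF scanner), 200
random peptide pairs ≤ 12 aa (exhaustive Gotoh DP), random graphs ≤ 50 nodes
(components), and 1000 randomized candidate sets (selection rule).
Recovery properties use 50 seeded 25 kb regions with one in-window and one
distant planted precursor each. The full suite runs in well under a minute on
one CPU.

## Known limitations

- The coding scorer is not Prodigal: no GC frame plot, no start-site
  refinement, no dicodon/metagenomic models; scores are comparable only
  within this package's calibration.
- The PSSM scanner is ungapped; profiles with indel-tolerant matches in real
  HMM search may be missed.
- E-values use fixed Karlin–Altschul constants rather than per-query
  estimation.
- The mass module does no peak picking, isotope scoring or vendor-format
  parsing; inputs are plain feature/fragment tables.
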