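# Methods

## Problem and model

A large insertion (here the canonical case: an AluYa8 retrotransposon in
*MAK* exon 9 — 280 nt Alu body, a poly-adenine stretch, and a 13 bp
target-site duplication, 353 nt in total) creates two novel junctions in the
carrier genome. Short reads spanning a junction are systematically
soft-clipped or mis-placed by aligners, so alignment-based callers miss the
event. `junctionscan` detects the insertion by exact string matching on the
raw reads:

* **Stage 1 — probe search.** A junction probe is a *k*-mer (default 23)
  that straddles the mutant 5' junction; its wildtype counterpart straddles
  the intact site. A read counts as a hit if it contains the probe or its
  reverse complement as an exact substring. Quality strings are ignored; a
  read shorter than the probe simply cannot hit; N never matches. Only
  parsed sequence lines are searched — a raw line-grep could in principle
  match header or quality lines, an artifact class parsing removes.
* **Stage 2 — full-read validation.** A stage-1 hit is a *full match* if
  the entire read is an exact substring (either orientation) of the
  allele's extended context: `flank_len` (default 150) reference bases each
  side of the site, with the inserted element between them on the mutant
  context. The wildtype context is thus exactly 300 bp. Exactness is
  deliberate: it removes probe-carrying artifacts (chimeric reads, index
  bleed-through) at the cost of discarding reads with any sequencing error
  or nearby second-site SNP — a conservative trade documented below.
* **Genotyping.** Calls use full-match counts only. With
  `min_support = 3` (tunable): mutant ≥ 3 and wildtype = 0 → homozygous
  mutant; both ≥ 3 → heterozygous; mutant = 0 and wildtype ≥ 3 → wildtype;
  anything else → no-call with a `low_coverage` flag. True carriers show
  ≥ 11 full matches even at the low end of junction coverage while
  artifacts contribute 1–2 reads, so 3 separates the regimes with wide
  margin. Allele fractions `mut/(mut+wt)` are reported from both counter
  tiers at full precision (two decimals in reports, NA for 0/0) and are
  never thresholded — heterozygote `af_all` as low as ~0.28 occurs under
  capture bias and must not invalidate a call. Normalizing counts by total
  reads discriminates true from false positives *worse* than full-match
  validation, so `total_reads` is reported for QC only.

### Flags

* `probable_false_positive`: zero mutant full matches but 1–2 mutant probe
  hits — the signature of rare spurious probe *k*-mers.
* `probe_only_discordance`: an allele with more probe hits than the
  false-positive band (> `fp_flag_max` = 2) yet zero full matches —
  e.g. contaminating reads from a flowcell neighbor. Applied to either
  allele.
* `low_coverage`: accompanies every no-call.

## Probe and context construction

From an insertion definition (left flank, right flank, inserted element —
explicit strings; genomic coordinates are metadata only, avoiding genome
build and 0/1-base ambiguity), the mutant probe is the last `left_len` nt
of the left flank plus the first `k − left_len` nt of the insert
(`left_len` defaults to `k // 2`, a symmetric straddle), and the wildtype
probe substitutes the start of the right flank. Construction enforces
`k ≥ 8`, `1 ≤ left_len ≤ k−1`, and sufficient flank/insert lengths.

Context construction verifies probe specificity: each probe (either
orientation — reads and therefore probes are orientation-free) must occur
in its own context and in neither orientation in the other allele's
context, else an ambiguous-probe error advises a longer or repositioned
probe. Target-site duplications (TSDs) are the canonical trap: the TSD
reappears at the insertion's 3' junction, so a wildtype probe that does not
span the *entire* duplicated site plus at least one base 5' of it is
reconstituted on the mutant allele. The test suite exercises exactly this
failure.

The built-in `MAK_Alu_ex9` probe set ships the canonical 23-mers verbatim
(`GAAAAAAGGAGGCCGGGCGCGGT` / `CGAAATGGAGAATCTTTTTTCCT`, with reverse
complements `ACCGCGCCCGGCCTCCTTTTTTC` / `AGGAAAAAAGATTCTCCATTTCG`). The
genomic flanks and the full deposited Alu element are not bundled; the
probes are paired with a **synthetic** stand-in locus (seeded random 400 bp
flanks, 353 nt insert = 280 body + 60 poly-A + 13 TSD) engineered so both
probes sit at geometrically correct junctions: the wildtype probe's
plus-strand form spans the junction covering the full TSD plus two bases 5'
of it, so it is not reconstituted at the 3' junction. Users scanning real
data for other events supply their own flanks via the TSV config, from
which real contexts are derived. Sequences are uppercased on ingest, and
IUPAC ambiguity codes (including N) are rejected in probes and contexts —
exact matching renders them meaningless.

## Read simulator

The simulator materializes the two local haplotypes (wildtype =
left + right flank; mutant = left + insert + right) and draws
`round(coverage × locus_len / read_length)` reads, where `locus_len` is the
allele-fraction-weighted mean haplotype length. `allele_fraction` is
defined as the fraction of sequencing *depth* contributed by the mutant
haplotype: a diploid heterozygote sequences each chromosome at half depth,
and because the insertion-bearing haplotype is longer it contributes
proportionally more reads. Each read therefore picks the mutant haplotype
with probability `af·|mut| / (af·|mut| + (1−af)·|wt|)`, which makes the
expected fraction of junction-spanning reads equal `allele_fraction` — the
property the parameter-recovery tests check. Starts are uniform, strands
50/50, substitution errors independent per base at `error_rate`
(default 0.001), qualities constant (the scanner ignores them); output is
deterministic given the seed. Paired mode draws a fragment
(Normal insert size, default 300 ± 30, clipped into the haplotype) and
emits both mates; the scanner pools mates like any other reads.

Defaults mirror the targeted-capture regime the method was characterized
in: 121 bp reads, ~50× locus coverage, per-base substitution error 0.001
(Phred ~30 platform error after the exact-match filter's perspective), 60 nt
poly-A (reported poly-A lengths for this element range ~54–60; the length
is a parameter and nothing downstream depends on it). A 121 nt read cannot
span the 353 nt element plus both junctions, so every informative read
covers exactly one junction — a structural property the suite asserts.

The truth manifest records, per read, the source haplotype, start, strand,
error positions, and whether the read fully covers each allele's probe
interval (located positionally on the haplotype, not by re-scanning the
read). With `error_rate = 0`, scanner full-match counters equal the
manifest's junction-spanning counts exactly — the central oracle test.

### What the simulator does not model

Capture bias (the real driver of heterozygote `af_all` down to ~0.28), PCR
duplicates, platform-specific error profiles, indel sequencing errors, and
quality variation. Indel errors in particular would defeat exact full-read
matching — that is the documented behavior of the exact-match design, not a
simulator gap to paper over. Passing tests therefore demonstrate
correctness of the counting and calling machinery under the stated read
model, not robustness to capture or chemistry artifacts in real data.

## Numerical and edge-case choices

* Counters are plain integers; allele fractions are exact IEEE doubles,
  rounded only at the reporting boundary (2 decimals, NA for 0/0).
* Empty FASTQ input yields an all-zero result and a no-call, not an error;
  truncated or wrapped (multi-line) FASTQ is a hard parse error naming file
  and record index — silently mis-counting a wrapped file is worse than
  refusing it. gzip is detected by magic bytes, not file extension.
* A read may in principle hit both alleles' probes; the two searches are
  independent (matching two independent grep invocations) and each
  counter is bounded by `total_reads`.
* Scanning without extended references reports full-match counters as
  not-computed (NA); genotype calling then refuses rather than silently
  degrading to probe-only calls.
* Batch mode isolates per-sample failures (`status=error` rows) — a
  thousand-sample screen must not die on one truncated file. Reports carry
  the tool version and no timestamps, so identical inputs produce
  byte-identical outputs.
* Multi-probe scans evaluate all probe sets in one streaming pass to keep
  I/O linear in file size.

## Test problem sizes

The sensitivity/specificity check classifies 10 homozygous-mutant and 10
wildtype simulated samples at 50× (≈ 480 reads each over the ~1.2 kb
locus); oracle-equivalence runs 50 random configurations (coverage 3–25×,
read length 50–150, error 0–0.01, plain and gzipped, single and paired
end); allele-fraction recovery pools full-match counts over 100
heterozygous samples and requires agreement with 0.5 within three binomial
standard errors at the realized junction depth. These sizes make the whole
suite run in seconds while leaving the statistical assertions sharp.

## Known limitations

Known-event screening only: the junction sequence must be known in advance
and must not pre-exist in the genome; de novo breakpoint discovery is out
of scope, as are BAM/CRAM input, fuzzy matching, read deduplication and
mate-pair-aware logic. Probe uniqueness is validated only against the
supplied contexts, not genome-wide. A second-site SNP adjacent to the
junction suppresses full matches (false-negative risk inherent to exact
matching); the probe-hit tier remains visible in reports precisely so such
discordances surface as flags rather than silent drops.
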