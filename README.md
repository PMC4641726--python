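# junctionscan

Alignment-free detection of known large insertions — such as the Alu
retrotransposon insertion in *MAK* exon 9 that causes autosomal-recessive
retinitis pigmentosa — directly in raw NGS reads (FASTQ or FASTQ.gz).

Standard alignment-based variant callers routinely miss insertions longer
than a fraction of the read length: aligners soft-clip the inserted sequence
off junction-spanning reads and report an artifactually normal locus.
`junctionscan` sidesteps alignment entirely. For clinical and research labs
that already hold archives of raw reads, it answers "does this sample carry
insertion X?" in a single streaming pass, with no realignment and no wet-lab
assay.

## Method

For a known insertion with left flank *L*, inserted element *I* and right
flank *R*:

1. **Junction probes.** A *k*-mer (default *k* = 23) spanning the novel
   5' junction *L·I* exists only on the mutant allele; a matching *k*-mer
   spanning the intact site *L·R* exists only on the wildtype allele. Each
   read is tested for an exact occurrence of either probe in either
   orientation (reads are unoriented), giving stage-1 counts
   `mut_probe_hits` and `wt_probe_hits`.
2. **Full-match validation.** Each stage-1 hit is promoted to a "full
   match" only if the *entire* read is an exact substring (either
   orientation) of an extended reference context: 150 bp of reference flank
   on each side of the site, with the inserted element included for the
   mutant context. This removes chimeric-read and index bleed-through
   artifacts that carry the probe *k*-mer but not the surrounding sequence.
3. **Genotyping.** The mutant allele fraction is
   `AF = mut / (mut + wt)`, computed from probe hits (`af_all`) and from
   full matches (`af_full`). Calls use full-match counts only, with
   `min_support = 3` reads to assert an allele: mut ≥ 3 & wt = 0 →
   `homozygous_mutant`; both ≥ 3 → `heterozygous_mutant`; mut = 0 & wt ≥ 3 →
   `wildtype`; otherwise `no_call`. Probe-only mutant evidence (1–2 reads)
   is flagged `probable_false_positive`; larger probe-only counts on either
   allele are flagged `probe_only_discordance`.

The canonical *MAK*-Alu probe pair is built in
(`--probe-id MAK_Alu_ex9`); probe sets for other insertions are supplied as
a small TSV of either literal probes or flank+insert sequences, from which
probes and contexts are derived and validated (a probe that pre-exists on
the other allele — e.g. a wildtype probe that does not span the whole
target-site duplication — is rejected as ambiguous).

A seeded read simulator (`junctionscan simulate`) generates FASTQ over
wildtype/mutant haplotypes with configurable allele fraction, coverage,
read length and substitution error rate, plus a ground-truth manifest, so
the whole pipeline is testable without patient data.

## Worked example

Simulate a homozygous-mutant sample at 50× coverage and scan it:

```sh
$ junctionscan simulate --af 1.0 --coverage 50 --seed 7 --out-prefix patient1
$ junctionscan scan --probe-id MAK_Alu_ex9 --sample-id patient1 --fastq patient1.fastq
# junctionscan 0.1.0
sample	probe_id	mut_probe_hits	mut_full	wt_probe_hits	wt_full	af_all	af_full	call	flags	total_reads	files
patient1	MAK_Alu_ex9	37	36	0	0	1.00	1.00	homozygous_mutant	.	476	patient1.fastq
```

Of 476 simulated reads, 37 contain the mutant junction 23-mer and 36 of
those match the extended mutant context in full (one read carries a
simulated sequencing error); no read supports the wildtype site, so the
mutant allele fraction is 1.00 and the sample is called homozygous mutant.
Cohorts run via `junctionscan batch --manifest samples.tsv` (one row per
sample, tab-separated FASTQ paths; a failing sample is reported as
`status=error` without aborting the batch).

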