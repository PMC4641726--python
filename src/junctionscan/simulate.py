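"""Synthetic read simulation over an insertion locus, with ground truth.

Generates FASTQ with the structure the scanner assumes: reads drawn
uniformly from the wildtype and mutant haplotypes of an insertion locus,
with a configurable mutant allele fraction, strand chosen 50/50,
substitution-only sequencing errors, and constant high quality strings
(quality is ignored by the scanner). A truth manifest records, per read,
the source haplotype, start, strand, the error positions, and whether the
read fully covers each allele's junction probe site — the quantities oracle
tests compare scanner counters against.

The model is deliberately minimal: uniform coverage (no capture bias), no
PCR duplicates, no indel errors (an indel would defeat exact full-read
matching by design — that is documented scanner behavior, not a bug).
"""

from __future__ import annotations

import gzip
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .fastq_engine import _rc_read
from .probe_design import MutationDefinition, ProbeSet, _clean_dna

__all__ = [
    "SimulationConfig",
    "ReadTruth",
    "TruthManifest",
    "make_alu_like_insert",
    "build_haplotypes",
    "simulate_sample",
]

_QUAL_CHAR = "I"  # constant Phred 40


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated sample.

    ``allele_fraction`` is the fraction of sequencing depth contributed by
    the mutant haplotype (1.0 = homozygous mutant, 0.5 = heterozygote under
    unbiased capture, 0.0 = wildtype). Depth, not read count, is what a
    diploid sample splits between alleles: the insertion-bearing haplotype
    is longer and therefore yields proportionally more reads, and defining
    the fraction on depth makes the junction-spanning read fraction converge
    to ``allele_fraction``. ``coverage`` is mean total depth over the locus;
    read length defaults to 121 nt (a typical targeted-panel paired-end
    read, and short enough that no single read can span a full ~350 nt Alu
    insertion). ``error_rate`` is the per-base substitution probability.
    """

    mutation: MutationDefinition
    allele_fraction: float
    coverage: float
    read_length: int = 121
    error_rate: float = 0.001
    paired: bool = False
    insert_size_mean: float = 300.0
    insert_size_sd: float = 30.0
    seed: int = 0
    polyA_len: int = 60

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_fraction <= 1.0:
            raise ValueError(f"allele_fraction {self.allele_fraction} not in [0, 1]")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError(f"error_rate {self.error_rate} not in [0, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


@dataclass(frozen=True)
class ReadTruth:
    """Ground truth for one simulated read."""

    read_id: str
    haplotype: str  # "mut" | "wt"
    start: int  # 0-based offset of the read on its haplotype
    strand: str  # "+" | "-"
    error_positions: tuple[int, ...]  # read coordinates, post-orientation
    spans_mut_probe: bool
    spans_wt_probe: bool


@dataclass
class TruthManifest:
    """Per-read truth plus per-sample junction-spanning totals."""

    reads: list[ReadTruth] = field(default_factory=list)

    @property
    def mut_junction_reads(self) -> int:
        return sum(1 for r in self.reads if r.spans_mut_probe)

    @property
    def wt_junction_reads(self) -> int:
        return sum(1 for r in self.reads if r.spans_wt_probe)

    def to_tsv(self) -> str:
        lines = [
            "read_id\thaplotype\tstart\tstrand\terror_positions\t"
            "spans_mut_probe\tspans_wt_probe"
        ]
        for r in self.reads:
            lines.append(
                f"{r.read_id}\t{r.haplotype}\t{r.start}\t{r.strand}\t"
                f"{','.join(map(str, r.error_positions)) or '.'}\t"
                f"{int(r.spans_mut_probe)}\t{int(r.spans_wt_probe)}"
            )
        lines.append(
            f"#totals\tmut_junction_reads={self.mut_junction_reads}\t"
            f"wt_junction_reads={self.wt_junction_reads}"
        )
        return "\n".join(lines) + "\n"


def make_alu_like_insert(
    alu_body_len: int,
    polyA_len: int,
    tsd: str,
    seed: int = 0,
    rng: Optional[random.Random] = None,
) -> str:
    """Assemble an Alu-like inserted element: random body + poly-A + TSD.

    The element anatomy mirrors a young SINE integration: a retrotransposon
    body, a poly-adenine stretch, and a target-site duplication (a copy of
    the sequence immediately 5' of the insertion point, supplied by the
    caller). With a 280 nt body, a 60 nt poly-A and a 13 bp TSD the element
    totals 353 nt. The body is seeded random sequence — the scan algorithm is
    sequence-agnostic, so tests do not need the true Alu consensus.
    """
    if alu_body_len < 0 or polyA_len < 0:
        raise ValueError("lengths must be >= 0")
    if tsd:
        tsd = _clean_dna(tsd, what="tsd")
    rng = rng if rng is not None else random.Random(seed)
    body = "".join(rng.choice("ACGT") for _ in range(alu_body_len))
    return body + "A" * polyA_len + tsd


def build_haplotypes(mut: MutationDefinition) -> tuple[str, str]:
    """Materialize the two local haplotypes: (wildtype, mutant).

    wildtype = left_flank + right_flank; mutant = left_flank + inserted_seq +
    right_flank.
    """
    wt = mut.left_flank + mut.right_flank
    mt = mut.left_flank + mut.inserted_seq + mut.right_flank
    return wt, mt


def _probe_interval(haplotype: str, probe: str) -> Optional[tuple[int, int]]:
    """Half-open interval of the probe's unique occurrence, or None."""
    i = haplotype.find(probe)
    if i < 0:
        return None
    if haplotype.find(probe, i + 1) >= 0:
        raise ValueError("probe occurs more than once on the haplotype")
    return (i, i + len(probe))


def _apply_errors(
    seq: str, error_rate: float, rng: random.Random
) -> tuple[str, tuple[int, ...]]:
    if error_rate == 0.0:
        return seq, ()
    chars = list(seq)
    positions = []
    for i, base in enumerate(chars):
        if rng.random() < error_rate:
            chars[i] = rng.choice([b for b in "ACGT" if b != base])
            positions.append(i)
    return "".join(chars), tuple(positions)


def simulate_sample(
    cfg: SimulationConfig,
    out_prefix: str | Path,
    probe_set: Optional[ProbeSet] = None,
    gzip_output: bool = False,
) -> tuple[list[Path], TruthManifest]:
    """Simulate one sample; write FASTQ file(s) and return paths + truth.

    The read count is ``round(coverage * locus_length / read_length)`` with
    ``locus_length`` the allele-fraction-weighted mean haplotype length
    (mates in paired mode count toward it). Each read/fragment picks the
    mutant haplotype with the depth-preserving probability
    ``af * |mut| / (af * |mut| + (1 - af) * |wt|)``, a uniform start, and a
    50/50 strand; substitution errors are applied at ``error_rate``.
    Deterministic given ``cfg.seed``.

    When ``probe_set`` is given, the manifest's junction-spanning bits mark
    reads whose interval fully covers that allele's probe occurrence on the
    source haplotype (located positionally, not by rescanning the read).

    Single-end mode writes ``<prefix>.fastq``; paired mode writes
    ``<prefix>_R1.fastq`` and ``<prefix>_R2.fastq`` (``.gz`` appended when
    ``gzip_output``).
    """
    wt_hap, mut_hap = build_haplotypes(cfg.mutation)
    if cfg.read_length > len(wt_hap):
        raise ValueError(
            f"read_length {cfg.read_length} exceeds wildtype haplotype "
            f"length {len(wt_hap)}"
        )
    mut_iv = _probe_interval(mut_hap, probe_set.mut_probe) if probe_set else None
    wt_iv = _probe_interval(wt_hap, probe_set.wt_probe) if probe_set else None
    if probe_set and wt_iv is None:
        # the wildtype probe may be stored minus-strand; locate its rc
        wt_iv = _probe_interval(wt_hap, probe_set.wt_probe_rc)
    if probe_set and mut_iv is None:
        mut_iv = _probe_interval(mut_hap, probe_set.mut_probe_rc)

    rng = random.Random(cfg.seed)
    af = cfg.allele_fraction
    locus_len = af * len(mut_hap) + (1 - af) * len(wt_hap)
    # probability that a read comes from the mutant haplotype such that each
    # haplotype receives depth proportional to its allele fraction
    p_mut = af * len(mut_hap) / locus_len
    n_frags = round(cfg.coverage * locus_len / cfg.read_length)
    if cfg.paired:
        n_frags = max(1, n_frags // 2)

    manifest = TruthManifest()
    out_prefix = Path(out_prefix)
    suffix = ".fastq.gz" if gzip_output else ".fastq"

    def _emit(fh, read_id: str, hap_name: str, hap: str, start: int, strand: str):
        raw = hap[start : start + cfg.read_length]
        if strand == "-":
            raw = _rc_read(raw)
        seq, errs = _apply_errors(raw, cfg.error_rate, rng)
        fh.write(f"@{read_id}\n{seq}\n+\n{_QUAL_CHAR * len(seq)}\n")
        end = start + cfg.read_length
        manifest.reads.append(
            ReadTruth(
                read_id=read_id,
                haplotype=hap_name,
                start=start,
                strand=strand,
                error_positions=errs,
                spans_mut_probe=(
                    hap_name == "mut"
                    and mut_iv is not None
                    and start <= mut_iv[0]
                    and end >= mut_iv[1]
                ),
                spans_wt_probe=(
                    hap_name == "wt"
                    and wt_iv is not None
                    and start <= wt_iv[0]
                    and end >= wt_iv[1]
                ),
            )
        )

    def _open(path: Path):
        if gzip_output:
            return gzip.open(path, "wt", encoding="ascii")
        return open(path, "w", encoding="ascii")

    if not cfg.paired:
        path = out_prefix.with_name(out_prefix.name + suffix)
        with _open(path) as fh:
            for i in range(n_frags):
                hap_name = "mut" if rng.random() < p_mut else "wt"
                hap = mut_hap if hap_name == "mut" else wt_hap
                start = rng.randrange(0, len(hap) - cfg.read_length + 1)
                strand = "+" if rng.random() < 0.5 else "-"
                _emit(fh, f"{cfg.mutation.id}_sim_{i}", hap_name, hap, start, strand)
        paths = [path]
    else:
        p1 = out_prefix.with_name(out_prefix.name + "_R1" + suffix)
        p2 = out_prefix.with_name(out_prefix.name + "_R2" + suffix)
        with _open(p1) as fh1, _open(p2) as fh2:
            for i in range(n_frags):
                hap_name = "mut" if rng.random() < p_mut else "wt"
                hap = mut_hap if hap_name == "mut" else wt_hap
                frag_len = max(
                    cfg.read_length,
                    min(
                        len(hap),
                        round(rng.gauss(cfg.insert_size_mean, cfg.insert_size_sd)),
                    ),
                )
                frag_start = rng.randrange(0, len(hap) - frag_len + 1)
                frag_end = frag_start + frag_len
                # R1 from the fragment 5' end on the plus strand, R2 the
                # reverse complement of the 3' end; pooled by the scanner.
                _emit(fh1, f"{cfg.mutation.id}_sim_{i}/1", hap_name, hap, frag_start, "+")
                _emit(
                    fh2,
                    f"{cfg.mutation.id}_sim_{i}/2",
                    hap_name,
                    hap,
                    frag_end - cfg.read_length,
                    "-",
                )
        paths = [p1, p2]
    return paths, manifest
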