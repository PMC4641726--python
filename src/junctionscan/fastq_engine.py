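"""Streaming two-stage probe search over FASTQ files.

Stage 1 tests each read for an exact occurrence of a junction probe in
either orientation (reads are unoriented). Stage 2 requires the *entire*
read to be an exact substring of an extended reference context spanning the
insertion site — the "full match" filter that removes chimeric-read and
index-bleed artifacts which happen to contain the probe k-mer.

Only parsed sequence lines are searched (a raw line-grep could in principle
hit read headers or quality strings); no deduplication, quality filtering or
mate-pair logic is applied — counts reflect unprocessed reads, and paired
files are simply pooled.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional, Sequence

from .probe_design import ExtendedReference, ProbeSet

__all__ = [
    "FastqParseError",
    "ReadRecord",
    "ScanResult",
    "iter_fastq",
    "probe_hit",
    "full_match",
    "scan",
    "scan_many",
]

# Permissive complement for read sequences: reads may carry N (and other
# IUPAC codes), which can never match an ACGT-only probe or context but must
# not crash orientation handling.
_READ_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN"
)


class FastqParseError(ValueError):
    """A FASTQ file is structurally invalid (truncated or wrapped records)."""


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: id, sequence (may contain N) and quality string."""

    read_id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FastqParseError(f"read {self.read_id!r} has an empty sequence")
        if len(self.sequence) != len(self.quality):
            raise FastqParseError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.quality)}"
            )


@dataclass
class ScanResult:
    """Per-sample counters for one probe set.

    ``*_probe_hits`` count reads containing the probe in either orientation;
    ``*_full`` count the subset whose entire sequence matches the allele's
    extended context (``None`` when no context was supplied). A read may in
    principle count for both alleles — the two probe searches are
    independent, like two separate grep invocations.
    """

    sample_id: str
    probe_id: str
    mut_probe_hits: int = 0
    mut_full: Optional[int] = 0
    wt_probe_hits: int = 0
    wt_full: Optional[int] = 0
    total_reads: int = 0
    files: tuple[str, ...] = ()


def _open_maybe_gzip(path: str | Path) -> io.TextIOBase:
    """Open text or gzip FASTQ, sniffing the gzip magic bytes (not the name)."""
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, encoding="ascii")


def iter_fastq(paths: Sequence[str | Path]) -> Iterator[ReadRecord]:
    """Stream every record of every file in order, in constant memory.

    Records must be strict 4-line FASTQ ('@' header, sequence, '+' separator,
    quality). Wrapped (multi-line sequence) records and truncated files raise
    :class:`FastqParseError` naming the file and record index. Sequences are
    uppercased.
    """
    for path in paths:
        with _open_maybe_gzip(path) as fh:
            record_idx = 0
            while True:
                header = fh.readline()
                if not header:
                    break
                seq = fh.readline()
                plus = fh.readline()
                qual = fh.readline()
                if not qual and not (seq and plus):
                    raise FastqParseError(
                        f"{path}: truncated record {record_idx} "
                        "(file length is not a multiple of 4 lines)"
                    )
                header, seq = header.rstrip("\n"), seq.rstrip("\n")
                plus, qual = plus.rstrip("\n"), qual.rstrip("\n")
                if not header.startswith("@"):
                    raise FastqParseError(
                        f"{path}: record {record_idx}: header does not start with '@'"
                    )
                if not plus.startswith("+"):
                    raise FastqParseError(
                        f"{path}: record {record_idx}: separator line does not start "
                        "with '+' (wrapped multi-line FASTQ is not supported)"
                    )
                if not qual:
                    raise FastqParseError(
                        f"{path}: truncated record {record_idx} (missing quality line)"
                    )
                yield ReadRecord(
                    read_id=header[1:].split()[0] if len(header) > 1 else "",
                    sequence=seq.upper(),
                    quality=qual,
                )
                record_idx += 1


def _rc_read(seq: str) -> str:
    return seq.translate(_READ_COMPLEMENT)[::-1]


def probe_hit(read: ReadRecord, probe: str, probe_rc: str) -> bool:
    """True iff the probe or its reverse complement occurs exactly in the read.

    Quality is ignored; N in the read never matches.
    """
    seq = read.sequence
    return probe in seq or probe_rc in seq


def full_match(read: ReadRecord, context: str) -> bool:
    """True iff the entire read (either orientation) is an exact substring of
    ``context``. Any mismatch — a sequencing error, a second-site SNP, an N —
    makes this False; reads longer than the context cannot match."""
    seq = read.sequence
    if len(seq) > len(context):
        return False
    return seq in context or _rc_read(seq) in context


def scan_many(
    sample_id: str,
    paths: Sequence[str | Path],
    targets: Sequence[tuple[ProbeSet, Optional[ExtendedReference]]],
) -> list[ScanResult]:
    """Scan all reads once, accumulating counters for several probe sets.

    A single streaming pass keeps I/O linear regardless of how many probe
    sets are screened. Per probe set and read: stage 1 tests the mutant and
    wildtype probes independently; a stage-1 hit is promoted to a full match
    if the whole read matches that allele's extended context.
    """
    results = [
        ScanResult(
            sample_id=sample_id,
            probe_id=ps.id,
            mut_full=0 if ext is not None else None,
            wt_full=0 if ext is not None else None,
            files=tuple(str(p) for p in paths),
        )
        for ps, ext in targets
    ]
    total = 0
    for read in iter_fastq(paths):
        total += 1
        for (ps, ext), res in zip(targets, results):
            if probe_hit(read, ps.mut_probe, ps.mut_probe_rc):
                res.mut_probe_hits += 1
                if ext is not None and full_match(read, ext.mut_context):
                    res.mut_full += 1
            if probe_hit(read, ps.wt_probe, ps.wt_probe_rc):
                res.wt_probe_hits += 1
                if ext is not None and full_match(read, ext.wt_context):
                    res.wt_full += 1
    for res in results:
        res.total_reads = total
    return results


def scan(
    sample_id: str,
    paths: Sequence[str | Path],
    probe_set: ProbeSet,
    ext_ref: Optional[ExtendedReference] = None,
) -> ScanResult:
    """Two-stage scan of one sample against one probe set.

    Without ``ext_ref`` only stage-1 probe counts are computed and the
    full-match counters are reported as not computed (``None``).
    """
    return scan_many(sample_id, paths, [(probe_set, ext_ref)])[0]
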