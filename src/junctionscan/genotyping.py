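"""Allele-fraction estimation and genotype calling from scan counters.

Calls are made on full-match counts only: the full-read validation stage is
what removes probe-only artifacts (chimeric reads, index bleed-through), so
probe-hit counts are reported and used for quality flags but never drive the
call. Read-count normalization by total reads is deliberately not a call
criterion — it discriminates true from false positives worse than the
full-match filter — so ``total_reads`` is carried for QC only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .fastq_engine import ScanResult

__all__ = [
    "CALL_HOM",
    "CALL_HET",
    "CALL_WT",
    "CALL_NONE",
    "FLAG_FP",
    "FLAG_LOWCOV",
    "FLAG_DISCORDANT",
    "CallThresholds",
    "GenotypeCall",
    "MissingFullMatchError",
    "allele_fraction",
    "call_genotype",
    "format_report",
    "REPORT_COLUMNS",
]

CALL_HOM = "homozygous_mutant"
CALL_HET = "heterozygous_mutant"
CALL_WT = "wildtype"
CALL_NONE = "no_call"

FLAG_FP = "probable_false_positive"
FLAG_LOWCOV = "low_coverage"
FLAG_DISCORDANT = "probe_only_discordance"


class MissingFullMatchError(ValueError):
    """Genotype calling requires full-match counters; supply an ExtendedReference."""


@dataclass(frozen=True)
class CallThresholds:
    """Thresholds for genotype calling.

    ``min_support``: minimum full-match reads to assert an allele. True
    positives carry >= 11 full matches even at the low end of junction
    coverage while artifact counts are 1-2 reads, so the default of 3
    separates the regimes with a wide margin.

    ``fp_flag_max``: probe-only mutant count at or below which (with zero
    mutant full matches) the probable-false-positive flag is raised.
    """

    min_support: int = 3
    fp_flag_max: int = 2

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if self.fp_flag_max < 0:
            raise ValueError("fp_flag_max must be >= 0")


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    probe_id: str
    af_all: Optional[float]
    af_full: Optional[float]
    call: str
    flags: frozenset[str] = frozenset()


def allele_fraction(mut_count: int, wt_count: int) -> Optional[float]:
    """Mutant allele fraction ``mut / (mut + wt)``.

    Returns ``None`` (reported as NA) when both counts are zero. Full
    precision is retained; reports round to two decimals.
    """
    if mut_count < 0 or wt_count < 0:
        raise ValueError(f"counts must be non-negative (got {mut_count}, {wt_count})")
    total = mut_count + wt_count
    if total == 0:
        return None
    return mut_count / total


def call_genotype(
    result: ScanResult, thresholds: CallThresholds = CallThresholds()
) -> GenotypeCall:
    """Categorical genotype from a ScanResult's full-match counters.

    With ``ms = min_support``:

    * ``mut_full >= ms`` and ``wt_full == 0``  -> homozygous_mutant
    * ``mut_full >= ms`` and ``wt_full >= ms`` -> heterozygous_mutant
    * ``mut_full == 0`` and ``wt_full >= ms``  -> wildtype
    * anything else -> no_call with a low_coverage flag

    Probe-only mutant evidence (``mut_full == 0`` but probe hits present) is
    flagged: up to ``fp_flag_max`` hits as a probable false positive, more as
    probe-only discordance. The discordance flag is applied symmetrically to
    a wildtype side whose probe hits all fail validation (the signature of a
    contaminating read population on a shared flowcell).
    """
    if result.mut_full is None or result.wt_full is None:
        raise MissingFullMatchError(
            "scan was run without an ExtendedReference; full-match counters are "
            "required for genotype calling"
        )
    mut_full, wt_full = result.mut_full, result.wt_full
    ms = thresholds.min_support
    flags: set[str] = set()

    if mut_full >= ms and wt_full == 0:
        call = CALL_HOM
    elif mut_full >= ms and wt_full >= ms:
        call = CALL_HET
    elif mut_full == 0 and wt_full >= ms:
        call = CALL_WT
    else:
        call = CALL_NONE
        flags.add(FLAG_LOWCOV)

    if mut_full == 0 and result.mut_probe_hits >= 1:
        if result.mut_probe_hits <= thresholds.fp_flag_max:
            flags.add(FLAG_FP)
        else:
            flags.add(FLAG_DISCORDANT)
    if wt_full == 0 and result.wt_probe_hits > thresholds.fp_flag_max:
        flags.add(FLAG_DISCORDANT)

    return GenotypeCall(
        sample_id=result.sample_id,
        probe_id=result.probe_id,
        af_all=allele_fraction(result.mut_probe_hits, result.wt_probe_hits),
        af_full=allele_fraction(mut_full, wt_full),
        call=call,
        flags=frozenset(flags),
    )


# ---------------------------------------------------------------------------
# TSV reporting
# ---------------------------------------------------------------------------

REPORT_COLUMNS = (
    "sample",
    "probe_id",
    "mut_probe_hits",
    "mut_full",
    "wt_probe_hits",
    "wt_full",
    "af_all",
    "af_full",
    "call",
    "flags",
    "total_reads",
    "files",
)


def _fmt_af(af: Optional[float]) -> str:
    return "NA" if af is None else f"{af:.2f}"


def _fmt_count(n: Optional[int]) -> str:
    return "NA" if n is None else str(n)


def format_report_row(result: ScanResult, call: Optional[GenotypeCall]) -> str:
    """One TSV row for a scanned sample (call fields NA when no call made)."""
    fields = [
        result.sample_id,
        result.probe_id,
        str(result.mut_probe_hits),
        _fmt_count(result.mut_full),
        str(result.wt_probe_hits),
        _fmt_count(result.wt_full),
        _fmt_af(call.af_all) if call else "NA",
        _fmt_af(call.af_full) if call else "NA",
        call.call if call else "NA",
        ",".join(sorted(call.flags)) if call and call.flags else ".",
        str(result.total_reads),
        ";".join(result.files),
    ]
    return "\t".join(fields)


def format_report(
    rows: Iterable[tuple[ScanResult, Optional[GenotypeCall]]],
    version: str = "",
) -> str:
    """Full TSV report: a version comment, header, one row per sample x probe.

    Deliberately timestamp-free so identical inputs give byte-identical
    reports.
    """
    lines = []
    if version:
        lines.append(f"# junctionscan {version}")
    lines.append("\t".join(REPORT_COLUMNS))
    for result, call in rows:
        lines.append(format_report_row(result, call))
    return "\n".join(lines) + "\n"
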