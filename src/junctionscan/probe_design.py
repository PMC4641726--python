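"""Junction probes and extended reference contexts for known insertions.

A known insertion (e.g. the MAK exon-9 Alu retrotransposon) creates a novel
junction between the 5' reference flank and the inserted element. A short
fixed-length "probe" spanning that junction occurs only in reads carrying the
mutant allele; a corresponding probe spanning the intact site occurs only in
wildtype reads. This module builds such probe pairs from an insertion
definition, assembles the ~300 bp extended reference contexts used for
second-stage full-read validation, and ships the canonical MAK-Alu 23-mer
probe pair together with a synthetic stand-in locus for testing.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

__all__ = [
    "InvalidSequenceError",
    "ProbeConstructionError",
    "AmbiguousProbeError",
    "ProbeConfigError",
    "MutationDefinition",
    "ProbeSet",
    "ExtendedReference",
    "reverse_complement",
    "build_probe_set",
    "build_extended_references",
    "load_probe_config",
    "load_probe_config_full",
    "builtin_probe_set",
    "builtin_mutation",
    "BUILTIN_IDS",
    "MAK_ALU_ID",
]

_DNA_RE = re.compile(r"^[ACGT]*$")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class InvalidSequenceError(ValueError):
    """A sequence contains characters outside the A/C/G/T alphabet."""


class ProbeConstructionError(ValueError):
    """Flanks or insert are too short, or the resulting probes are degenerate."""


class AmbiguousProbeError(ValueError):
    """A probe occurs in the context of the wrong allele; a longer probe is needed."""


class ProbeConfigError(ValueError):
    """A probe-configuration file is malformed."""


def _clean_dna(seq: str, *, what: str = "sequence") -> str:
    """Uppercase ``seq`` and reject anything outside A/C/G/T.

    Exact-match semantics make IUPAC ambiguity codes (including N)
    meaningless in probes and contexts, so they are rejected outright.
    """
    up = seq.upper()
    if not _DNA_RE.match(up):
        for i, ch in enumerate(up):
            if ch not in "ACGT":
                raise InvalidSequenceError(
                    f"invalid character {ch!r} at position {i} in {what}"
                )
    return up


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an A/C/G/T string (case-insensitive).

    Returns uppercase; an involution (applying twice returns the input).
    Raises :class:`InvalidSequenceError` naming the first offending position
    for non-ACGT input.
    """
    up = _clean_dna(seq)
    return up.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MutationDefinition:
    """A known insertion event described by explicit flank strings.

    ``left_flank`` and ``right_flank`` are the reference sequence 5' and 3'
    of the insertion point; ``inserted_seq`` is the full inserted element
    (for an Alu: body + poly-A + target-site duplication, modeled as one
    string). Genomic coordinates are carried as metadata only — all
    computation operates on the explicit strings, which sidesteps genome
    build and 0/1-based ambiguity.
    """

    id: str
    left_flank: str
    right_flank: str
    inserted_seq: str
    gene: str = ""
    coords: Optional[str] = None
    notes: str = ""

    def __post_init__(self) -> None:
        for name in ("left_flank", "right_flank", "inserted_seq"):
            object.__setattr__(self, name, _clean_dna(getattr(self, name), what=name))
        if not self.inserted_seq:
            raise ValueError("inserted_seq must be non-empty for an insertion event")


@dataclass(frozen=True)
class ProbeSet:
    """A mutant/wildtype junction probe pair plus reverse complements.

    The scanner searches reads for ``mut_probe`` or ``mut_probe_rc`` (reads
    are unoriented) and analogously for the wildtype pair.
    """

    id: str
    mut_probe: str
    wt_probe: str
    mut_probe_rc: str = ""
    wt_probe_rc: str = ""

    def __post_init__(self) -> None:
        mut = _clean_dna(self.mut_probe, what="mut_probe")
        wt = _clean_dna(self.wt_probe, what="wt_probe")
        object.__setattr__(self, "mut_probe", mut)
        object.__setattr__(self, "wt_probe", wt)
        if not self.mut_probe_rc:
            object.__setattr__(self, "mut_probe_rc", reverse_complement(mut))
        if not self.wt_probe_rc:
            object.__setattr__(self, "wt_probe_rc", reverse_complement(wt))
        if len(mut) != len(wt) or not mut:
            raise ProbeConstructionError(
                f"probe lengths differ or are empty: |mut|={len(mut)}, |wt|={len(wt)}"
            )
        if self.mut_probe_rc != reverse_complement(mut):
            raise ProbeConstructionError("mut_probe_rc is not the reverse complement of mut_probe")
        if self.wt_probe_rc != reverse_complement(wt):
            raise ProbeConstructionError("wt_probe_rc is not the reverse complement of wt_probe")
        if mut == wt:
            raise ProbeConstructionError("mut_probe equals wt_probe")
        if mut == self.wt_probe_rc or wt == self.mut_probe_rc:
            raise ProbeConstructionError("a probe equals its partner's reverse complement")

    @property
    def k(self) -> int:
        """Probe length in nucleotides."""
        return len(self.mut_probe)


@dataclass(frozen=True)
class ExtendedReference:
    """Mutant and wildtype context sequences for full-read validation.

    ``wt_context`` spans the intact insertion site (``flank_len`` reference
    nucleotides each side); ``mut_context`` additionally carries the inserted
    element between the flanks. A read whose entire sequence matches one of
    these contexts exactly is a "full match" for that allele.
    """

    mut_context: str
    wt_context: str
    flank_len: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "mut_context", _clean_dna(self.mut_context, what="mut_context"))
        object.__setattr__(self, "wt_context", _clean_dna(self.wt_context, what="wt_context"))
        if len(self.wt_context) != 2 * self.flank_len:
            raise ValueError(
                f"|wt_context|={len(self.wt_context)} != 2*flank_len={2 * self.flank_len}"
            )


def _contains_either_strand(haystack: str, probe: str, probe_rc: str) -> bool:
    return probe in haystack or probe_rc in haystack


def build_probe_set(
    mut: MutationDefinition,
    k: int = 23,
    left_len: Optional[int] = None,
    probe_id: Optional[str] = None,
) -> ProbeSet:
    """Build a junction probe pair of length ``k`` from an insertion definition.

    The mutant probe is the last ``left_len`` nt of the left flank followed by
    the first ``k - left_len`` nt of the inserted element; the wildtype probe
    replaces the insert part with the start of the right flank. ``left_len``
    defaults to ``k // 2`` — a symmetric straddle of the junction.
    """
    if k < 8:
        raise ProbeConstructionError(f"probe length k={k} too short (minimum 8)")
    if left_len is None:
        left_len = k // 2
    if not 1 <= left_len <= k - 1:
        raise ProbeConstructionError(f"left_len={left_len} must be in [1, k-1]=[1, {k - 1}]")
    right_len = k - left_len
    if len(mut.left_flank) < left_len:
        raise ProbeConstructionError(
            f"left_flank length {len(mut.left_flank)} < left_len {left_len}"
        )
    if len(mut.inserted_seq) < right_len:
        raise ProbeConstructionError(
            f"inserted_seq length {len(mut.inserted_seq)} < k-left_len {right_len}"
        )
    if len(mut.right_flank) < right_len:
        raise ProbeConstructionError(
            f"right_flank length {len(mut.right_flank)} < k-left_len {right_len}"
        )
    left = mut.left_flank[-left_len:]
    return ProbeSet(
        id=probe_id or mut.id,
        mut_probe=left + mut.inserted_seq[:right_len],
        wt_probe=left + mut.right_flank[:right_len],
    )


def build_extended_references(
    mut: MutationDefinition,
    flank_len: int = 150,
    probe_set: Optional[ProbeSet] = None,
) -> ExtendedReference:
    """Assemble the extended mutant and wildtype reference contexts.

    With the default ``flank_len`` of 150 the wildtype context is exactly
    300 bp of reference sequence centered on the insertion site; the mutant
    context additionally contains the full inserted element.

    When ``probe_set`` is supplied, probe specificity is verified: each probe
    (in either orientation, since reads are unoriented) must occur in its own
    allele's context and in neither orientation in the other allele's context.
    A violation raises :class:`AmbiguousProbeError` — the junction k-mer
    pre-exists on the other allele, so a longer or repositioned probe is
    required. Target-site duplications are the classic trigger: a wildtype
    probe that does not span the entire duplicated target site is
    reconstituted at the insertion's 3' junction.
    """
    if len(mut.left_flank) < flank_len or len(mut.right_flank) < flank_len:
        raise ValueError(
            f"flanks must each be >= flank_len={flank_len} nt "
            f"(got {len(mut.left_flank)} / {len(mut.right_flank)})"
        )
    left = mut.left_flank[-flank_len:]
    right = mut.right_flank[:flank_len]
    ext = ExtendedReference(
        mut_context=left + mut.inserted_seq + right,
        wt_context=left + right,
        flank_len=flank_len,
    )
    if probe_set is not None:
        ps = probe_set
        if not _contains_either_strand(ext.mut_context, ps.mut_probe, ps.mut_probe_rc):
            raise AmbiguousProbeError(
                f"mutant probe of set {ps.id!r} not found in the mutant context"
            )
        if not _contains_either_strand(ext.wt_context, ps.wt_probe, ps.wt_probe_rc):
            raise AmbiguousProbeError(
                f"wildtype probe of set {ps.id!r} not found in the wildtype context"
            )
        if _contains_either_strand(ext.wt_context, ps.mut_probe, ps.mut_probe_rc):
            raise AmbiguousProbeError(
                f"mutant probe of set {ps.id!r} occurs in the wildtype context; "
                "increase k or reposition the junction split"
            )
        if _contains_either_strand(ext.mut_context, ps.wt_probe, ps.wt_probe_rc):
            raise AmbiguousProbeError(
                f"wildtype probe of set {ps.id!r} occurs in the mutant context "
                "(does it span the whole target-site duplication?); "
                "increase k or reposition the junction split"
            )
    return ext


# ---------------------------------------------------------------------------
# Built-in fixtures
# ---------------------------------------------------------------------------

MAK_ALU_ID = "MAK_Alu_ex9"

# The canonical 23-mer probe pair for the MAK exon-9 AluYa8 insertion,
# matching the junction of the mutant allele and the intact wildtype site.
_MAK_MUT_PROBE = "GAAAAAAGGAGGCCGGGCGCGGT"
_MAK_WT_PROBE = "CGAAATGGAGAATCTTTTTTCCT"

# Synthetic stand-in locus for the MAK exon-9 insertion site. The true
# genomic flanks and the deposited AluYa8 element are not bundled; instead a
# seeded random locus embeds the canonical probe pair with the real event's
# anatomy: a 353 nt insert (280 nt Alu-like body, 60 nt poly-A, 13 bp
# target-site duplication). The wildtype probe spans the full target site
# plus one extra base on the 5' side so it is not reconstituted at the
# insert's 3' junction — the same constraint the real probe satisfies.
_MAK_LIKE_FLANK = 400
_MAK_LIKE_SEED = 20151111
_MAK_L_END = "AGGAAAAAAGATTCT"  # last 15 nt of the left flank
_MAK_R_START = "CCATTTCG"  # first 8 nt of the right flank
_MAK_TSD = _MAK_L_END[-13:]  # duplicated target site
_MAK_POLYA = 60


def _random_dna(n: int, rng: random.Random) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _make_mak_like_locus() -> MutationDefinition:
    rng = random.Random(_MAK_LIKE_SEED)
    left = _random_dna(_MAK_LIKE_FLANK - len(_MAK_L_END), rng) + _MAK_L_END
    right = _MAK_R_START + _random_dna(_MAK_LIKE_FLANK - len(_MAK_R_START), rng)
    body_fill = _random_dna(280 - len(_MAK_MUT_PROBE), rng)
    insert = _MAK_MUT_PROBE + body_fill + "A" * _MAK_POLYA + _MAK_TSD
    assert len(insert) == 353
    return MutationDefinition(
        id=MAK_ALU_ID,
        gene="MAK",
        left_flank=left,
        right_flank=right,
        inserted_seq=insert,
        coords="chr6:10805962 (hg19, metadata only)",
        notes="synthetic stand-in flanks; probe pair is the canonical MAK-Alu set",
    )


def builtin_probe_set(probe_id: str = MAK_ALU_ID) -> ProbeSet:
    """Return a built-in probe set by id (currently only the MAK-Alu pair)."""
    if probe_id != MAK_ALU_ID:
        raise KeyError(f"unknown built-in probe set {probe_id!r}; known: {BUILTIN_IDS}")
    return ProbeSet(id=MAK_ALU_ID, mut_probe=_MAK_MUT_PROBE, wt_probe=_MAK_WT_PROBE)


def builtin_mutation(probe_id: str = MAK_ALU_ID) -> MutationDefinition:
    """Return the built-in (synthetic stand-in) locus paired with a probe set."""
    if probe_id != MAK_ALU_ID:
        raise KeyError(f"unknown built-in mutation {probe_id!r}; known: {BUILTIN_IDS}")
    return _make_mak_like_locus()


BUILTIN_IDS = (MAK_ALU_ID,)


# ---------------------------------------------------------------------------
# Probe/mutation configuration files
# ---------------------------------------------------------------------------

def load_probe_config(path: str | Path) -> list[ProbeSet]:
    """Load probe sets from a tab-separated configuration file.

    Grammar (one record per line, ``#`` comments and blank lines ignored)::

        id <TAB> probes <TAB> mut_probe <TAB> wt_probe
        id <TAB> flanks <TAB> left_flank <TAB> right_flank <TAB> inserted_seq [<TAB> k [<TAB> left_len]]

    ``flanks`` records derive the probe pair via :func:`build_probe_set`.
    Malformed records, duplicate ids, and probe-invariant violations raise
    :class:`ProbeConfigError` carrying the line number.
    """
    return [ps for ps, _ in load_probe_config_full(path)]


def load_probe_config_full(
    path: str | Path,
) -> list[tuple[ProbeSet, Optional[MutationDefinition]]]:
    """Like :func:`load_probe_config` but also returns each record's mutation
    definition (``None`` for ``probes``-mode records, which carry no flank
    sequence and therefore cannot supply extended reference contexts)."""
    path = Path(path)
    out: list[tuple[ProbeSet, Optional[MutationDefinition]]] = []
    seen: set[str] = set()
    with open(path, encoding="ascii") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ProbeConfigError(f"{path}:{lineno}: expected at least id and mode")
            rec_id, mode = fields[0].strip(), fields[1].strip()
            if not rec_id:
                raise ProbeConfigError(f"{path}:{lineno}: empty record id")
            if rec_id in seen:
                raise ProbeConfigError(f"{path}:{lineno}: duplicate id {rec_id!r}")
            mutdef: Optional[MutationDefinition] = None
            try:
                if mode == "probes":
                    if len(fields) != 4:
                        raise ProbeConfigError(
                            f"{path}:{lineno}: 'probes' mode needs exactly "
                            f"id, mode, mut_probe, wt_probe (got {len(fields)} fields)"
                        )
                    ps = ProbeSet(id=rec_id, mut_probe=fields[2], wt_probe=fields[3])
                elif mode == "flanks":
                    if not 5 <= len(fields) <= 7:
                        raise ProbeConfigError(
                            f"{path}:{lineno}: 'flanks' mode needs id, mode, left_flank, "
                            f"right_flank, inserted_seq [, k [, left_len]]"
                        )
                    mutdef = MutationDefinition(
                        id=rec_id,
                        left_flank=fields[2],
                        right_flank=fields[3],
                        inserted_seq=fields[4],
                    )
                    k = int(fields[5]) if len(fields) >= 6 else 23
                    left_len = int(fields[6]) if len(fields) >= 7 else None
                    ps = build_probe_set(mutdef, k=k, left_len=left_len)
                else:
                    raise ProbeConfigError(
                        f"{path}:{lineno}: unknown mode {mode!r} (expected 'probes' or 'flanks')"
                    )
            except ProbeConfigError:
                raise
            except (ValueError, KeyError) as exc:
                raise ProbeConfigError(f"{path}:{lineno}: {exc}") from exc
            seen.add(rec_id)
            out.append((ps, mutdef))
    return out
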