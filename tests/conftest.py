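import gzip
import random

import pytest

from junctionscan import (
    MutationDefinition,
    build_extended_references,
    builtin_mutation,
    builtin_probe_set,
)


@pytest.fixture(scope="session")
def mak_probes():
    return builtin_probe_set()


@pytest.fixture(scope="session")
def mak_locus():
    return builtin_mutation()


@pytest.fixture(scope="session")
def mak_ext(mak_locus, mak_probes):
    return build_extended_references(mak_locus, 150, probe_set=mak_probes)


def random_dna(n, rng):
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture
def random_mutation():
    """A generic synthetic insertion locus with 400 bp flanks and a 353 nt
    insert (no target-site duplication, so symmetric probe construction is
    unambiguous)."""
    rng = random.Random(424242)
    return MutationDefinition(
        id="synth",
        left_flank=random_dna(400, rng),
        right_flank=random_dna(400, rng),
        inserted_seq=random_dna(353, rng),
    )


def write_fastq(path, records, compress=False):
    """records: iterable of (read_id, seq, qual) triples."""
    opener = gzip.open if compress else open
    with opener(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    return path
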