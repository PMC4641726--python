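"""FASTQ streaming and the two-stage exact-match scan."""

import gzip
import random

import pytest

from junctionscan import (
    ReadRecord,
    SimulationConfig,
    full_match,
    iter_fastq,
    probe_hit,
    reverse_complement,
    scan,
    simulate_sample,
)
from junctionscan.fastq_engine import FastqParseError

from conftest import write_fastq


MUT_PROBE = "GAAAAAAGGAGGCCGGGCGCGGT"


def naive_scan_oracle(paths, probe_set, ext):
    """Independent counter: load all reads with Biopython and count with
    plain substring tests."""
    from Bio.Seq import Seq
    from Bio import SeqIO

    def rc(s):
        return str(Seq(s).reverse_complement())

    counts = dict(mut_probe_hits=0, mut_full=0, wt_probe_hits=0, wt_full=0, total=0)
    for path in paths:
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                seq = str(rec.seq).upper()
                counts["total"] += 1
                for allele, probe, ctx in (
                    ("mut", probe_set.mut_probe, ext.mut_context),
                    ("wt", probe_set.wt_probe, ext.wt_context),
                ):
                    if probe in seq or rc(probe) in seq:
                        counts[f"{allele}_probe_hits"] += 1
                        if seq in ctx or rc(seq) in ctx:
                            counts[f"{allele}_full"] += 1
    return counts


class TestIterFastq:
    def test_single_record(self, tmp_path):
        path = write_fastq(tmp_path / "a.fastq", [("r1", "ACGTN", "IIIII")])
        recs = list(iter_fastq([path]))
        assert recs == [ReadRecord("r1", "ACGTN", "IIIII")]

    def test_gzip_transparency_by_magic_bytes(self, tmp_path):
        records = [("r1", "ACGT", "IIII"), ("r2", "GGCC", "IIII")]
        plain = write_fastq(tmp_path / "a.fastq", records)
        # deliberately misleading extension: detection is by content
        gz = write_fastq(tmp_path / "b.fastq", records, compress=True)
        assert list(iter_fastq([plain])) == list(iter_fastq([gz]))

    def test_multiple_files_streamed_in_order(self, tmp_path):
        p1 = write_fastq(tmp_path / "a.fastq", [("r1", "AAAA", "IIII")])
        p2 = write_fastq(tmp_path / "b.fastq", [("r2", "CCCC", "IIII")])
        assert [r.read_id for r in iter_fastq([p1, p2])] == ["r1", "r2"]

    def test_truncated_record_names_file_and_index(self, tmp_path):
        path = tmp_path / "trunc.fastq"
        path.write_text("@r1\nACGT\n+\nIIII\n@r2\nACGT\n")
        with pytest.raises(FastqParseError, match=r"trunc\.fastq.*record 1"):
            list(iter_fastq([path]))

    def test_wrapped_fastq_rejected(self, tmp_path):
        path = tmp_path / "wrapped.fastq"
        path.write_text("@r1\nACGT\nACGT\n+\nIIIIIIII\n")
        with pytest.raises(FastqParseError, match="wrapped|'\\+'"):
            list(iter_fastq([path]))

    def test_simulator_read_count(self, tmp_path, mak_locus, mak_probes):
        cfg = SimulationConfig(mutation=mak_locus, allele_fraction=0.5, coverage=20,
                               paired=True, seed=3)
        paths, manifest = simulate_sample(cfg, tmp_path / "sim", probe_set=mak_probes)
        assert len(paths) == 2
        assert sum(1 for _ in iter_fastq(paths)) == len(manifest.reads)


class TestProbeHit:
    def test_probe_itself_and_rc(self):
        read = ReadRecord("r", MUT_PROBE, "I" * 23)
        assert probe_hit(read, MUT_PROBE, reverse_complement(MUT_PROBE))
        rc_read = ReadRecord("r", reverse_complement(MUT_PROBE), "I" * 23)
        assert probe_hit(rc_read, MUT_PROBE, reverse_complement(MUT_PROBE))

    def test_no_hit_in_homopolymer(self):
        read = ReadRecord("r", "A" * 121, "I" * 121)
        assert not probe_hit(read, MUT_PROBE, reverse_complement(MUT_PROBE))

    def test_n_never_matches(self):
        seq = MUT_PROBE[:10] + "N" + MUT_PROBE[11:]
        read = ReadRecord("r", seq, "I" * len(seq))
        assert not probe_hit(read, MUT_PROBE, reverse_complement(MUT_PROBE))


class TestFullMatch:
    def test_verbatim_slice_matches_and_snp_breaks(self, mak_ext):
        ctx = mak_ext.mut_context
        seq = ctx[100:221]
        assert full_match(ReadRecord("r", seq, "I" * 121), ctx)
        mutated = seq[:60] + ("A" if seq[60] != "A" else "C") + seq[61:]
        assert not full_match(ReadRecord("r", mutated, "I" * 121), ctx)

    def test_reverse_complement_orientation_matches(self, mak_ext):
        ctx = mak_ext.wt_context
        seq = reverse_complement(ctx[50:171])
        assert full_match(ReadRecord("r", seq, "I" * 121), ctx)

    def test_read_longer_than_context_is_false(self):
        assert not full_match(ReadRecord("r", "ACGT" * 30, "I" * 120), "ACGT")

    def test_chimeric_probe_only_read(self, mak_probes, mak_ext):
        """A chimera carrying the probe k-mer but foreign sequence elsewhere
        passes stage 1 and fails stage 2 — the false-positive class the
        full-match filter removes."""
        chimera = "TTTT" + mak_probes.mut_probe + "TTTTGGGGTTTTGGGG"
        read = ReadRecord("r", chimera, "I" * len(chimera))
        assert probe_hit(read, mak_probes.mut_probe, mak_probes.mut_probe_rc)
        assert not full_match(read, mak_ext.mut_context)


class TestScan:
    def test_empty_fastq_gives_all_zero(self, tmp_path, mak_probes, mak_ext):
        path = tmp_path / "empty.fastq"
        path.write_text("")
        res = scan("s", [path], mak_probes, mak_ext)
        assert (res.mut_probe_hits, res.mut_full, res.wt_probe_hits, res.wt_full,
                res.total_reads) == (0, 0, 0, 0, 0)

    def test_single_forced_hit(self, tmp_path, mak_probes, mak_ext):
        seq = mak_ext.mut_context[80:201]
        assert mak_probes.mut_probe in seq
        path = write_fastq(tmp_path / "one.fastq", [("r1", seq, "I" * len(seq))])
        res = scan("s", [path], mak_probes, mak_ext)
        assert (res.mut_probe_hits, res.mut_full, res.wt_probe_hits, res.wt_full) == (1, 1, 0, 0)

    def test_without_ext_ref_full_counters_not_computed(self, tmp_path, mak_probes):
        path = write_fastq(tmp_path / "a.fastq", [("r1", "ACGT" * 30, "I" * 120)])
        res = scan("s", [path], mak_probes)
        assert res.mut_full is None and res.wt_full is None

    def test_orientation_invariance(self, tmp_path, mak_locus, mak_probes, mak_ext):
        """Reverse-complementing every read leaves all counters unchanged."""
        cfg = SimulationConfig(mutation=mak_locus, allele_fraction=0.5, coverage=15,
                               seed=11)
        paths, _ = simulate_sample(cfg, tmp_path / "fwd", probe_set=mak_probes)
        flipped = write_fastq(
            tmp_path / "rc.fastq",
            [(r.read_id, reverse_complement(r.sequence), r.quality)
             for r in iter_fastq(paths)],
        )
        a = scan("s", paths, mak_probes, mak_ext)
        b = scan("s", [flipped], mak_probes, mak_ext)
        assert (a.mut_probe_hits, a.mut_full, a.wt_probe_hits, a.wt_full) == (
            b.mut_probe_hits, b.mut_full, b.wt_probe_hits, b.wt_full)

    @pytest.mark.parametrize("compress", [False, True])
    @pytest.mark.parametrize("af,cov,err,seed", [
        (0.0, 10, 0.0, 1), (1.0, 10, 0.01, 2), (0.5, 25, 0.001, 3), (0.3, 40, 0.005, 4),
    ])
    def test_counters_match_naive_oracle(self, tmp_path, mak_locus, mak_probes,
                                         mak_ext, af, cov, err, seed, compress):
        cfg = SimulationConfig(mutation=mak_locus, allele_fraction=af, coverage=cov,
                               error_rate=err, seed=seed)
        paths, _ = simulate_sample(cfg, tmp_path / "sim", probe_set=mak_probes,
                                   gzip_output=compress)
        res = scan("s", paths, mak_probes, mak_ext)
        oracle = naive_scan_oracle(paths, mak_probes, mak_ext)
        assert res.mut_probe_hits == oracle["mut_probe_hits"]
        assert res.mut_full == oracle["mut_full"]
        assert res.wt_probe_hits == oracle["wt_probe_hits"]
        assert res.wt_full == oracle["wt_full"]
        assert res.total_reads == oracle["total"]
        assert res.mut_full <= res.mut_probe_hits
        assert res.wt_full <= res.wt_probe_hits

    def test_plain_and_gzip_scans_identical(self, tmp_path, mak_locus, mak_probes,
                                            mak_ext):
        cfg = SimulationConfig(mutation=mak_locus, allele_fraction=0.5, coverage=20,
                               seed=8)
        plain, _ = simulate_sample(cfg, tmp_path / "p", probe_set=mak_probes)
        gz, _ = simulate_sample(cfg, tmp_path / "g", probe_set=mak_probes,
                                gzip_output=True)
        a, b = scan("s", plain, mak_probes, mak_ext), scan("s", gz, mak_probes, mak_ext)
        assert (a.mut_probe_hits, a.mut_full, a.wt_probe_hits, a.wt_full,
                a.total_reads) == (b.mut_probe_hits, b.mut_full, b.wt_probe_hits,
                                   b.wt_full, b.total_reads)
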