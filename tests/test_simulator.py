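import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mapbench import (
    SequenceRecord,
    SimulationProfile,
    TruthTable,
    decode_truth_name,
    determine_read_count,
    generate_synthetic_genome,
    import_gold_standard,
    mutate_sequence,
    simulate_reads,
    subsample_reads,
    write_fastq,
)
from mapbench.simulator import (
    FORWARD,
    REVERSE,
    GoldStandardError,
    ReadTruth,
    encode_truth_name,
    reverse_complement,
)
from conftest import make_dataset


class TestMutateSequence:
    def test_zero_rates_identity(self):
        rec = SequenceRecord("c", "ACGTACGTNNACGT")
        profile = SimulationProfile(read_length=4)
        mutated, mmap = mutate_sequence(rec, profile, np.random.default_rng(1))
        assert mutated.sequence == rec.sequence
        assert mmap.events == []
        assert mmap.lift(5) == 5

    def test_snp_count_within_three_sigma(self):
        n, rate = 1_000_000, 0.01
        rec = generate_synthetic_genome(n, seed=11).records[0]
        profile = SimulationProfile(read_length=100, snp_rate=rate)
        _, mmap = mutate_sequence(rec, profile, np.random.default_rng(2))
        snps = sum(1 for e in mmap.events if e.kind == "SNP")
        sigma = math.sqrt(n * rate * (1 - rate))
        assert abs(snps - n * rate) <= 3 * sigma

    def test_snps_change_the_base(self):
        rec = generate_synthetic_genome(10_000, seed=12).records[0]
        profile = SimulationProfile(read_length=100, snp_rate=0.05)
        mutated, mmap = mutate_sequence(rec, profile, np.random.default_rng(3))
        for e in mmap.events:
            assert e.ref != e.alt
            assert rec.sequence[e.position] == e.ref

    def test_n_positions_never_mutated(self):
        rec = SequenceRecord("c", ("ACGT" * 100) + ("N" * 200) + ("ACGT" * 100))
        profile = SimulationProfile(read_length=10, snp_rate=0.5, indel_rate=0.2)
        mutated, mmap = mutate_sequence(rec, profile, np.random.default_rng(4))
        assert mutated.sequence.count("N") == 200
        for e in mmap.events:
            assert "N" not in e.ref and "N" not in e.alt

    def test_liftover_recovers_original_base(self):
        """Exhaustive on 1 kb: every non-inserted mutated position lifts to an
        original position; un-mutated positions must carry the same base."""
        rec = generate_synthetic_genome(1_000, seed=13).records[0]
        profile = SimulationProfile(
            read_length=10, snp_rate=0.02, indel_rate=0.01, max_indel_length=5
        )
        mutated, mmap = mutate_sequence(rec, profile, np.random.default_rng(5))
        snp_positions = {e.position for e in mmap.events if e.kind == "SNP"}
        for mut_start, orig_start, length in mmap.segments:
            for d in range(length):
                orig_pos = mmap.lift(mut_start + d)
                assert orig_pos == orig_start + d
                if orig_pos not in snp_positions:
                    assert mutated.sequence[mut_start + d] == rec.sequence[orig_pos]

    def test_liftover_is_monotone(self):
        rec = generate_synthetic_genome(5_000, seed=14).records[0]
        profile = SimulationProfile(read_length=10, indel_rate=0.02, max_indel_length=8)
        mutated, mmap = mutate_sequence(rec, profile, np.random.default_rng(6))
        lifted = [mmap.lift(i) for i in range(len(mutated.sequence))]
        assert all(a <= b for a, b in zip(lifted, lifted[1:]))


class TestDetermineReadCount:
    @pytest.mark.parametrize("length,rl,cov,expected", [
        (36_000_000, 150, 1.0, 240_000),
        (1_000_000, 100, 0.5, 5_000),
    ])
    def test_coverage_arithmetic(self, length, rl, cov, expected):
        profile = SimulationProfile(read_length=rl, coverage=cov)
        assert determine_read_count(length, profile) == expected

    def test_paired_count_rounded_down_to_even(self):
        profile = SimulationProfile(
            read_length=100, coverage=1.0, paired=True, insert_mean=300
        )
        assert determine_read_count(100_100, profile) % 2 == 0
        assert determine_read_count(100_100, profile) == 1_000


class TestSimulateReads:
    def test_zero_noise_reads_are_reference_substrings(self, toy_genome, toy_artificial):
        """With all rates zero, every forward read is an exact reference
        substring at its truth coordinates; every reverse read is the reverse
        complement of that substring."""
        _, artificial, rmap = toy_artificial
        profile = SimulationProfile(read_length=100, seed=21)
        reads, truth = simulate_reads(artificial, rmap, profile)
        assert len(reads) == truth.count > 0
        for read in reads:
            t = truth.get(read.id, read.mate)
            ref = toy_genome.get(t.contig).sequence[t.true_pos:t.true_pos + 100]
            if t.strand == FORWARD:
                assert read.sequence == ref
            else:
                assert read.sequence == reverse_complement(ref)

    def test_truth_count_matches_read_count_rule(self, toy_artificial):
        _, artificial, rmap = toy_artificial
        profile = SimulationProfile(read_length=100, coverage=0.5, seed=22)
        reads, truth = simulate_reads(artificial, rmap, profile)
        assert truth.count == determine_read_count(rmap.sampled_length, profile)
        assert len(reads) == truth.count

    def test_error_rate_sets_quality_and_mismatch_fraction(self, toy_genome, toy_artificial):
        _, artificial, rmap = toy_artificial
        profile = SimulationProfile(read_length=100, error_rate=0.01, coverage=2.0, seed=23)
        reads, truth = simulate_reads(artificial, rmap, profile)
        assert all(set(r.quality) == {chr(20 + 33)} for r in reads)  # Phred 20
        mismatches = bases = 0
        for read in reads:
            t = truth.get(read.id, read.mate)
            ref = toy_genome.get(t.contig).sequence[t.true_pos:t.true_pos + 100]
            query = read.sequence if t.strand == FORWARD else reverse_complement(read.sequence)
            mismatches += sum(a != b for a, b in zip(query, ref))
            bases += 100
        sigma = math.sqrt(bases * 0.01 * 0.99)
        assert abs(mismatches - bases * 0.01) <= 3 * sigma

    def test_paired_mode_emits_fr_mates_with_min_insert(self, toy_genome):
        from mapbench import SamplingConfig

        sampling = SamplingConfig(read_length=100, insert_size=300, min_total=40_000, seed=24)
        profile = SimulationProfile(
            read_length=100, paired=True, insert_mean=300, insert_sd=30, seed=24
        )
        _, _, rmap, reads, truth, _ = make_dataset(
            toy_genome, profile=profile, sampling=sampling, seed=24
        )
        assert len(reads) % 2 == 0
        for first, second in zip(reads[0::2], reads[1::2]):
            t1 = truth.get(first.id, 1)
            t2 = truth.get(second.id, 2)
            assert {t1.strand, t2.strand} == {FORWARD, REVERSE}
            fwd, rev = (t1, t2) if t1.strand == FORWARD else (t2, t1)
            insert = rev.true_pos + 100 - fwd.true_pos
            assert insert >= 200

    def test_deterministic_for_seed(self, toy_artificial):
        _, artificial, rmap = toy_artificial
        profile = SimulationProfile(read_length=100, snp_rate=0.01, error_rate=0.01, seed=25)
        a, _ = simulate_reads(artificial, rmap, profile)
        b, _ = simulate_reads(artificial, rmap, profile)
        assert a == b

    def test_zero_error_rate_gives_quality_41(self, toy_artificial):
        _, artificial, rmap = toy_artificial
        reads, _ = simulate_reads(
            artificial, rmap, SimulationProfile(read_length=100, seed=26)
        )
        assert set(reads[0].quality) == {chr(41 + 33)}


class TestTruthNames:
    def test_documented_example(self):
        t = decode_truth_name("sim:17|chr2|1001|R|1")
        assert t.contig == "chr2"
        assert t.true_pos == 1000
        assert t.strand == REVERSE
        assert t.mate == 1

    @given(
        serial=st.integers(0, 10**6),
        contig=st.from_regex(r"[A-Za-z0-9_.]{1,12}", fullmatch=True),
        pos0=st.integers(0, 10**8),
        strand=st.sampled_from([FORWARD, REVERSE]),
        mate=st.integers(0, 2),
    )
    @settings(max_examples=50, derandomize=True)
    def test_encode_decode_round_trip(self, serial, contig, pos0, strand, mate):
        name = encode_truth_name(serial, contig, pos0, strand, mate)
        t = decode_truth_name(name)
        assert (t.contig, t.true_pos, t.strand, t.mate) == (contig, pos0, strand, mate)

    @pytest.mark.parametrize("name", ["SRR000001.5", "sim:x|c|1|F|0", "read1"])
    def test_foreign_names_unparseable(self, name):
        assert decode_truth_name(name) is None

    def test_sidecar_tsv_agrees_with_name_encoding(self, tmp_path, toy_artificial):
        _, artificial, rmap = toy_artificial
        profile = SimulationProfile(read_length=100, snp_rate=0.005, seed=27)
        _, truth = simulate_reads(artificial, rmap, profile)
        p = truth.write_tsv(tmp_path / "truth.tsv")
        back = TruthTable.read_tsv(p)
        for (read_id, mate), t in back.items():
            decoded = decode_truth_name(read_id)
            assert (decoded.contig, decoded.true_pos, decoded.strand, decoded.mate) == (
                t.contig, t.true_pos, t.strand, t.mate
            )


class TestGoldStandardImport:
    def _write_sam(self, path, rows, contigs=(("chr1", 10_000),)):
        lines = ["@HD\tVN:1.6\tSO:unsorted"]
        lines += [f"@SQ\tSN:{name}\tLN:{length}" for name, length in contigs]
        for qname, flag, contig, pos1 in rows:
            lines.append(
                f"{qname}\t{flag}\t{contig}\t{pos1}\t60\t4M\t*\t0\t0\tACGT\tIIII"
            )
        path.write_text("\n".join(lines) + "\n")
        return path

    def _write_fastq(self, path, ids):
        path.write_text("".join(f"@{i}\nACGT\n+\nIIII\n" for i in ids))
        return path

    def test_three_read_toy_import(self, tmp_path):
        fq = self._write_fastq(tmp_path / "r.fastq", ["r1", "r2", "r3"])
        sam = self._write_sam(
            tmp_path / "gold.sam",
            [("r1", 0, "chr1", 1001), ("r2", 16, "chr1", 51), ("r3", 0, "chr1", 5)],
        )
        truth = import_gold_standard([fq], sam)
        assert truth.count == 3
        assert truth.get("r1").true_pos == 1000  # 1-based SAM POS -> 0-based
        assert truth.get("r2").strand == REVERSE

    def test_missing_read_named_in_error(self, tmp_path):
        fq = self._write_fastq(tmp_path / "r.fastq", ["r1", "orphan"])
        sam = self._write_sam(tmp_path / "gold.sam", [("r1", 0, "chr1", 1)])
        with pytest.raises(GoldStandardError, match="orphan"):
            import_gold_standard([fq], sam)

    def test_unmapped_gold_record_rejected(self, tmp_path):
        fq = self._write_fastq(tmp_path / "r.fastq", ["r1"])
        sam = tmp_path / "gold.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr1\tLN:10000\n"
            "r1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII\n"
        )
        with pytest.raises(GoldStandardError, match="unmapped"):
            import_gold_standard([fq], sam)


class TestSubsampleReads:
    def _simulated_fastq(self, tmp_path, n_reads, seed, paired=False):
        genome = generate_synthetic_genome(60_000, seed=seed)
        profile = SimulationProfile(
            read_length=100,
            coverage=n_reads * 100 / 30_000,
            paired=paired,
            insert_mean=300 if paired else None,
            insert_sd=20,
            seed=seed,
        )
        from mapbench import SamplingConfig

        sampling = SamplingConfig(
            read_length=100, insert_size=300 if paired else None,
            min_total=30_000, seed=seed,
        )
        *_, paths = make_dataset(
            genome, profile=profile, sampling=sampling, seed=seed,
            out_prefix=tmp_path / "reads",
        )
        return paths

    def test_exact_cardinality_and_determinism(self, tmp_path):
        paths = self._simulated_fastq(tmp_path, 300, seed=31)
        out1 = subsample_reads(paths, 100, seed=1, out_paths=[tmp_path / "s1.fastq"])
        out2 = subsample_reads(paths, 100, seed=1, out_paths=[tmp_path / "s2.fastq"])
        assert out1[0].read_text().count("@sim:") == 100
        assert out1[0].read_text() == out2[0].read_text()

    def test_n_larger_than_file_passes_everything(self, tmp_path):
        paths = self._simulated_fastq(tmp_path, 50, seed=32)
        original = paths[0].read_text().count("@sim:")
        out = subsample_reads(paths, 10_000, seed=1, out_paths=[tmp_path / "s.fastq"])
        assert out[0].read_text().count("@sim:") == original

    def test_paired_mates_kept_together(self, tmp_path):
        paths = self._simulated_fastq(tmp_path, 200, seed=33, paired=True)
        outs = subsample_reads(
            paths, 40, seed=2,
            out_paths=[tmp_path / "s_1.fastq", tmp_path / "s_2.fastq"],
        )
        ids1 = [l[1:].split("|")[0] for l in outs[0].read_text().splitlines()[0::4]]
        ids2 = [l[1:].split("|")[0] for l in outs[1].read_text().splitlines()[0::4]]
        assert len(ids1) == len(ids2) == 40
        assert ids1 == ids2  # same serials, same order
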