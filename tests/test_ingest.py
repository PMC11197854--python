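import numpy as np
import pytest

from ribolens import (
    LengthRange,
    ReadRecord,
    SimulationConfig,
    build_experiment,
    parse_alignments,
    simulate_reads,
    simulate_reference,
)
from ribolens.ingest import FilterStats


def _write_sam(path, records, ref):
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for rec in ref.records:
        lines.append(f"@SQ\tSN:{rec.id}\tLN:{rec.length}")
    lines += records
    path.write_text("\n".join(lines) + "\n")
    return path


class TestParseAlignments:
    def test_pos_is_one_based_and_span_from_cigar(self, tmp_path, tiny_ref):
        sam = _write_sam(tmp_path / "a.sam", ["r1\t0\tT1\t19\t255\t28M\t*\t0\t0\t*\t*"], tiny_ref)
        reads, stats = parse_alignments(sam, tiny_ref, LengthRange(15, 40))
        assert reads == [ReadRecord(0, 18, 28)]
        assert stats.accepted == 1 and stats.total_records == 1

    def test_soft_clips_do_not_change_footprint_length(self, tmp_path, tiny_ref):
        sam = _write_sam(
            tmp_path / "a.sam", ["r1\t0\tT1\t19\t255\t3S28M2S\t*\t0\t0\t*\t*"], tiny_ref
        )
        reads, _ = parse_alignments(sam, tiny_ref, LengthRange(15, 40))
        assert reads == [ReadRecord(0, 18, 28)]

    @pytest.mark.parametrize(
        "record,counter",
        [
            ("r\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*", "unmapped"),
            ("r\t256\tT1\t19\t255\t28M\t*\t0\t0\t*\t*", "secondary_or_supplementary"),
            ("r\t2048\tT1\t19\t255\t28M\t*\t0\t0\t*\t*", "secondary_or_supplementary"),
            ("r\t16\tT1\t19\t255\t28M\t*\t0\t0\t*\t*", "reverse_strand"),
            ("r\t0\tT1\t19\t255\t50M\t*\t0\t0\t*\t*", "out_of_length_range"),
            ("r\t0\tT1\t100\t255\t28M\t*\t0\t0\t*\t*", "out_of_bounds"),
        ],
    )
    def test_rejection_counters(self, tmp_path, tiny_ref, record, counter):
        sam = _write_sam(tmp_path / "a.sam", [record], tiny_ref)
        reads, stats = parse_alignments(sam, tiny_ref, LengthRange(15, 40))
        assert reads == []
        assert getattr(stats, counter) == 1
        stats.check()

    def test_unknown_transcript_counted_not_fatal(self, tmp_path, tiny_ref):
        lines = ["@SQ\tSN:T1\tLN:120", "@SQ\tSN:T9\tLN:500",
                 "r1\t0\tT9\t10\t255\t28M\t*\t0\t0\t*\t*",
                 "r2\t0\tT1\t19\t255\t28M\t*\t0\t0\t*\t*"]
        sam = tmp_path / "a.sam"
        sam.write_text("\n".join(lines) + "\n")
        reads, stats = parse_alignments(sam, tiny_ref, LengthRange(15, 40))
        assert stats.unknown_transcript == 1 and stats.accepted == 1
        assert reads == [ReadRecord(0, 18, 28)]

    def test_first_failing_filter_wins(self, tmp_path, tiny_ref):
        # reverse strand AND overlong: charged to the earlier filter (strand)
        sam = _write_sam(tmp_path / "a.sam", ["r\t16\tT1\t19\t255\t50M\t*\t0\t0\t*\t*"], tiny_ref)
        _, stats = parse_alignments(sam, tiny_ref, LengthRange(15, 40))
        assert stats.reverse_strand == 1 and stats.out_of_length_range == 0


def naive_build(reads, ref, rng, radius):
    """Independent per-read accumulation with plain dicts (the oracle)."""
    nl, n_t, w = rng.n_lengths, len(ref), 2 * radius + 1
    region = np.zeros((nl, n_t, 3), dtype=np.int64)
    mg_start = np.zeros((nl, w), dtype=np.int64)
    mg_stop = np.zeros((nl, w), dtype=np.int64)
    cov: dict = {}
    for r in reads:
        rec = ref.records[r.transcript_index]
        li = r.length - rng.min_len
        if r.five_prime < rec.cds_start:
            reg = 0
        elif r.five_prime < rec.cds_end:
            reg = 1
        else:
            reg = 2
        region[li, r.transcript_index, reg] += 1
        p = r.five_prime - rec.cds_start
        if -radius <= p <= radius:
            mg_start[li, p + radius] += 1
        p = r.five_prime - (rec.cds_end - 3)
        if -radius <= p <= radius:
            mg_stop[li, p + radius] += 1
        key = (r.length, r.transcript_index, r.five_prime)
        cov[key] = cov.get(key, 0) + 1
    return region, mg_start, mg_stop, cov


class TestBuildExperiment:
    def test_example_reads(self, tiny_ref):
        rng = LengthRange(15, 40)
        reads = [ReadRecord(0, 18, 28), ReadRecord(0, 86, 28), ReadRecord(1, 48, 30)]
        exp = build_experiment(reads, tiny_ref, rng, radius=50)
        li28, li30 = 28 - 15, 30 - 15
        assert exp.region_counts[li28, 0, 0] == 1  # 18 < cds_start 30 -> UTR5
        assert exp.region_counts[li28, 0, 1] == 1  # 86 < cds_end 90 -> CDS
        assert exp.region_counts[li30, 1, 2] == 1  # 48 >= cds_end 48 -> UTR3
        assert exp.metagene_start[li28, -12 + 50] == 1  # 18 - 30 = -12
        assert exp.metagene_stop[li28, -1 + 50] == 1  # 86 - (90 - 3) = -1

    def test_read_violating_invariants_rejected(self, tiny_ref):
        with pytest.raises(ValueError, match="invariants"):
            build_experiment([ReadRecord(0, 100, 28)], tiny_ref, LengthRange(15, 40), 50)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_naive_oracle(self, seed):
        cfg = SimulationConfig(seed=seed, n_reads=2000, n_transcripts=10)
        ref = simulate_reference(cfg)
        reads, _ = simulate_reads(ref, cfg)
        rng, radius = cfg.length_range, 30
        exp = build_experiment(reads, ref, rng, radius=radius)
        region, mg_start, mg_stop, cov = naive_build(reads, ref, rng, radius)
        np.testing.assert_array_equal(exp.region_counts, region)
        np.testing.assert_array_equal(exp.metagene_start, mg_start)
        np.testing.assert_array_equal(exp.metagene_stop, mg_stop)
        got = {}
        for L, sc in exp.coverage.items():
            for t in range(len(ref)):
                pos, val = sc.row(t)
                for p, v in zip(pos, val):
                    got[(L, t, int(p))] = int(v)
        assert got == cov

    def test_conservation_per_length(self):
        cfg = SimulationConfig(seed=3, n_reads=5000, n_transcripts=10)
        ref = simulate_reference(cfg)
        reads, _ = simulate_reads(ref, cfg)
        exp = build_experiment(reads, ref, cfg.length_range, radius=50)
        per_length = np.bincount(
            [r.length - cfg.length_range.min_len for r in reads],
            minlength=cfg.length_range.n_lengths,
        )
        np.testing.assert_array_equal(exp.region_counts.sum(axis=(1, 2)), per_length)
        assert exp.region_counts.sum() == len(reads)
        # metagene bound and coverage conservation
        assert (exp.metagene_start.sum(axis=1) <= per_length).all()
        assert sum(sc.total for sc in exp.coverage.values()) == len(reads)

    def test_empty_input_gives_zero_arrays(self, tiny_ref):
        exp = build_experiment([], tiny_ref, LengthRange(15, 40), radius=50)
        assert exp.region_counts.sum() == 0
        assert exp.metagene_start.sum() == 0


class TestFilterStats:
    def test_counter_sum_invariant_enforced(self):
        s = FilterStats(total_records=3, accepted=1, unmapped=1)
        with pytest.raises(AssertionError):
            s.check()
        s.reverse_strand = 1
        s.check()
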