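import numpy as np
import pytest

from ribolens import (
    LengthRange,
    ReadRecord,
    build_experiment,
    read_store,
    write_store,
)
from ribolens.ingest import ExperimentData, FilterStats
from ribolens.qc import (
    OffsetTable,
    apply_offsets,
    detect_psite_offsets,
    frame_distribution,
    length_distribution,
    metagene,
    normalize_cpm,
    region_counts,
    transcript_coverage,
)


def make_exp(rng, radius, start_cols, n_transcripts=2, accepted=None):
    """ExperimentData with a hand-crafted start metagene: start_cols maps
    length -> {relative position -> count}."""
    nl, w = rng.n_lengths, 2 * radius + 1
    mg = np.zeros((nl, w), dtype=np.int64)
    for L, cols in start_cols.items():
        for p, c in cols.items():
            mg[rng.index(L), p + radius] = c
    total = int(mg.sum()) if accepted is None else accepted
    return ExperimentData(
        length_range=rng,
        radius=radius,
        stats=FilterStats(total_records=total, accepted=total),
        region_counts=np.zeros((nl, n_transcripts, 3), dtype=np.int64),
        metagene_start=mg,
        metagene_stop=np.zeros((nl, w), dtype=np.int64),
    )


class TestLengthDistribution:
    def test_counts_and_fractions(self, tiny_experiment):
        ld = length_distribution(tiny_experiment)
        assert ld.loc[28, "count"] == 3 and ld.loc[30, "count"] == 1
        assert ld.loc[28, "fraction"] == 0.75 and ld.loc[30, "fraction"] == 0.25
        assert ld["fraction"].sum() == pytest.approx(1.0)

    def test_single_length_subrange(self, tiny_experiment):
        ld = length_distribution(tiny_experiment, length_range=LengthRange(28, 28))
        assert list(ld["count"]) == [3]

    def test_empty_experiment_warns_not_divides(self, tiny_ref):
        exp = build_experiment([], tiny_ref, LengthRange(15, 40), 50)
        with pytest.warns(UserWarning, match="no reads"):
            ld = length_distribution(exp)
        assert (ld["fraction"] == 0).all()

    def test_range_outside_stored_states_both(self, tiny_experiment):
        with pytest.raises(ValueError, match=r"\[10, 45\].*\[15, 40\]"):
            length_distribution(tiny_experiment, length_range=LengthRange(10, 45))


class TestMetagene:
    def test_sums_over_length_range(self):
        rng = LengthRange(28, 29)
        exp = make_exp(rng, 50, {28: {-12: 1}, 29: {-12: 2}})
        prof = metagene(exp, site="start", length_range=rng)
        assert prof.value_at(-12) == 3
        prof = metagene(exp, site="start", length_range=LengthRange(28, 28))
        assert prof.value_at(-12) == 1

    def test_cpm_normalization(self):
        rng = LengthRange(28, 28)
        exp = make_exp(rng, 50, {28: {-12: 3}}, accepted=4)
        prof = metagene(exp, site="start", normalize=True)
        assert prof.value_at(-12) == pytest.approx(750000.0)

    def test_normalizing_empty_experiment_errors(self):
        exp = make_exp(LengthRange(28, 28), 50, {}, accepted=0)
        with pytest.raises(ValueError, match="cannot normalize empty experiment"):
            metagene(exp, site="start", normalize=True)

    def test_additivity_over_lengths(self, tiny_experiment):
        whole = metagene(tiny_experiment, site="stop").values
        parts = sum(
            metagene(tiny_experiment, site="stop", length_range=LengthRange(L, L)).values
            for L in LengthRange(15, 40).lengths
        )
        np.testing.assert_array_equal(whole, parts)


class TestRegionCounts:
    def test_boundary_rules(self, tiny_ref):
        reads = [
            ReadRecord(0, 18, 28),  # UTR5
            ReadRecord(0, 30, 28),  # five_prime == cds_start -> CDS
            ReadRecord(1, 48, 30),  # five_prime == cds_end -> UTR3
        ]
        exp = build_experiment(reads, tiny_ref, LengthRange(15, 40), 50)
        rc = region_counts(exp)
        assert list(rc["count"]) == [1, 1, 1]
        assert rc["percent"].sum() == pytest.approx(100.0)

    def test_percentages(self, tiny_ref):
        reads = [ReadRecord(0, 18, 28), ReadRecord(0, 30, 28)]
        exp = build_experiment(reads, tiny_ref, LengthRange(15, 40), 50)
        rc = region_counts(exp)
        assert list(rc["count"]) == [1, 1, 0]
        assert list(rc["percent"]) == [50.0, 50.0, 0.0]

    def test_per_transcript_breakdown_sums_to_totals(self, tiny_experiment):
        rc, by_t = region_counts(tiny_experiment, per_transcript=True)
        np.testing.assert_array_equal(by_t.sum(axis=0), rc["count"].to_numpy())


class TestDetectOffsets:
    def test_argmax_is_the_offset(self):
        rng = LengthRange(28, 28)
        cols = {-o: 1 for o in range(3, 19)}
        cols[-12] = 100
        exp = make_exp(rng, 50, {28: cols})
        table = detect_psite_offsets(exp)
        assert table.offset(28) == 12 and table.entries[28].confident

    def test_tie_breaks_toward_smaller_offset(self):
        exp = make_exp(LengthRange(28, 28), 50, {28: {-12: 50, -13: 50}})
        assert detect_psite_offsets(exp).offset(28) == 12

    def test_low_support_falls_back_unconfident(self):
        exp = make_exp(LengthRange(28, 28), 50, {28: {-7: 4}})
        table = detect_psite_offsets(exp)
        e = table.entries[28]
        assert e.offset == 12 and not e.confident and e.support == 4

    def test_support_counts_candidate_window_only(self):
        exp = make_exp(LengthRange(28, 28), 50, {28: {-12: 30, -2: 999, -20: 999}})
        e = detect_psite_offsets(exp).entries[28]
        assert e.support == 30 and e.offset == 12

    def test_short_length_clamps_default(self):
        # search window [16, 18] entirely >= L - 1 for L = 16
        exp = make_exp(LengthRange(16, 16), 50, {16: {-12: 100}})
        table = detect_psite_offsets(exp, search=(16, 18), default_offset=20)
        e = table.entries[16]
        assert e.offset == 15 and not e.confident

    def test_every_length_in_range_has_entry(self):
        rng = LengthRange(26, 32)
        exp = make_exp(rng, 50, {28: {-12: 100}})
        table = detect_psite_offsets(exp)
        assert table.lengths() == list(rng.lengths)


class TestApplyOffsets:
    def _store(self, tmp_path, ref, reads, rng=LengthRange(15, 40)):
        exp = build_experiment(reads, ref, rng, 50)
        path = tmp_path / "s.h5"
        write_store(path, ref, {"WT": exp})
        return read_store(path)

    def test_single_shift(self, tmp_path, tiny_ref):
        st = self._store(tmp_path, tiny_ref, [ReadRecord(0, 18, 28)])
        table = OffsetTable.from_dict({L: 12 for L in LengthRange(15, 40).lengths})
        psite = apply_offsets(st, "WT", offsets=table)
        assert psite.vectors[0][30] == 1 and psite.clipped == 0
        st.close()

    def test_clipping_rule_drops_past_end(self, tiny_ref):
        # Coverage can hold a 5' end near the transcript end (e.g. an
        # annotation edit after ingestion); the shift must drop it into
        # the clipped tally, never wrap or error. T2 is 80 nt: position
        # 75 + offset 12 = 87 >= 80 is dropped, position 30 + 12 = 42 kept.
        import numpy as np

        from ribolens.ingest import SparseCoverage

        rng = LengthRange(28, 28)
        exp = build_experiment([], tiny_ref, rng, 50)
        exp.coverage[28] = SparseCoverage(
            indptr=np.array([0, 0, 2]),
            positions=np.array([30, 75]),
            values=np.array([1, 1]),
        )
        table = OffsetTable.from_dict({28: 12})
        psite = apply_offsets(exp, offsets=table, ref=tiny_ref)
        assert psite.vectors[1][42] == 1
        assert psite.clipped == 1
        assert psite.total + psite.clipped == 2

    def test_additivity_of_lengths_landing_same_position(self, tmp_path, tiny_ref):
        reads = [ReadRecord(0, 18, 28), ReadRecord(0, 17, 29)]
        st = self._store(tmp_path, tiny_ref, reads)
        table = OffsetTable.from_dict({28: 12, 29: 13})
        psite = apply_offsets(st, "WT", offsets=table, length_range=LengthRange(28, 29))
        assert psite.vectors[0][30] == 2
        st.close()

    def test_store_without_coverage_advises_reingest(self, tmp_path, tiny_ref):
        exp = build_experiment([ReadRecord(0, 18, 28)], tiny_ref, LengthRange(15, 40), 50,
                               with_coverage=False)
        path = tmp_path / "nc.h5"
        write_store(path, tiny_ref, {"WT": exp})
        with read_store(path) as st:
            with pytest.raises(Exception, match="re-ingest"):
                apply_offsets(st, "WT", offsets=OffsetTable.from_dict({28: 12}))


class TestFrameDistribution:
    def test_hand_placed_psites(self, tiny_ref, tmp_path):
        from ribolens.qc import PsiteCoverage

        vecs = [np.zeros(120, dtype=np.int64), np.zeros(80, dtype=np.int64)]
        for pos in (30, 33, 34):
            vecs[0][pos] += 1
        frac = frame_distribution(PsiteCoverage(vectors=vecs, clipped=0), tiny_ref)
        np.testing.assert_allclose(frac, [2 / 3, 1 / 3, 0])

    def test_uniform_psites_approach_one_third(self, tiny_ref):
        from ribolens.qc import PsiteCoverage

        rng = np.random.default_rng(7)
        n = 30000
        vecs = [np.zeros(120, dtype=np.int64), np.zeros(80, dtype=np.int64)]
        pos = rng.integers(30, 90, size=n)  # CDS of T1, length 60 (divisible by 3)
        np.add.at(vecs[0], pos, 1)
        frac = frame_distribution(PsiteCoverage(vectors=vecs, clipped=0), tiny_ref)
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        assert np.all(np.abs(frac - 1 / 3) < 4 * se)

    def test_zero_cds_mass_warns(self, tiny_ref):
        from ribolens.qc import PsiteCoverage

        vecs = [np.zeros(120, dtype=np.int64), np.zeros(80, dtype=np.int64)]
        with pytest.warns(UserWarning, match="zero CDS mass"):
            frac = frame_distribution(PsiteCoverage(vectors=vecs, clipped=0), tiny_ref)
        assert (frac == 0).all()


class TestTranscriptCoverage:
    def _store(self, tmp_path, ref, reads):
        exp = build_experiment(reads, ref, LengthRange(15, 40), 50)
        path = tmp_path / "s.h5"
        write_store(path, ref, {"WT": exp})
        return read_store(path)

    def test_raw_and_shifted(self, tmp_path, tiny_ref):
        st = self._store(tmp_path, tiny_ref, [ReadRecord(0, 18, 28)])
        vec, seq = transcript_coverage(st, "WT", transcript_id="T1")
        assert vec[18] == 1 and vec.sum() == 1 and seq is None
        table = OffsetTable.from_dict({L: 12 for L in LengthRange(15, 40).lengths})
        vec, _ = transcript_coverage(st, "WT", transcript_id="T1", offsets=table)
        assert vec[30] == 1 and vec.sum() == 1
        st.close()

    def test_sequence_track_attached(self, tmp_path, tiny_ref):
        from dataclasses import replace

        from ribolens import Reference

        recs = tuple(replace(r, sequence="A" * r.length) for r in tiny_ref.records)
        ref = Reference("tiny", recs)
        st = self._store(tmp_path, ref, [ReadRecord(0, 18, 28)])
        # sequences live on the Reference (FASTA attachment), not in the store
        vec, seq = transcript_coverage(st, "WT", transcript_id="T1", ref=ref)
        assert len(seq) == 120 == len(vec)
        st.close()

    def test_unknown_transcript_suggests_nearest(self, tmp_path, tiny_ref):
        st = self._store(tmp_path, tiny_ref, [ReadRecord(0, 18, 28)])
        with pytest.raises(KeyError, match="T1"):
            transcript_coverage(st, "WT", transcript_id="T11")
        st.close()


class TestLengthAdditivity:
    """Any analysis restricted to [a, b] equals the sum of single-length calls."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 1),  # transcript index
                st.integers(0, 79),  # 5' end (fits both transcripts for L <= 40... bounded below)
                st.integers(15, 40),  # footprint length
            ),
            min_size=1,
            max_size=60,
        )
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_region_counts_additive_over_lengths(self, raw):
        from ribolens.ingest import ReadRecord as RR

        ref_lengths = (120, 80)
        reads = [
            RR(t, p, L)
            for t, p, L in raw
            if p + L <= ref_lengths[t]
        ]
        if not reads:
            return
        ref = _tiny_ref_for_hypothesis()
        exp = build_experiment(reads, ref, LengthRange(15, 40), 50)
        whole = region_counts(exp)["count"].to_numpy()
        parts = np.zeros(3, dtype=np.int64)
        for L in LengthRange(15, 40).lengths:
            if exp.region_counts[L - 15].sum() == 0:
                continue
            parts += region_counts(exp, length_range=LengthRange(L, L))["count"].to_numpy()
        np.testing.assert_array_equal(whole, parts)


def _tiny_ref_for_hypothesis():
    from ribolens import Reference, TranscriptRecord

    return Reference(
        "tiny", (TranscriptRecord("T1", 120, 30, 90), TranscriptRecord("T2", 80, 12, 48))
    )


class TestNormalizeCpm:
    def test_scaling(self):
        np.testing.assert_allclose(
            normalize_cpm([2, 3, 5], 10), [200000.0, 300000.0, 500000.0]
        )

    def test_conservation_to_one_million(self):
        rng = np.random.default_rng(1)
        v = rng.integers(0, 50, size=200)
        total = int(v.sum())
        assert normalize_cpm(v, total).sum() == pytest.approx(1e6, rel=1e-6)

    def test_zero_total_is_an_error(self):
        with pytest.raises(ValueError):
            normalize_cpm([1, 2], 0)
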