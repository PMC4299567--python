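"""Depth pileup, duplicate removal, modal normalization and profile algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import nuwtscan as ns
from nuwtscan.coverage_profile import AlignmentRecord, AlignmentSet, DepthTrack, _window_bounds


def _record(ref="chr", start=0, length=40, strand="+", rid="r0", **kw):
    return AlignmentRecord(ref, start, length, strand, rid, **kw)


class TestSamIO:
    def test_round_trip_reproduces_set_exactly(self, genome_pair, hawaii_sim, tmp_path):
        for aset in (hawaii_sim.host, hawaii_sim.endo):
            path = tmp_path / "rt.sam"
            ns.write_sam(aset, str(path))
            back = ns.read_alignments(str(path))
            assert back.references == aset.references
            assert back.records == aset.records

    def test_unmapped_records_skipped(self, tmp_path):
        path = tmp_path / "mini.sam"
        path.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n"
            "@SQ\tSN:chr\tLN:100\n"
            "a\t0\tchr\t1\t60\t40M\t*\t0\t0\t*\t*\n"
            "b\t16\tchr\t21\t60\t40M\t*\t0\t0\t*\t*\n"
            "c\t0\tchr\t41\t60\t40M\t*\t0\t0\t*\t*\n"
            "u\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n"
        )
        aset = ns.read_alignments(str(path))
        assert len(aset) == 3
        assert {r.read_id for r in aset} == {"a", "b", "c"}
        assert aset.for_reference("chr")[1].strand == "-"

    def test_empty_body_with_valid_header(self, tmp_path):
        path = tmp_path / "empty.sam"
        path.write_text("@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr\tLN:100\n")
        aset = ns.read_alignments(str(path))
        assert len(aset) == 0
        assert aset.references == {"chr": 100}

    def test_record_beyond_reference_rejected(self, tmp_path):
        path = tmp_path / "bad.sam"
        path.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr\tLN:50\n"
            "a\t0\tchr\t31\t60\t40M\t*\t0\t0\t*\t*\n"
        )
        with pytest.raises(ValueError, match="record 1"):
            ns.read_alignments(str(path))

    def test_duplicate_flag_honored(self, tmp_path):
        path = tmp_path / "dup.sam"
        path.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr\tLN:100\n"
            "a\t1024\tchr\t1\t60\t40M\t*\t0\t0\t*\t*\n"
        )
        aset = ns.read_alignments(str(path))
        assert aset.records[0].is_duplicate


class TestMarkDuplicates:
    def test_identical_key_collapses_to_one(self):
        recs = [_record(rid=f"r{i}") for i in range(3)]
        out = ns.mark_duplicates(AlignmentSet({"chr": 100}, recs))
        assert len(out) == 1
        assert out.records[0].read_id == "r0"  # lexicographically smallest retained

    def test_distinct_starts_unchanged(self):
        recs = [_record(start=10 * i, rid=f"r{i}") for i in range(5)]
        out = ns.mark_duplicates(AlignmentSet({"chr": 1000}, recs))
        assert len(out) == 5

    def test_matches_brute_force_key_oracle(self, genome_pair, hawaii_arch):
        cfg = ns.ReadoutConfig(duplicate_rate=0.1, seed=21)
        sim = ns.simulate_alignments(genome_pair, hawaii_arch, cfg)
        for aset in (sim.host, sim.endo):
            distinct = {
                (r.reference, r.start, r.strand, r.mate_reference, r.mate_start)
                for r in aset.records
            }
            assert len(ns.mark_duplicates(aset)) == len(distinct)

    def test_idempotent(self, hawaii_sim):
        once = ns.mark_duplicates(hawaii_sim.host)
        twice = ns.mark_duplicates(once)
        assert once.records == twice.records

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        keys=st.lists(
            st.tuples(st.integers(0, 20), st.sampled_from("+-"), st.integers(0, 20)),
            min_size=1,
            max_size=30,
        ),
        seed=st.integers(0, 1000),
    )
    def test_order_insensitive(self, keys, seed):
        recs = [
            _record(start=s, strand=strand, rid=f"r{i}", mate_reference="chr", mate_start=m)
            for i, (s, strand, m) in enumerate(keys)
        ]
        shuffled = list(recs)
        np.random.default_rng(seed).shuffle(shuffled)
        a = ns.mark_duplicates(AlignmentSet({"chr": 100}, recs))
        b = ns.mark_duplicates(AlignmentSet({"chr": 100}, shuffled))
        assert a.records == b.records


class TestDepthTrack:
    def test_single_read(self):
        aset = AlignmentSet({"chr": 100}, [_record()])
        track = ns.depth_track(aset, "chr")
        assert track.depth[:40].tolist() == [1] * 40
        assert track.depth[40:].sum() == 0

    def test_overlap_counts_twice(self):
        aset = AlignmentSet({"chr": 100}, [_record(rid="a"), _record(start=20, rid="b")])
        track = ns.depth_track(aset, "chr")
        assert (track.depth[20:40] == 2).all()
        assert (track.depth[:20] == 1).all()
        assert (track.depth[40:60] == 1).all()

    def test_depth_conservation(self, hawaii_sim, genome_pair):
        """Sum of depth equals the sum of aligned lengths, for every reference."""
        for aset in (ns.mark_duplicates(hawaii_sim.host), hawaii_sim.endo):
            for ref in aset.references:
                track = ns.depth_track(aset, ref)
                lengths = sum(r.length for r in aset.for_reference(ref) if not r.is_duplicate)
                assert int(track.depth.sum()) == lengths

    def test_out_of_range_record_rejected(self):
        aset = AlignmentSet({"chr": 30}, [_record(length=40)])
        with pytest.raises(ValueError):
            ns.depth_track(aset, "chr")


class TestModalDepth:
    def test_most_frequent_value(self):
        assert ns.modal_depth(DepthTrack("chr", [5, 5, 5, 10])) == 5

    def test_zeros_excluded(self):
        assert ns.modal_depth(DepthTrack("chr", [0, 0, 0, 7, 7])) == 7

    def test_tie_breaks_toward_larger_depth(self):
        assert ns.modal_depth(DepthTrack("chr", [4, 4, 5, 5])) == 5

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ns.modal_depth(DepthTrack("chr", [0, 0, 0]))

    def test_poisson_single_copy_mode_is_adjacent_to_rate(self, genome_pair, hawaii_sim):
        """Poisson(5) puts equal mass on 4 and 5, so the per-base mode of a 5x
        host track is one of the two; the windowed mode settles on 5."""
        track = ns.depth_track(ns.mark_duplicates(hawaii_sim.host), genome_pair.host_id)
        assert ns.modal_depth(track) in (4, 5)
        assert ns.windowed_modal_depth(track) == 5


class TestCopyNumberProfile:
    @pytest.mark.parametrize("depth,expected", [(10, 2.0), (60, 12.0)])
    def test_constant_depth_scaling(self, depth, expected):
        track = DepthTrack("wRi", np.full(3_000, depth))
        profile = ns.copy_number_profile(track, modal=5)
        assert (profile.rows["copy_number"] == expected).all()

    def test_window_grid_drops_half_window_remnant(self):
        track = DepthTrack("wRi", np.ones(2_000))
        profile = ns.copy_number_profile(track, modal=1, window=1000, step=500)
        assert profile.rows["start"].tolist() == [0, 500, 1000]

    def test_zero_modal_rejected(self):
        with pytest.raises(ValueError):
            ns.copy_number_profile(DepthTrack("wRi", np.ones(100)), modal=0)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        length=st.integers(1, 5_000),
        step=st.integers(1, 1_200),
        extra=st.integers(0, 1_200),
    )
    def test_window_bounds_invariants(self, length, step, extra):
        window = step + extra
        bounds = _window_bounds(length, window, step)
        for s, e in bounds:
            assert 0 <= s < e <= length
            assert s % step == 0
            assert e - s == window or 2 * (e - s) > window
        starts = [s for s, _ in bounds]
        assert starts == sorted(set(starts))

    def test_scaling_invariance_under_doubled_coverage(self, genome_pair, hawaii_arch):
        """Doubling coverage (a second, independent run) doubles the modal
        depth and leaves the copy-number profile unchanged up to noise."""
        sims = [
            ns.simulate_alignments(genome_pair, hawaii_arch, ns.ReadoutConfig(seed=s))
            for s in (31, 32)
        ]
        single = sims[0].endo
        merged_endo = AlignmentSet(
            dict(single.references),
            sims[0].endo.records
            + [
                AlignmentRecord(r.reference, r.start, r.length, r.strand, "b" + r.read_id,
                                mate_reference=r.mate_reference, mate_start=r.mate_start)
                for r in sims[1].endo.records
            ],
        )
        host1 = ns.depth_track(sims[0].host, genome_pair.host_id)
        merged_host = AlignmentSet(
            dict(sims[0].host.references),
            sims[0].host.records
            + [
                AlignmentRecord(r.reference, r.start, r.length, r.strand, "b" + r.read_id,
                                mate_reference=r.mate_reference, mate_start=r.mate_start)
                for r in sims[1].host.records
            ],
        )
        host2 = ns.depth_track(merged_host, genome_pair.host_id)
        m1 = ns.windowed_modal_depth(host1)
        m2 = ns.windowed_modal_depth(host2)
        assert abs(m2 - 2 * m1) <= 1
        p1 = ns.copy_number_profile(ns.depth_track(single, genome_pair.endo_id), m1)
        p2 = ns.copy_number_profile(ns.depth_track(merged_endo, genome_pair.endo_id), m2)
        diff = (p1.rows["copy_number"] - p2.rows["copy_number"]).abs()
        assert diff.median() < 0.5


class TestCrossMappingAudit:
    def test_disjoint_sets_share_nothing(self):
        a = AlignmentSet({"wRi": 100}, [_record(ref="wRi", rid="x")])
        b = AlignmentSet({"mito": 100}, [_record(ref="mito", rid="y")])
        assert ns.cross_mapping_audit(a, b) == (0, [])

    def test_identical_sets_share_everything(self):
        recs = [_record(ref="wRi", start=i, rid=f"r{i}") for i in range(4)]
        a = AlignmentSet({"wRi": 100}, recs)
        count, ids = ns.cross_mapping_audit(a, a)
        assert count == 4 and len(ids) == 4

    def test_homology_block_produces_shared_reads(self, genome_pair, hawaii_sim):
        """Every cross-mapped read originates inside the mito homology block."""
        mito = AlignmentSet(
            {genome_pair.mito_id: genome_pair.mito_length},
            hawaii_sim.host.for_reference(genome_pair.mito_id),
        )
        count, ids = ns.cross_mapping_audit(hawaii_sim.endo, mito)
        assert count > 0
        (_e, _), (m0, m1) = (genome_pair.homology_block[0], genome_pair.homology_block[1])
        by_id = {r.read_id: [] for r in mito.records}
        for r in mito.records:
            by_id[r.read_id].append(r)
        for rid in ids:
            assert any(r.start >= m0 and r.end <= m1 for r in by_id[rid])


class TestMappingStats:
    @pytest.mark.parametrize(
        "total,host,endo,host_pct,ratio",
        [
            (33_602_456, 26_875_741, 605_174, 80.0, 2.3),
            (55_650_278, 47_522_893, 471_055, 85.4, 0.99),
        ],
    )
    def test_summary_table_arithmetic(self, total, host, endo, host_pct, ratio):
        s = ns.read_fraction_stats(total, host, endo)
        assert round(s.host_pct, 1) == host_pct
        assert round(s.endo_to_host_ratio_pct, 2 if ratio < 1 else 1) == ratio

    def test_zero_endo_gives_zero_ratio(self):
        assert ns.read_fraction_stats(100, 90, 0).endo_to_host_ratio_pct == 0.0

    def test_zero_host_with_endo_is_undefined(self):
        with pytest.raises(ValueError):
            ns.read_fraction_stats(100, 0, 10)

    def test_mapped_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            ns.read_fraction_stats(10, 8, 8)


class TestLgtSize:
    @pytest.mark.parametrize(
        "ratio,genome,expected",
        [(2.3, 215, 4.945), (0.0, 215, 0.0), (1.0, 100, 1.0)],
    )
    def test_size_from_read_ratio(self, ratio, genome, expected):
        assert ns.estimate_lgt_size(ratio, genome) == pytest.approx(expected)


class TestProfileRatio:
    def _profile(self, copies, reference="wRi"):
        rows = pd.DataFrame(
            {
                "start": np.arange(len(copies)) * 500,
                "end": np.arange(len(copies)) * 500 + 1000,
                "mean_depth": np.asarray(copies) * 5.0,
                "copy_number": np.asarray(copies, dtype=float),
            }
        )
        return ns.CopyNumberProfile(reference, 1000, 500, 5, rows)

    def test_identity_ratio(self):
        a = self._profile([1, 2, 4])
        assert (ns.profile_ratio(a, a)["ratio"] == 1.0).all()

    def test_zero_denominator_gives_missing(self):
        a = self._profile([2, 2, 2])
        b = self._profile([2, 0, 2])
        ratio = ns.profile_ratio(a, b)["ratio"]
        assert np.isnan(ratio.iloc[1]) and ratio.iloc[0] == 1.0

    def test_grid_mismatch_rejected(self):
        a = self._profile([1, 2, 4])
        b = self._profile([1, 2])
        with pytest.raises(ValueError):
            ns.profile_ratio(a, b)

    def test_uneven_over_even_recovers_copy_map_shape(self, genome_pair, hawaii_arch):
        """Hawaii-like / Indonesia-like(copies=2) profile ratio tracks the
        ground-truth copy map divided by 2."""
        indo = ns.build_nuwt_architecture("indonesia_like", 20_000, copies=2)
        sim_h = ns.simulate_alignments(genome_pair, hawaii_arch, ns.ReadoutConfig(seed=41))
        sim_i = ns.simulate_alignments(genome_pair, indo, ns.ReadoutConfig(seed=42))
        th = ns.depth_track(sim_h.endo, genome_pair.endo_id)
        ti = ns.depth_track(sim_i.endo, genome_pair.endo_id)
        pa = ns.copy_number_profile(th, 5)
        pb = ns.copy_number_profile(ti, 5)
        ratio = ns.profile_ratio(pa, pb)
        for s, e, c in hawaii_arch.segments:
            mask = (ratio["start"] >= s + 300) & (ratio["end"] <= e - 300)
            if not mask.any():
                continue
            observed = ratio.loc[mask, "ratio"].median()
            assert observed == pytest.approx(c / 2, rel=0.35)
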