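"""Termination profiles and Ψ-ratio: trivial cases, oracle equality, recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import expected_psi_ratio, naive_sam_profile
from psiforge import psi_quant, synthetic


def _sites(*entries):
    return pd.DataFrame(
        [{"site_id": f"{m}:{p}", "molecule": m, "position": p, "guides": ""} for m, p in entries]
    )


class TestBuildProfile:
    def test_single_read_start_and_overlap(self, sam_of_reads):
        sam = sam_of_reads([("M", 10, 40, "r1")], {"M": 300})
        prof = psi_quant.build_profile(sam, {"M": 300}, "s")
        assert prof.starts["M"][9] == 1 and prof.starts["M"].sum() == 1
        assert prof.overlap["M"][9:40].tolist() == [1] * 31
        assert prof.overlap["M"][8] == 0 and prof.overlap["M"][40] == 0
        prof.check()

    def test_duplicate_reads_double_all_counters(self, sam_of_reads):
        one = psi_quant.build_profile(
            sam_of_reads([("M", 10, 40, "r1")], {"M": 300}, "one.sam"), {"M": 300}
        )
        two = psi_quant.build_profile(
            sam_of_reads([("M", 10, 40, "r1"), ("M", 10, 40, "r2")], {"M": 300}, "two.sam"),
            {"M": 300},
        )
        assert np.array_equal(two.starts["M"], 2 * one.starts["M"])
        assert np.array_equal(two.overlap["M"], 2 * one.overlap["M"])

    def test_profile_equals_naive_per_read_enumeration(self, hotspot_config, sam_of_reads):
        reads, _ = synthetic.simulate_termination_reads(hotspot_config, "S1")
        assert len(reads) >= 500
        sam = sam_of_reads(reads, hotspot_config.molecule_lengths)
        prof = psi_quant.build_profile(sam, hotspot_config.molecule_lengths, "S1")
        naive = naive_sam_profile(sam.read_text())
        for mol, length in hotspot_config.molecule_lengths.items():
            for pos in range(1, length + 1):
                assert prof.starts[mol][pos - 1] == naive[mol]["starts"].get(pos, 0)
                assert prof.overlap[mol][pos - 1] == naive[mol]["overlap"].get(pos, 0)

    def test_reverse_strand_reads_discarded_and_counted(self, tmp_path):
        import pysam

        from psiforge import io

        path = tmp_path / "rev.sam"
        header = io.sam_header({"M": 300})
        with pysam.AlignmentFile(path, "w", header=header) as out:
            for flag in (0, 16):
                rec = pysam.AlignedSegment(header)
                rec.query_name = f"r{flag}"
                rec.reference_id = 0
                rec.reference_start = 9
                rec.cigartuples = [(0, 30)]
                rec.flag = flag
                rec.mapping_quality = 60
                out.write(rec)
        prof = psi_quant.build_profile(path, {"M": 300})
        assert prof.total_mapped == 1
        assert prof.n_reverse_discarded == 1

    def test_unknown_reference_is_hard_error(self, sam_of_reads):
        sam = sam_of_reads([("M", 10, 40, "r1")], {"M": 300})
        with pytest.raises(ValueError, match="unknown reference"):
            psi_quant.build_profile(sam, {"OTHER": 300})

    def test_empty_input_warns_and_yields_empty_profile(self, sam_of_reads):
        sam = sam_of_reads([], {"M": 300})
        with pytest.warns(UserWarning, match="no mapped"):
            prof = psi_quant.build_profile(sam, {"M": 300})
        assert prof.total_mapped == 0
        assert prof.starts["M"].sum() == 0


def _profile(starts, overlap, sample="s"):
    prof = psi_quant.TerminationProfile(sample_id=sample)
    prof.starts = {"M": np.asarray(starts, dtype=np.int64)}
    prof.overlap = {"M": np.asarray(overlap, dtype=np.int64)}
    prof.total_mapped = int(np.sum(starts))
    return prof


class TestPsiRatio:
    def test_ratio_arithmetic(self):
        # 10 starting + 90 merely overlapping reads -> 0.10
        starts = np.zeros(300, int)
        overlap = np.zeros(300, int)
        starts[104] = 10
        overlap[104] = 100
        col = psi_quant.psi_ratio_column(_profile(starts, overlap), _sites(("M", 105)))
        assert col.loc["M:105", "ratio"] == pytest.approx(0.10)

    def test_full_termination_hits_upper_bound(self):
        starts = np.zeros(300, int)
        overlap = np.zeros(300, int)
        starts[104] = 50
        overlap[104] = 50  # every covering read starts here
        col = psi_quant.psi_ratio_column(_profile(starts, overlap), _sites(("M", 105)))
        assert col.loc["M:105", "ratio"] == 1.0

    def test_low_coverage_reported_missing(self):
        starts = np.zeros(300, int)
        overlap = np.zeros(300, int)
        starts[104], overlap[104] = 3, 10
        col = psi_quant.psi_ratio_column(
            _profile(starts, overlap), _sites(("M", 105)), min_coverage=20
        )
        assert np.isnan(col.loc["M:105", "ratio"])
        assert col.loc["M:105", "n_overlap"] == 10

    def test_offset_outside_molecule_is_missing_with_warning(self):
        starts = np.zeros(300, int)
        overlap = np.zeros(300, int)
        with pytest.warns(UserWarning, match="outside molecule"):
            col = psi_quant.psi_ratio_column(
                _profile(starts, overlap), _sites(("M", 300)), offset=1
            )
        assert np.isnan(col.loc["M:300", "ratio"])

    @pytest.mark.parametrize("f", [0.25, 0.75])
    def test_simulated_ratio_within_three_se_of_oracle(self, f, sam_of_reads):
        cfg = synthetic.SimPsiConfig(
            molecule_lengths={"M": 400},
            sites=[synthetic.PsiSite("M", 201, f)],
            termination_efficiency=1.0,
            background_stop_rate=0.0,
            coverage=2000,
            seed=21,
        )
        reads, _ = synthetic.simulate_termination_reads(cfg, "S")
        sam = sam_of_reads(reads, cfg.molecule_lengths, f"f{f}.sam")
        prof = psi_quant.build_profile(sam, cfg.molecule_lengths, "S")
        col = psi_quant.psi_ratio_column(prof, _sites(("M", 201)))
        expected = expected_psi_ratio(400, {201: f}, 201, 0.0, cfg.mean_read_length)
        n = col.loc["M:201", "n_overlap"]
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(col.loc["M:201", "ratio"] - expected) < 3 * se

    @given(
        starts=st.integers(min_value=0, max_value=500),
        extra=st.integers(min_value=0, max_value=500),
    )
    @settings(max_examples=50, deadline=None)
    def test_ratio_always_bounded(self, starts, extra):
        st_arr = np.zeros(120, int)
        ov_arr = np.zeros(120, int)
        st_arr[59] = starts
        ov_arr[59] = starts + extra
        col = psi_quant.psi_ratio_column(
            _profile(st_arr, ov_arr), _sites(("M", 60)), min_coverage=1
        )
        ratio = col.loc["M:60", "ratio"]
        assert np.isnan(ratio) or 0.0 <= ratio <= 1.0


class TestRegionSum:
    def test_sum_over_hotspot(self, ratio_matrix_factory):
        values = pd.DataFrame(
            {"s1": [0.2, 0.3, 0.1]},
            index=["18S:105", "18S:109", "18S:119"],
        )
        sums, complete = psi_quant.region_sum(
            ratio_matrix_factory(values), "18S", [105, 109, 119]
        )
        assert sums["s1"] == pytest.approx(0.6)
        assert complete["s1"]

    def test_sample_with_missing_site_flagged(self, ratio_matrix_factory):
        values = pd.DataFrame(
            {"s1": [0.2, np.nan, 0.1], "s2": [0.1, 0.2, 0.3]},
            index=["18S:105", "18S:109", "18S:119"],
        )
        sums, complete = psi_quant.region_sum(
            ratio_matrix_factory(values), "18S", [105, 109, 119]
        )
        assert not complete["s1"] and np.isnan(sums["s1"])
        assert complete["s2"] and sums["s2"] == pytest.approx(0.6)

    def test_empty_region_rejected(self, ratio_matrix_factory):
        values = pd.DataFrame({"s1": [0.2]}, index=["18S:105"])
        with pytest.raises(ValueError, match="empty region"):
            psi_quant.region_sum(ratio_matrix_factory(values), "18S", [])

    def test_unknown_site_rejected(self, ratio_matrix_factory):
        values = pd.DataFrame({"s1": [0.2]}, index=["18S:105"])
        with pytest.raises(ValueError, match="absent"):
            psi_quant.region_sum(ratio_matrix_factory(values), "18S", [105, 999])
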