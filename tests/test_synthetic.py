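"""Generator correctness: construction, determinism, conservation, nulls."""

import numpy as np
import pandas as pd
import pytest

from oracles import expected_psi_ratio
from psiforge import io, psi_quant, synthetic


def _psi_config(**kw):
    base = dict(
        molecule_lengths={"18S-like": 500},
        sites=[synthetic.PsiSite("18S-like", 105, 0.5)],
        termination_efficiency=1.0,
        background_stop_rate=0.0,
        coverage=100,
        seed=1,
    )
    base.update(kw)
    return synthetic.SimPsiConfig(**base)


class TestReference:
    def test_hotspot_reference_has_t_at_sites(self, hotspot_config):
        seqs, table = synthetic.make_reference(hotspot_config)
        assert len(seqs["18S-like"]) == 500
        for pos in (105, 109, 119):
            assert seqs["18S-like"][pos - 1] == "T"
        assert table["site_id"].tolist() == ["18S-like:105", "18S-like:109", "18S-like:119"]

    def test_reference_fasta_bytes_deterministic(self, hotspot_config, tmp_path):
        blobs = []
        for name in ("a.fa", "b.fa"):
            seqs, _ = synthetic.make_reference(hotspot_config)
            io.write_fasta(seqs, tmp_path / name)
            blobs.append((tmp_path / name).read_bytes())
        assert blobs[0] == blobs[1]

    def test_site_beyond_molecule_rejected_with_site_named(self):
        with pytest.raises(ValueError, match="18S-like:600"):
            _psi_config(sites=[synthetic.PsiSite("18S-like", 600, 0.5)])

    @pytest.mark.parametrize(
        "kw",
        [
            {"background_stop_rate": 0.2},
            {"termination_efficiency": 1.5},
            {"molecule_lengths": {"x": 150}, "sites": []},
            {"termination_offset": 2},
            {"sites": [synthetic.PsiSite("18S-like", 105, 1.3)]},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            _psi_config(**kw)


class TestTerminationReads:
    def test_forced_termination_gives_ratio_one(self, sam_of_reads):
        cfg = _psi_config(sites=[synthetic.PsiSite("18S-like", 250, 1.0)], coverage=50)
        reads, _ = synthetic.simulate_termination_reads(cfg, "S")
        sam = sam_of_reads(reads, cfg.molecule_lengths)
        prof = psi_quant.build_profile(sam, cfg.molecule_lengths, "S")
        col = psi_quant.psi_ratio_column(prof, synthetic.make_reference(cfg)[1], min_coverage=5)
        assert col.loc["18S-like:250", "ratio"] == 1.0

    def test_null_stoichiometry_matches_fragmentation_baseline(self, sam_of_reads):
        cfg = _psi_config(sites=[synthetic.PsiSite("18S-like", 250, 0.0)], coverage=800, seed=4)
        reads, _ = synthetic.simulate_termination_reads(cfg, "S")
        sam = sam_of_reads(reads, cfg.molecule_lengths)
        prof = psi_quant.build_profile(sam, cfg.molecule_lengths, "S")
        col = psi_quant.psi_ratio_column(prof, synthetic.make_reference(cfg)[1])
        expected = expected_psi_ratio(500, {250: 0.0}, 250, 0.0, cfg.mean_read_length)
        n = col.loc["18S-like:250", "n_overlap"]
        se = np.sqrt(max(expected * (1 - expected), 1e-9) / n)
        assert abs(col.loc["18S-like:250", "ratio"] - expected) < 3 * se

    def test_same_seed_reproduces_sam_bytes(self, hotspot_config, tmp_path):
        seqs, _ = synthetic.make_reference(hotspot_config)
        blobs = []
        for name in ("a.sam", "b.sam"):
            reads, _ = synthetic.simulate_termination_reads(hotspot_config, "S1")
            io.write_sam(tmp_path / name, hotspot_config.molecule_lengths, reads, seqs)
            blobs.append((tmp_path / name).read_bytes())
        assert blobs[0] == blobs[1]

    def test_coverage_close_to_target(self, hotspot_config):
        reads, _ = synthetic.simulate_termination_reads(hotspot_config, "S1")
        total_bases = sum(end - start + 1 for _, start, end, _ in reads)
        mean_cov = total_bases / 500
        assert abs(mean_cov - hotspot_config.coverage) / hotspot_config.coverage < 0.1

    def test_offset_one_shifts_stop_downstream_of_site(self, sam_of_reads):
        cfg = _psi_config(
            sites=[synthetic.PsiSite("18S-like", 250, 1.0)], coverage=60, termination_offset=1
        )
        reads, _ = synthetic.simulate_termination_reads(cfg, "S")
        sam = sam_of_reads(reads, cfg.molecule_lengths)
        prof = psi_quant.build_profile(sam, cfg.molecule_lengths, "S")
        # every read crossing the site stops one base 3' of it
        assert prof.starts["18S-like"][250] > 0  # index 250 = position 251
        assert prof.starts["18S-like"][249] == 0
        col = psi_quant.psi_ratio_column(
            prof, synthetic.make_reference(cfg)[1], offset=1, min_coverage=5
        )
        assert col.loc["18S-like:250", "ratio"] == 1.0

    def test_expected_ratio_monotone_in_stoichiometry_by_oracle(self):
        vals = [
            expected_psi_ratio(500, {250: f * 0.9}, 250, 0.01, 80.0)
            for f in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestSnornaCounts:
    def test_upregulated_set_has_configured_expected_ratio(self):
        cfg = synthetic.SimCountConfig(seed=9, fold_change=4.0)
        counts, totals, design, truth = synthetic.simulate_snorna_counts(cfg)
        up = truth["upregulated"].to_numpy()
        t_cols = design["sample_a"].tolist()
        n_cols = design["sample_b"].tolist()
        cpm_t = (counts[t_cols] / totals[t_cols] * 1e6).mean(axis=1)
        cpm_n = (counts[n_cols] / totals[n_cols] * 1e6).mean(axis=1)
        obs_fc = (cpm_t[up] / cpm_n[up]).mean()
        assert 3.0 < obs_fc < 5.0
        assert 0.8 < (cpm_t[~up] / cpm_n[~up]).mean() < 1.25

    def test_class_labels_and_design_shape(self):
        cfg = synthetic.SimCountConfig(n_cd=5, n_haca=4, n_pairs=3, n_upregulated=2, seed=0)
        counts, totals, design, truth = synthetic.simulate_snorna_counts(cfg)
        assert counts.shape == (9, 6)
        assert (truth["sno_class"].value_counts() == pd.Series({"CD_box": 5, "HACA_box": 4})).all()
        assert set(design.columns) == {"unit", "sample_a", "sample_b"}
        assert (totals >= counts.sum(axis=0)).all()

    def test_too_few_snornas_per_class_rejected(self):
        with pytest.raises(ValueError, match="2 snoRNAs per class"):
            synthetic.SimCountConfig(n_cd=1, n_haca=5)

    def test_identical_seed_identical_counts(self):
        a = synthetic.simulate_snorna_counts(synthetic.SimCountConfig(seed=3))[0]
        b = synthetic.simulate_snorna_counts(synthetic.SimCountConfig(seed=3))[0]
        pd.testing.assert_frame_equal(a, b)


class TestScreenCounts:
    def test_depth_conservation_per_sample(self):
        cfg = synthetic.SimScreenConfig(
            targets=[synthetic.TargetSpec("A", 3, -0.2), synthetic.TargetSpec("B", 2, 0.0)],
            n_nontargeting=5, depth=50_000, seed=2,
        )
        table, _ = synthetic.simulate_screen_counts(cfg)
        for col in table.columns:
            if col.startswith("d"):
                assert table[col].sum() == 50_000

    def test_fitness_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="growth model undefined"):
            synthetic.SimScreenConfig(targets=[synthetic.TargetSpec("A", 3, -1.0)])

    def test_day_zero_required(self):
        with pytest.raises(ValueError, match="day 0"):
            synthetic.SimScreenConfig(
                targets=[synthetic.TargetSpec("A", 2, 0.0)], timepoints_days=(3, 9)
            )

    def test_every_grna_maps_to_one_target(self):
        cfg = synthetic.SimScreenConfig(
            targets=[synthetic.TargetSpec("A", 2, 0.1)], n_nontargeting=3, depth=1000, seed=0
        )
        table, _ = synthetic.simulate_screen_counts(cfg)
        assert table["grna"].is_unique
        assert set(table["target"]) == {"A", synthetic.NONTARGETING}
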