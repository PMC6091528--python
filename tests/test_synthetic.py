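import networkx as nx
import numpy as np
import pytest

import metabomark as mm
from metabomark.errors import ConfigurationError


class TestFeatureTableGeneration:
    def test_design_sample_counts(self):
        """5 levels x 5 tubes x 4 individuals = 20 per group, 100 total."""
        cfg = mm.SyntheticConfig(n_bins=50, seed=0)
        table, _ = mm.generate_feature_table(cfg)
        assert table.n_samples == 100
        counts = table.sample_meta.groupby("concentration_ug_per_L").size()
        assert set(counts) == {20}
        assert len(counts) == 5

    @pytest.mark.parametrize("tubes,indiv,concs", [
        (3, 2, (0.0, 1250.0)), (2, 5, (0.0, 10.0, 50.0)),
    ])
    def test_sample_count_formula(self, tubes, indiv, concs):
        cfg = mm.SyntheticConfig(n_bins=20, tubes_per_group=tubes,
                                 individuals_per_tube=indiv, concentrations=concs,
                                 n_planted=5, seed=1)
        table, _ = mm.generate_feature_table(cfg)
        assert table.n_samples == len(concs) * tubes * indiv

    def test_strictly_positive_abundances(self):
        table, _ = mm.generate_feature_table(mm.SyntheticConfig(n_bins=40, seed=2))
        assert (table.values() > 0).all()

    def test_seed_reproducibility_byte_identical(self, tmp_path):
        cfg = mm.SyntheticConfig(n_bins=30, seed=5)
        a, ta = mm.generate_feature_table(cfg)
        b, tb = mm.generate_feature_table(mm.SyntheticConfig(n_bins=30, seed=5))
        a.to_tsv(tmp_path / "a.tsv")
        b.to_tsv(tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
        assert ta.planted_bins == tb.planted_bins

    def test_planted_shift_matches_dose_model(self):
        """Planted bins move by direction x effect x dose scale in log2 units."""
        cfg = mm.SyntheticConfig(n_bins=60, n_planted=8, effect_size=2.0,
                                 noise_sigma=0.1, tube_sigma=0.0, seed=3)
        table, truth = mm.generate_feature_table(cfg)
        conc = table.sample_meta["concentration_ug_per_L"].astype(float)
        log2 = np.log2(table.abundances)
        for b in truth.planted_bins:
            observed = (log2.loc[conc == 1250.0, b].mean()
                        - log2.loc[conc == 0.0, b].mean())
            expected = truth.per_bin_direction[b] * 2.0
            assert observed == pytest.approx(expected, abs=0.15)

    def test_step_dose_model(self):
        cfg = mm.SyntheticConfig(n_bins=10, n_planted=2, dose_model="step",
                                 step_threshold=250.0, seed=0)
        assert cfg.dose_scale(10.0) == 0.0
        assert cfg.dose_scale(250.0) == 1.0 == cfg.dose_scale(1250.0)

    def test_truth_json_round_trip(self, tmp_path):
        _, truth = mm.generate_feature_table(mm.SyntheticConfig(n_bins=20, n_planted=4,
                                                                seed=9))
        truth.to_json(tmp_path / "t.json")
        back = mm.SyntheticTruth.from_json(tmp_path / "t.json")
        assert back.planted_bins == truth.planted_bins
        assert back.per_bin_direction == truth.per_bin_direction

    @pytest.mark.parametrize("bad,fieldname", [
        (dict(n_bins=0), "n_bins"),
        (dict(n_planted=100, n_bins=10), "n_planted"),
        (dict(concentrations=(10.0, 50.0)), "concentrations"),
        (dict(concentrations=(0.0, -5.0)), "concentrations"),
        (dict(effect_size=-1.0), "effect_size"),
        (dict(noise_sigma=0.0), "noise_sigma"),
        (dict(tubes_per_group=0), "tubes_per_group"),
        (dict(dose_model="weird"), "dose_model"),
    ])
    def test_invalid_config_names_field(self, bad, fieldname):
        cfg = mm.SyntheticConfig(**{**dict(n_bins=20, n_planted=2), **bad})
        with pytest.raises(ConfigurationError, match=fieldname):
            mm.generate_feature_table(cfg)


class TestSpectralLibraryGeneration:
    def test_single_record_base_peak_999(self):
        lib = mm.generate_spectral_library(1, 8, seed=0)
        assert len(lib) == 1
        assert max(lib.entries[0].spectrum.intensities) == pytest.approx(999.0)

    def test_deterministic(self):
        a = mm.generate_spectral_library(10, 12, seed=4)
        b = mm.generate_spectral_library(10, 12, seed=4)
        assert [e.name for e in a] == [e.name for e in b]
        assert all(x.spectrum == y.spectrum for x, y in zip(a, b))

    def test_msp_round_trip_50_records(self, tmp_path):
        lib = mm.generate_spectral_library(50, 30, seed=6)
        lib.to_msp(tmp_path / "l.msp")
        back = mm.SpectralLibrary.from_msp(tmp_path / "l.msp")
        assert len(back) == 50
        for orig, loaded in zip(lib, back):
            assert loaded.name == orig.name
            assert loaded.spectrum.mz == orig.spectrum.mz
            np.testing.assert_allclose(loaded.spectrum.intensities,
                                       orig.spectrum.intensities, rtol=1e-5)
            assert loaded.spectrum.retention_time == pytest.approx(
                orig.spectrum.retention_time, abs=1e-6)

    def test_invalid_counts(self):
        with pytest.raises(ConfigurationError):
            mm.generate_spectral_library(0, 5)
        with pytest.raises(ConfigurationError):
            mm.generate_spectral_library(5, 0)


class TestPathwayLibraryGeneration:
    def test_exact_size_and_connected(self):
        lib = mm.generate_pathway_library(1, 20, (5, 5), seed=0)
        pw = lib.pathways[0]
        assert len(pw.compounds) == 5
        assert nx.is_connected(pw.graph)
        assert set(pw.graph.nodes) == set(pw.compounds)

    def test_union_within_background(self):
        lib = mm.generate_pathway_library(10, 1000, (5, 50), seed=1)
        union = set().union(*(p.compounds for p in lib))
        assert union <= lib.background
        assert len(lib.background) == 1000

    def test_serialization_deterministic(self, tmp_path):
        for tag in ("x", "y"):
            mm.generate_pathway_library(6, 50, (4, 12), seed=7).to_gmt(
                tmp_path / f"{tag}.gmt", edges_dir=tmp_path / f"{tag}.edges")
        assert (tmp_path / "x.gmt").read_bytes() == (tmp_path / "y.gmt").read_bytes()
        for f in sorted((tmp_path / "x.edges").iterdir()):
            assert f.read_bytes() == (tmp_path / "y.edges" / f.name).read_bytes()

    def test_infeasible_size_range(self):
        with pytest.raises(ConfigurationError):
            mm.generate_pathway_library(2, 10, (5, 20), seed=0)


class TestSpeciesBundle:
    def test_planted_bins_get_spectra_and_compounds(self):
        lib = mm.generate_spectral_library(20, 10, seed=2)
        cfg = mm.SyntheticConfig(n_bins=40, n_planted=6, tubes_per_group=2,
                                 individuals_per_tube=2, seed=3)
        bundle = mm.generate_species_bundle(cfg, lib)
        assert set(bundle.truth.bin_to_compound) == set(bundle.truth.planted_bins)
        assert set(bundle.bin_spectra) == set(bundle.truth.planted_bins)
        # measured spectra match their assigned library entry closely
        by_name = {e.name: e.spectrum for e in lib}
        for bin_id, comp in bundle.truth.bin_to_compound.items():
            sv = mm.match_factor(bundle.bin_spectra[bin_id], by_name[comp])
            assert sv > 950

    def test_forced_compound_pool_shared_between_species(self):
        lib = mm.generate_spectral_library(30, 10, seed=8)
        pool = lib.names()[:5]
        cfg_a = mm.SyntheticConfig(n_bins=30, n_planted=5, tubes_per_group=2,
                                   individuals_per_tube=2, seed=1)
        cfg_b = mm.SyntheticConfig(n_bins=30, n_planted=5, tubes_per_group=2,
                                   individuals_per_tube=2, seed=2)
        ba = mm.generate_species_bundle(cfg_a, lib, compounds=pool)
        bb = mm.generate_species_bundle(cfg_b, lib, compounds=pool)
        assert set(ba.truth.bin_to_compound.values()) == set(pool)
        assert set(bb.truth.bin_to_compound.values()) == set(pool)
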