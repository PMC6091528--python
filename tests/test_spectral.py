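import math

import numpy as np
import pytest

import metabomark as mm
from metabomark.errors import ConfigurationError, DataError
from metabomark.spectral import (INTENSITY_POWER, MZ_POWER, compound_best_sv,
                                 read_bin_spectra_msp, write_bin_spectra_msp)
from conftest import make_table


def random_spectrum(rng, n_peaks=12, rt=None, mz_lo=50, mz_hi=650):
    mz = np.sort(rng.choice(np.arange(mz_lo, mz_hi), size=n_peaks, replace=False))
    inten = rng.uniform(1.0, 999.0, size=n_peaks)
    return mm.Spectrum(tuple(float(m) for m in mz), tuple(float(i) for i in inten),
                       float(rt if rt is not None else rng.uniform(60, 1500)))


class TestMatchFactor:
    def test_hand_computed_weighted_cosine(self):
        """Oracle: direct evaluation of the weighted-cosine formula."""
        q = mm.Spectrum.from_peaks([(100.0, 999.0), (150.0, 500.0)])
        r = mm.Spectrum.from_peaks([(100.0, 999.0)])
        wq = np.array([100.0 ** MZ_POWER * 999.0 ** INTENSITY_POWER,
                       150.0 ** MZ_POWER * 500.0 ** INTENSITY_POWER])
        wr = np.array([100.0 ** MZ_POWER * 999.0 ** INTENSITY_POWER])
        expected = math.floor(999.0 * (wq[0] * wr[0]) /
                              (np.linalg.norm(wq) * np.linalg.norm(wr)))
        assert mm.match_factor(q, r) == expected == 531

    @pytest.mark.parametrize("seed", range(5))
    def test_self_match_is_999(self, seed):
        s = random_spectrum(np.random.default_rng(seed))
        assert mm.match_factor(s, s) == 999

    def test_proportional_spectra_score_999(self):
        s = random_spectrum(np.random.default_rng(9))
        scaled = mm.Spectrum(s.mz, tuple(i * 7.3 for i in s.intensities), s.retention_time)
        assert mm.match_factor(s, scaled) == 999

    def test_disjoint_spectra_score_0(self):
        rng = np.random.default_rng(1)
        a = random_spectrum(rng, mz_lo=50, mz_hi=300)
        b = random_spectrum(rng, mz_lo=350, mz_hi=650)
        assert mm.match_factor(a, b) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_symmetry_and_scale_invariance(self, seed):
        rng = np.random.default_rng(100 + seed)
        a, b = random_spectrum(rng), random_spectrum(rng)
        sv = mm.match_factor(a, b)
        assert sv == mm.match_factor(b, a)
        a_scaled = mm.Spectrum(a.mz, tuple(i * 0.017 for i in a.intensities),
                               a.retention_time)
        assert mm.match_factor(a_scaled, b) == sv

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_matchms_cosine_greedy(self, seed):
        """Independent oracle: matchms CosineGreedy with the same weighting."""
        from matchms import Spectrum as MSpectrum
        from matchms.similarity import CosineGreedy

        rng = np.random.default_rng(200 + seed)
        a, b = random_spectrum(rng, n_peaks=15), random_spectrum(rng, n_peaks=15)
        ma = MSpectrum(mz=np.array(a.mz), intensities=np.array(a.intensities),
                       metadata_harmonization=False)
        mb = MSpectrum(mz=np.array(b.mz), intensities=np.array(b.intensities),
                       metadata_harmonization=False)
        score = float(CosineGreedy(tolerance=0.5, mz_power=MZ_POWER,
                                   intensity_power=INTENSITY_POWER).pair(ma, mb)["score"])
        assert abs(mm.match_factor(a, b) - math.floor(999 * score + 1e-9)) <= 1

    def test_empty_spectrum_rejected(self):
        with pytest.raises(DataError):
            mm.Spectrum((), ())
        with pytest.raises(DataError):
            mm.Spectrum((100.0,), (0.0,))


class TestAnnotateBins:
    def _ranking(self, bins):
        return mm.RankedBins(order=bins, criterion=[0.0] * len(bins), schedule=[],
                             seed=0)

    def test_proportional_entry_at_matching_rt_accepted(self):
        rng = np.random.default_rng(3)
        ref = random_spectrum(rng, rt=300.0)
        measured = mm.Spectrum(ref.mz, tuple(i * 2.0 for i in ref.intensities), 300.02)
        library = mm.SpectralLibrary([mm.LibraryEntry("target", ref)])
        anns = mm.annotate_bins(self._ranking(["b1"]), 1, {"b1": measured}, library)
        assert len(anns) == 1
        assert anns[0].compound == "target"
        assert anns[0].similarity_value == 999 and anns[0].accepted

    def test_threshold_is_strict(self):
        # the hand case scores exactly 531: threshold 531 must reject it
        q = mm.Spectrum.from_peaks([(100.0, 999.0), (150.0, 500.0)], retention_time=10.0)
        r = mm.Spectrum.from_peaks([(100.0, 999.0)], retention_time=10.0)
        library = mm.SpectralLibrary([mm.LibraryEntry("c", r)])
        at = mm.annotate_bins(self._ranking(["b"]), 1, {"b": q}, library,
                              sv_threshold=531)
        below = mm.annotate_bins(self._ranking(["b"]), 1, {"b": q}, library,
                                 sv_threshold=530)
        assert at[0].similarity_value == 531
        assert not at[0].accepted and below[0].accepted

    def test_rt_window_excludes_candidates(self):
        rng = np.random.default_rng(4)
        ref = random_spectrum(rng, rt=500.0)
        measured = mm.Spectrum(ref.mz, ref.intensities, 500.2)  # 0.2 s away
        library = mm.SpectralLibrary([mm.LibraryEntry("far", ref)])
        assert mm.annotate_bins(self._ranking(["b"]), 1, {"b": measured}, library) == []

    def test_missing_spectra_skipped_not_fatal(self, caplog):
        library = mm.SpectralLibrary([])
        with caplog.at_level("WARNING"):
            anns = mm.annotate_bins(self._ranking(["b1", "b2"]), 2, {}, library)
        assert anns == [] and "no measured spectrum" in caplog.text

    def test_top_k_bounds(self):
        with pytest.raises(ConfigurationError):
            mm.annotate_bins(self._ranking(["b1"]), 2, {}, mm.SpectralLibrary([]))

    def test_output_no_larger_than_top_k(self):
        rng = np.random.default_rng(6)
        library = mm.generate_spectral_library(5, 10, seed=1)
        spectra = {f"b{i}": random_spectrum(rng, rt=library.entries[0].spectrum.retention_time)
                   for i in range(4)}
        anns = mm.annotate_bins(self._ranking([f"b{i}" for i in range(4)]), 3,
                                spectra, library)
        assert len(anns) <= 3
        for a in anns:
            assert abs(a.rt_delta) <= 0.05

    def test_compound_dedup_keeps_max_sv(self):
        anns = [mm.Annotation("b1", "X", 800, 0.0, True),
                mm.Annotation("b2", "X", 950, 0.0, True),
                mm.Annotation("b3", "Y", 650, 0.0, False)]
        best = compound_best_sv(anns)
        assert best["X"].similarity_value == 950 and "Y" not in best
        assert compound_best_sv(anns, accepted_only=False)["Y"].similarity_value == 650


class TestDirectionSign:
    def _table(self):
        X = np.array([[0.1, 0.3], [0.1, 0.3], [0.4, 0.3], [0.4, 0.3]])
        return make_table(X, concentrations=[0, 0, 1250, 1250])

    def test_signs(self):
        table = self._table()
        assert mm.direction_sign(table, table.bin_ids[0], 1250.0) == "+"
        assert mm.direction_sign(table, table.bin_ids[1], 1250.0) == "0"

    def test_negative_direction(self):
        X = np.array([[0.5], [0.5], [0.2], [0.2]])
        table = make_table(X, concentrations=[0, 0, 1250, 1250])
        assert mm.direction_sign(table, table.bin_ids[0], 1250.0) == "-"

    def test_unknown_bin_or_level(self):
        table = self._table()
        with pytest.raises(DataError):
            mm.direction_sign(table, "nope", 1250.0)
        with pytest.raises(DataError):
            mm.direction_sign(table, table.bin_ids[0], 42.0)


def test_bin_spectra_msp_round_trip(tmp_path):
    rng = np.random.default_rng(8)
    spectra = {f"RT{i}.0_MZ{70 + i}": random_spectrum(rng) for i in range(5)}
    path = tmp_path / "bins.msp"
    write_bin_spectra_msp(spectra, path)
    back = read_bin_spectra_msp(path)
    assert set(back) == set(spectra)
    for k in spectra:
        assert back[k].mz == spectra[k].mz
        # the writer keeps 6 significant digits
        assert back[k].retention_time == pytest.approx(spectra[k].retention_time,
                                                       abs=0.01)
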