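"""FIA MS1 chain: recalibration, normalization, detection, consensus,
gap filling, isotope collapsing, annotation."""

import numpy as np
import pytest

import metabodyn as md
from metabodyn.fia import (
    CalibrationError,
    NormalizationError,
    default_max_isotope_ratio,
)
from metabodyn.synthetic import CompoundRecord

from conftest import make_table

REFS = (112.9856, 301.9981, 601.9790, 922.0098)


def spectrum_with_drift(refs=REFS, drift=(0.0, 0.0, 0.0), extra=(), sid="s1"):
    a, b, c = drift
    true = np.array(list(refs) + [m for m, _ in extra])
    inten = np.array([1e6] * len(refs) + [i for _, i in extra])
    obs = true + a + b * true + c * true**2
    return md.Spectrum(sid, obs, inten)


class TestRecalibration:
    def test_exact_coefficient_recovery(self):
        drift = (1e-3, 2e-6, 5e-10)
        sp = spectrum_with_drift(drift=drift)
        model = md.fit_mass_recalibration(sp, REFS)
        assert model.coefficients == pytest.approx(drift, abs=1e-12)
        assert np.abs(model.residuals).max() <= 1e-9

    def test_zero_drift_gives_identity(self):
        sp = spectrum_with_drift()
        model = md.fit_mass_recalibration(sp, REFS)
        assert np.abs(model.coefficients).max() < 1e-12
        corrected = md.apply_recalibration(sp, model)
        assert corrected.mz == pytest.approx(sp.mz, abs=1e-12)

    def test_two_matched_references_error(self):
        sp = spectrum_with_drift(refs=REFS[:2])
        with pytest.raises(CalibrationError, match="601.979"):
            md.fit_mass_recalibration(sp, REFS)

    def test_corrected_reference_peaks_land_on_references(self):
        sp = spectrum_with_drift(drift=(2e-3, -3e-6, 1e-9))
        model = md.fit_mass_recalibration(sp, REFS)
        corrected = md.apply_recalibration(sp, model)
        for r in REFS:
            assert np.min(np.abs(corrected.mz - r)) < 1e-9

    def test_idempotence_on_noise_free_drift(self):
        sp = spectrum_with_drift(drift=(1e-3, 2e-6, 5e-10),
                                 extra=[(500.123, 5e5)])
        m1 = md.fit_mass_recalibration(sp, REFS)
        c1 = md.apply_recalibration(sp, m1)
        m2 = md.fit_mass_recalibration(c1, REFS)
        c2 = md.apply_recalibration(c1, m2)
        assert np.abs(c2.mz - c1.mz).max() < 1e-9


class TestNormalization:
    def test_scale_invariance(self):
        sp1 = spectrum_with_drift(extra=[(500.0, 2e5)])
        sp2 = sp1.with_peaks(sp1.mz, sp1.intensity * 2)
        n1 = md.normalize_by_reference(sp1, REFS)
        n2 = md.normalize_by_reference(sp2, REFS)
        assert n1.intensity == pytest.approx(n2.intensity)

    def test_division_by_reference_sum(self):
        sp = md.Spectrum("s", [100.0, 301.9981], [500.0, 1000.0])
        out = md.normalize_by_reference(sp, REFS)
        assert out.intensity[0] == pytest.approx(0.5)

    def test_missing_reference_error(self):
        sp = md.Spectrum("s", [100.0], [1.0])
        with pytest.raises(NormalizationError):
            md.normalize_by_reference(sp, REFS)


class TestTopPeaks:
    def test_keeps_most_intense(self):
        sp = md.Spectrum("s", [10, 20, 30, 40, 50], [5, 3, 9, 1, 7])
        out = md.detect_top_peaks(sp, 3)
        assert list(out.mz) == [10, 30, 50]

    def test_tie_at_rank_n_prefers_lower_mz(self):
        sp = md.Spectrum("s", [10, 20, 30], [5.0, 1.0, 1.0])
        out = md.detect_top_peaks(sp, 2)
        assert list(out.mz) == [10, 20]

    def test_short_spectrum_returned_whole(self):
        sp = md.Spectrum("s", [10.0], [1.0])
        assert len(md.detect_top_peaks(sp, 1000)) == 1

    def test_empty_spectrum(self):
        sp = md.Spectrum("s", [], [])
        assert len(md.detect_top_peaks(sp, 10)) == 0


class TestConsensus:
    def test_same_peak_across_samples_is_one_feature(self):
        sps = [md.Spectrum(f"s{i}", [200.0], [1.0]) for i in range(3)]
        feats = md.build_consensus_features(sps, tol_ppm=5)
        assert len(feats) == 1 and len(feats[0].members) == 3

    def test_distant_peaks_stay_separate(self):
        sps = [md.Spectrum("s1", [200.0, 200.01], [1.0, 1.0])]
        feats = md.build_consensus_features(sps, tol_ppm=5)
        assert len(feats) == 2

    def test_representative_is_intensity_weighted_mean(self):
        sps = [
            md.Spectrum("s1", [200.0], [100.0]),
            md.Spectrum("s2", [200.0005], [300.0]),
        ]
        feats = md.build_consensus_features(sps, tol_ppm=5)
        assert len(feats) == 1
        # (200.0*100 + 200.0005*300) / 400
        assert feats[0].representative_mz == pytest.approx(200.000375, abs=1e-9)

    def test_sample_order_invariance(self, design):
        _, truth = md.generate_feature_table(design, n_features=40, seed=8)
        spectra = md.generate_fia_spectra(truth, design, seed=8)
        pls = [md.detect_top_peaks(sp, 1000) for sp in spectra]
        f1 = md.build_consensus_features(pls, 5)
        f2 = md.build_consensus_features(pls[::-1], 5)
        assert [f.representative_mz for f in f1] == [f.representative_mz for f in f2]


class TestGapFilling:
    def test_detected_everywhere_matches_detection(self):
        sps = [md.Spectrum(f"s{i}", [200.0], [float(i + 1)]) for i in range(3)]
        feats = md.build_consensus_features(sps, 5)
        table = md.fill_gaps(sps, feats, 5)
        assert list(table.values.iloc[0]) == [1.0, 2.0, 3.0]

    def test_subthreshold_peak_recovered_from_raw(self):
        # s2's peak at 200.0 is below its top-1 cut but present in raw data
        raw = [
            md.Spectrum("s1", [200.0], [100.0]),
            md.Spectrum("s2", [200.0, 300.0], [7.0, 1000.0]),
        ]
        peaklists = [md.detect_top_peaks(sp, 1) for sp in raw]
        feats = md.build_consensus_features(peaklists, 5)
        table = md.fill_gaps(raw, feats, 5)
        assert table.values.loc[table.feature_meta["mz"].sub(200).abs().idxmin(),
                                "s2"] == pytest.approx(7.0)

    def test_truly_absent_is_zero(self):
        raw = [md.Spectrum("s1", [200.0], [10.0]), md.Spectrum("s2", [300.0], [5.0])]
        feats = md.build_consensus_features(raw, 5)
        table = md.fill_gaps(raw, feats, 5)
        f200 = table.feature_meta["mz"].sub(200).abs().idxmin()
        assert table.values.loc[f200, "s2"] == 0.0
        assert not table.values.isna().any().any()


class TestIsotopeCollapse:
    def _two_peak_table(self, ratio):
        vals = np.array([[100.0, 110.0, 90.0], [100.0 * ratio] * 3])
        return make_table(vals, mz=[200.0, 201.00335], n_replicates=3,
                          time_points=[0])

    def test_plausible_ratio_collapses_and_sums(self):
        table = self._two_peak_table(0.11)
        out = md.collapse_isotopes(table, delta_tol=0.005)
        assert out.n_features == 1
        assert out.feature_meta["n_collapsed"].iloc[0] == 1
        assert out.values.iloc[0].tolist() == pytest.approx(
            (table.values.iloc[0] + table.values.iloc[1]).tolist()
        )

    def test_implausible_ratio_not_collapsed(self):
        out = md.collapse_isotopes(self._two_peak_table(3.0), delta_tol=0.005)
        assert out.n_features == 2

    def test_planted_chain_collapses_to_single_feature(self):
        # M, M+1, M+2 for a 30-carbon molecule
        r1 = md.isotopologue_ratio(30, 1)
        r2 = md.isotopologue_ratio(30, 2)
        vals = np.array([[1e6] * 3, [1e6 * r1] * 3, [1e6 * r2] * 3])
        table = make_table(vals, mz=[400.0, 401.00335, 402.0067],
                           n_replicates=3, time_points=[0])
        out = md.collapse_isotopes(table, delta_tol=0.005)
        assert out.n_features == 1
        assert out.feature_meta["n_collapsed"].iloc[0] == 2

    def test_total_intensity_conserved(self, design):
        table, truth = md.generate_feature_table(design, n_features=50, seed=12)
        spectra = md.generate_fia_spectra(truth, design, seed=12)
        raw = md.process_fia_batch(spectra, md.TUNE_MIX_NEGATIVE, collapse=False)
        out = md.collapse_isotopes(raw)
        before = raw.values.sum(axis=0)
        after = out.values.sum(axis=0)
        assert np.abs(after - before).div(before).max() < 1e-9

    def test_keep_mono_drops_isotope_intensity(self):
        table = self._two_peak_table(0.11)
        out = md.collapse_isotopes(table, delta_tol=0.005, keep="mono")
        assert out.values.iloc[0].tolist() == pytest.approx(
            table.values.iloc[0].tolist()
        )

    def test_max_ratio_scales_with_mass(self):
        assert default_max_isotope_ratio(600.0) == pytest.approx(
            1.5 * 0.0107 * 50.0
        )


class TestAnnotation:
    DB = [
        CompoundRecord("LAC", "lactic acid", "C3H6O3", 90.03169),
        CompoundRecord("A", "a", "C4H8O2", 88.05243),
        CompoundRecord("B", "b (isobar of a)", "C3H4N2O", 88.05243 + 0.0005),
    ]

    def _table(self, mz):
        return make_table(np.ones((len(mz), 1)), mz=mz, time_points=[0])

    def test_lactic_acid_negative_mode(self):
        anns = md.annotate_features(self._table([89.024414]), self.DB, "-", 3.0)
        cands = anns[0].candidates
        assert any(cid == "LAC" for cid, _, _ in cands)
        cid, adduct, err = next(c for c in cands if c[0] == "LAC")
        assert adduct == "[M-H]-"
        assert abs(err) < 0.01  # mDa

    def test_multi_annotation_for_close_isobars(self):
        anns = md.annotate_features(self._table([88.05243 - 1.007276]),
                                    self.DB, "-", 1.0)
        assert {c[0] for c in anns[0].candidates} == {"A", "B"}

    def test_far_feature_unannotated(self):
        anns = md.annotate_features(self._table([85.0]), self.DB, "-", 3.0)
        assert anns[0].candidates == []

    def test_positive_mode_uses_protonated_adduct(self):
        anns = md.annotate_features(self._table([90.03169 + 1.007276]),
                                    self.DB, "+", 1.0)
        assert anns[0].candidates[0][1] == "[M+H]+"


class TestEndToEnd:
    def test_planted_features_recovered(self, design):
        table, truth = md.generate_feature_table(design, n_features=60, seed=21)
        spectra = md.generate_fia_spectra(truth, design, seed=21)
        out = md.process_fia_batch(spectra, md.TUNE_MIX_NEGATIVE,
                                   sample_meta=design.sample_meta())
        reps = out.feature_meta["mz"].to_numpy()
        found = sum(
            np.min(np.abs(reps - f.true_mz)) <= 5e-6 * f.true_mz
            for f in truth.features
        )
        assert found / len(truth.features) >= 0.95
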