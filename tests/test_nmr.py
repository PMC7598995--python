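"""The NMR screening calculus: CSP, mixtures, STD/WaterLOGSY, Kd fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from htsumd.errors import UnidentifiableError, ValidationError
from htsumd.nmr import (ADDITIVITY_COMPATIBLE, ADDITIVITY_UNEXPLAINED,
                        EVIDENCE_BINDER, EVIDENCE_CONTROVERSIAL,
                        EVIDENCE_NEGATIVE, MIXTURE_DISCARD, MIXTURE_FIRST,
                        MIXTURE_SECOND, CspResult, Peak, StdMeasurement,
                        Titration, additivity_check, bound_fraction,
                        classify_mixture, combine_ligand_evidence, csp,
                        csp_panel, design_mixtures, default_kd_grid, fit_kd,
                        fstd, waterlogsy_call)
from htsumd.synth import NmrSynthSpec, synth_titration


def _peak(res, dh, dn):
    return Peak(res, dh, dn)


class TestCsp:
    def test_zero_change_is_zero(self):
        assert csp(_peak("A1", 8.0, 120.0), _peak("A1", 8.0, 120.0)) == 0.0

    def test_hand_value(self):
        # dH = 0.1, dN = 0.5: sqrt((0.01 + 0.01)/2) = 0.1
        value = csp(_peak("A1", 8.0, 120.0), _peak("A1", 8.1, 120.5))
        assert value == pytest.approx(0.1, abs=1e-12)

    @given(st.floats(min_value=-0.5, max_value=0.5,
                     allow_nan=False, allow_subnormal=False))
    def test_nitrogen_scale_symmetry(self, x):
        """dH = x with dN = 5x gives exactly |x| for any x."""
        value = csp(_peak("A1", 8.0, 120.0), _peak("A1", 8.0 + x,
                                                   120.0 + 5 * x))
        assert value == pytest.approx(abs(x), abs=1e-9)

    @given(st.floats(min_value=-0.3, max_value=0.3, allow_nan=False),
           st.floats(min_value=-1.5, max_value=1.5, allow_nan=False),
           st.floats(min_value=0.0, max_value=4.0, allow_nan=False))
    @settings(max_examples=60)
    def test_direction_symmetry_and_linearity(self, dh, dn, k):
        """CSP is symmetric in which spectrum is apo and scales linearly."""
        apo = _peak("A1", 8.0, 118.0)
        mix = _peak("A1", 8.0 + dh, 118.0 + dn)
        forward = csp(apo, mix)
        backward = csp(mix, apo)
        assert forward == pytest.approx(backward, rel=1e-9, abs=1e-12)
        scaled = csp(apo, _peak("A1", 8.0 + k * dh, 118.0 + k * dn))
        assert scaled == pytest.approx(k * forward, rel=1e-9, abs=1e-9)

    def test_label_mismatch_raises(self):
        with pytest.raises(ValidationError):
            csp(_peak("A1", 8.0, 120.0), _peak("B2", 8.0, 120.0))


class TestClassifyMixture:
    @pytest.mark.parametrize("mean,expected", [
        (0.40, MIXTURE_FIRST),
        (0.30, MIXTURE_SECOND),
        (0.20, MIXTURE_DISCARD),
        (0.35, MIXTURE_SECOND),    # boundary: "larger than 0.35" is strict
        (0.25, MIXTURE_DISCARD),   # boundary: 0.25 itself is discarded
    ])
    def test_classes(self, mean, expected):
        assert classify_mixture(CspResult({"A1": mean})) == expected

    def test_monotone_in_mean(self):
        order = {MIXTURE_DISCARD: 0, MIXTURE_SECOND: 1, MIXTURE_FIRST: 2}
        classes = [order[classify_mixture(CspResult({"A1": m}))]
                   for m in np.linspace(0.0, 0.6, 61)]
        assert classes == sorted(classes)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValidationError):
            classify_mixture(CspResult({}))

    def test_panel_mean(self):
        apo = {r: _peak(r, 8.0, 120.0) for r in ("A", "B")}
        mix = {"A": _peak("A", 8.1, 120.5), "B": _peak("B", 8.0, 120.0)}
        result = csp_panel(apo, mix)
        assert result.mean == pytest.approx(0.05)


class TestDesignMixtures:
    def _peaklists(self, n, rng):
        return {f"F{i:03d}": rng.uniform(0.5, 9.5, rng.integers(3, 8))
                for i in range(n)}

    def test_hundred_fragments_give_twenty_mixtures(self):
        rng = np.random.default_rng(0)
        plan = design_mixtures(self._peaklists(100, rng), mixture_size=5,
                               seed=0)
        assert len(plan.mixtures) == 20
        assert all(len(m) == 5 for m in plan.mixtures)

    def test_partition_property(self):
        rng = np.random.default_rng(1)
        peaklists = self._peaklists(23, rng)
        plan = design_mixtures(peaklists, mixture_size=5, seed=3)
        flat = [f for m in plan.mixtures for f in m]
        assert sorted(flat) == sorted(peaklists)

    def test_remainder_forms_smaller_mixture(self):
        rng = np.random.default_rng(2)
        plan = design_mixtures(self._peaklists(7, rng), mixture_size=5)
        assert sorted(len(m) for m in plan.mixtures) == [2, 5]

    def test_identical_spectra_split_apart(self):
        peaks = {"Fa": [1.0, 2.0, 3.0], "Fb": [1.0, 2.0, 3.0],
                 "Fc": [7.0], "Fd": [8.0]}
        plan = design_mixtures(peaks, mixture_size=2, seed=0)
        homes = {f: i for i, m in enumerate(plan.mixtures) for f in m}
        assert homes["Fa"] != homes["Fb"]

    def test_swap_refinement_not_worse_than_greedy(self):
        rng = np.random.default_rng(5)
        peaklists = self._peaklists(30, rng)
        full = design_mixtures(peaklists, mixture_size=5, seed=1)
        greedy_only = design_mixtures(peaklists, mixture_size=5, seed=1,
                                      max_sweeps=0)
        assert full.overlap_cost <= greedy_only.overlap_cost

    def test_fragment_without_peaks_rejected(self):
        with pytest.raises(ValidationError):
            design_mixtures({"Fa": [], "Fb": [1.0]}, mixture_size=2)


class TestFstd:
    def test_null_difference_is_nonbinder(self):
        m = StdMeasurement(i_std_prot=0.1, i_std_0=0.1, i_0=1.0,
                           l_tot=600, p_tot=25)
        value, binder = fstd(m)
        assert value == 0.0 and not binder

    def test_hand_value(self):
        m = StdMeasurement(i_std_prot=0.15, i_std_0=0.05, i_0=1.0,
                           l_tot=600, p_tot=25)
        value, binder = fstd(m)
        assert value == pytest.approx(240.0)
        assert binder

    def test_boundary_fifty_is_binder(self):
        # (0.05 - 0.0)/1.0 * (10/1) * 100 = 50 exactly
        m = StdMeasurement(i_std_prot=0.05, i_std_0=0.0, i_0=1.0,
                           l_tot=10, p_tot=1.0)
        value, binder = fstd(m)
        assert value == pytest.approx(50.0)
        assert binder

    def test_bad_reference_integral(self):
        with pytest.raises(ValidationError):
            StdMeasurement(i_std_prot=0.1, i_std_0=0.0, i_0=0.0,
                           l_tot=600, p_tot=25)


class TestWaterlogsyAndEvidence:
    def test_sign_flip_is_binder(self):
        assert waterlogsy_call({"p1": 1, "p2": 1},
                               {"p1": -1, "p2": 1}) == "binder"

    def test_all_positive_is_nonbinder(self):
        assert waterlogsy_call({"p1": 1}, {"p1": 1}) == "non-binder"

    def test_negative_control_is_ambiguous(self):
        assert waterlogsy_call({"p1": -1}, {"p1": -1}) == "ambiguous"

    @pytest.mark.parametrize("std,wl,expected", [
        (True, "binder", EVIDENCE_BINDER),
        (True, "non-binder", EVIDENCE_CONTROVERSIAL),
        (False, "binder", EVIDENCE_CONTROVERSIAL),
        (False, "non-binder", EVIDENCE_NEGATIVE),
        (False, "ambiguous", EVIDENCE_CONTROVERSIAL),
    ])
    def test_combination_rules(self, std, wl, expected):
        assert combine_ligand_evidence(std, wl) == expected


class TestFitKd:
    def test_noiseless_recovery_within_grid_cell(self):
        titration, truth = synth_titration(NmrSynthSpec(noise_sd=0.0, seed=0))
        fit = fit_kd(titration)
        grid = default_kd_grid()
        cell = np.max(np.diff(np.log(grid)))
        assert abs(np.log(fit.kd_mean) - np.log(truth["kd"])) < cell

    def test_noiseless_saturated_shifts_recovered(self):
        spec = NmrSynthSpec(noise_sd=0.0, seed=0)
        titration, truth = synth_titration(spec)
        fit = fit_kd(titration)
        for peak, pf in fit.per_peak.items():
            assert pf.delta_sat == pytest.approx(truth["delta_sat"][peak],
                                                 abs=5e-3)

    def test_flat_titration_unidentifiable(self):
        conc = np.array([0.0, 100.0, 500.0, 2000.0, 5000.0])
        titration = Titration(ligand_conc=conc,
                              shifts={f"p{i}": np.full(5, 8.0)
                                      for i in range(3)},
                              protein_conc=90.0)
        with pytest.raises(UnidentifiableError):
            fit_kd(titration)

    def test_two_peaks_rejected_without_override(self):
        titration, _ = synth_titration(NmrSynthSpec(noise_sd=0.0))
        titration.shifts.pop("peak3")
        with pytest.raises(ValidationError):
            fit_kd(titration)
        assert fit_kd(titration, min_peaks=2).kd_mean > 0

    def test_bound_fraction_limits(self):
        conc = np.array([0.0, 1e7])
        fb = bound_fraction(conc, p_tot=90.0, kd=1500.0)
        assert fb[0] == pytest.approx(0.0, abs=1e-12)
        assert fb[1] == pytest.approx(1.0, abs=1e-3)

    def test_median_relative_error_under_noise(self):
        """Parameter recovery over 50 seeded noisy titrations (noise
        0.005 ppm, 8 points, 90 uM protein, 0-5100 uM ligand)."""
        errors = []
        for seed in range(50):
            titration, truth = synth_titration(
                NmrSynthSpec(noise_sd=0.005, seed=seed))
            fit = fit_kd(titration)
            errors.append(abs(fit.kd_mean - truth["kd"]) / truth["kd"])
        assert np.median(errors) < 0.15


class TestAdditivity:
    def test_within_relative_band(self):
        assert additivity_check(0.40, [0.38], 0.25) == ADDITIVITY_COMPATIBLE

    def test_half_explained_is_unexplained(self):
        assert additivity_check(0.40, [0.20], 0.25) == ADDITIVITY_UNEXPLAINED

    def test_noise_floor_covers_empty_mixture(self):
        assert additivity_check(0.05, [], 0.25) == ADDITIVITY_COMPATIBLE

    def test_zero_mixture_with_nonzero_singles_invalid(self):
        with pytest.raises(ValidationError):
            additivity_check(0.0, [0.1], 0.25)

    def test_tolerance_domain(self):
        with pytest.raises(ValidationError):
            additivity_check(0.4, [0.4], 1.5)
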