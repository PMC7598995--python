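"""Scoring primitives: interaction-energy surrogate, hydrogen bonds, HYD."""

import numpy as np
import pytest

from htsumd.energetics import (EnergyModel, HBondCriteria, HydParams,
                               detect_hbonds, frame_energies,
                               frame_hyd_scores, hbond_occupancy, hyd_score,
                               interaction_energy)
from htsumd.errors import ClashError

from conftest import simple_fragment, simple_receptor


def _pair(receptor_q, fragment_q, r, rec_el="C", frag_el="C"):
    rec = simple_receptor([[0.0, 0.0, 0.0]], [rec_el],
                          charges=[receptor_q], res_numbers=[1])
    frag = simple_fragment([[r, 0.0, 0.0]], [frag_el], charges=[fragment_q])
    return rec, frag


class TestInteractionEnergy:
    def test_screened_coulomb_hand_value(self):
        # +1, -1 e at 3 A: 332.0637 * (-1) / (4 * 9) = -9.224 kcal/mol
        rec, frag = _pair(1.0, -1.0, 3.0)
        model = EnergyModel(use_lj=False, gamma=0.0)
        assert interaction_energy(rec, frag, model=model) == pytest.approx(
            -9.2240, abs=1e-3)

    def test_lj_zero_crossing_at_sigma(self):
        from htsumd._elements import lj_sigma

        rec, frag = _pair(0.0, 0.0, lj_sigma("C"))
        model = EnergyModel(use_coulomb=False, gamma=0.0)
        assert interaction_energy(rec, frag, model=model) == pytest.approx(
            0.0, abs=1e-12)

    def test_zero_beyond_cutoff(self):
        rec, frag = _pair(1.0, -1.0, 9.5)
        assert interaction_energy(rec, frag) == 0.0

    def test_clash_raises(self):
        rec, frag = _pair(0.0, 0.0, 0.3)
        with pytest.raises(ClashError):
            interaction_energy(rec, frag)

    def test_rigid_motion_invariance(self, toy_receptor, binder_fragment):
        """Moving both molecules rigidly leaves the energy unchanged."""
        from htsumd.systems import Receptor, make_atom_set

        pose = binder_fragment.coords + np.array([0.0, 0.0, 12.0])
        e0 = interaction_energy(toy_receptor, binder_fragment, pose)
        rng = np.random.default_rng(3)
        a = rng.standard_normal((3, 3))
        q, r = np.linalg.qr(a)
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        shift = np.array([5.0, -3.0, 2.0])
        moved_rec = make_atom_set(
            toy_receptor.elements, toy_receptor.coords @ q.T + shift,
            charges=toy_receptor.charges,
            res_numbers=toy_receptor.res_numbers,
            res_names=toy_receptor.res_names, cls=Receptor)
        e1 = interaction_energy(moved_rec, binder_fragment, pose @ q.T + shift)
        assert abs(e1 - e0) < 1e-9

    def test_frame_energies_match_scalar_path(self, toy_receptor,
                                              binder_fragment):
        frames = np.stack([binder_fragment.coords + [0, 0, z]
                           for z in (8.0, 10.0, 14.0)])
        batch = frame_energies(toy_receptor, binder_fragment, frames)
        single = [interaction_energy(toy_receptor, binder_fragment, f)
                  for f in frames]
        np.testing.assert_allclose(batch, single, atol=1e-9)


class TestDetectHbonds:
    def _donor_fragment(self, d, h):
        return simple_fragment([d, h], ["O", "H"], charges=[-0.4, 0.4],
                               bonds=[(0, 1)])

    def _acceptor_receptor(self, a):
        return simple_receptor([a], ["O"], charges=[-0.4], res_numbers=[1])

    def test_collinear_within_criteria_detected(self):
        frag = self._donor_fragment([0, 0, 0], [1, 0, 0])
        rec = self._acceptor_receptor([2.8, 0, 0])
        hits = detect_hbonds(rec, frag)
        assert [(h[0], h[2], h[3]) for h in hits] == [(0, 0, "frag->rec")]

    def test_distance_just_over_three_not_detected(self):
        frag = self._donor_fragment([0, 0, 0], [1, 0, 0])
        rec = self._acceptor_receptor([3.2, 0, 0])
        assert detect_hbonds(rec, frag) == []

    def test_angle_below_120_not_detected(self):
        # D-A close (2.6 A) but H off to the side: angle at H is ~100 deg
        d = np.array([0.0, 0.0, 0.0])
        a = np.array([2.6, 0.0, 0.0])
        h = np.array([1.3, -1.4, 0.0])
        ang = np.degrees(np.arccos(
            np.dot(d - h, a - h)
            / (np.linalg.norm(d - h) * np.linalg.norm(a - h))))
        assert ang < 120
        frag = self._donor_fragment(d, h)
        rec = self._acceptor_receptor(a)
        assert detect_hbonds(rec, frag) == []

    def test_receptor_donor_direction(self):
        rec = simple_receptor([[0, 0, 0], [1, 0, 0]], ["N", "H"],
                              charges=[-0.4, 0.4], res_numbers=[1, 1])
        frag = simple_fragment([[2.7, 0, 0]], ["O"], charges=[-0.4])
        hits = detect_hbonds(rec, frag)
        assert [(h[0], h[2], h[3]) for h in hits] == [(0, 0, "rec->frag")]

    def test_agrees_with_brute_force_oracle(self):
        """Vectorised detection equals an all-triples geometric check on
        random small geometries (exact set equality)."""
        rng = np.random.default_rng(42)
        criteria = HBondCriteria()
        for _ in range(200):
            n_frag = int(rng.integers(2, 5))
            frag_el = ["O", "H"] + [str(rng.choice(["C", "O", "N"]))
                                    for _ in range(n_frag - 2)]
            frag_xyz = rng.uniform(-3, 3, (n_frag, 3))
            frag_xyz[1] = frag_xyz[0] + rng.normal(0, 0.4, 3)
            frag_xyz[1] *= 1.0  # H stays near its O
            frag = simple_fragment(frag_xyz, frag_el,
                                   bonds=[(0, 1)] + [(0, i) for i in
                                                     range(2, n_frag)])
            n_rec = int(rng.integers(1, 5))
            rec_el = [str(rng.choice(["C", "O", "N"])) for _ in range(n_rec)]
            rec = simple_receptor(rng.uniform(-3, 3, (n_rec, 3)), rec_el,
                                  res_numbers=list(range(1, n_rec + 1)))

            got = {(h[0], h[2], h[3]) for h in
                   detect_hbonds(rec, frag, criteria=criteria)}

            expect = set()
            for dp in frag.donor_pairs():
                for ai in rec.acceptor_indices():
                    if _is_hbond(frag.coords[dp[0]], frag.coords[dp[1]],
                                 rec.coords[ai], criteria):
                        expect.add((int(dp[0]), int(ai), "frag->rec"))
            for dp in rec.donor_pairs():
                for ai in frag.acceptor_indices():
                    if _is_hbond(rec.coords[dp[0]], rec.coords[dp[1]],
                                 frag.coords[ai], criteria):
                        expect.add((int(dp[0]), int(ai), "rec->frag"))
            assert got == expect


def _is_hbond(d, h, a, criteria):
    if np.linalg.norm(d - a) >= criteria.max_da_distance:
        return False
    v1, v2 = d - h, a - h
    cos = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return np.degrees(np.arccos(np.clip(cos, -1, 1))) > criteria.min_dha_angle


class TestHbondOccupancy:
    def _setup(self):
        frag = simple_fragment([[0, 0, 0], [1, 0, 0]], ["O", "H"],
                               bonds=[(0, 1)])
        rec = simple_receptor([[2.8, 0, 0]], ["O"], res_numbers=[7])
        return rec, frag

    def test_partial_occupancy(self):
        rec, frag = self._setup()
        near = frag.coords
        far = frag.coords + np.array([4.0, 0, 0])
        frames = np.stack([near] * 7 + [far] * 3)
        records = hbond_occupancy(rec, frag, frames)
        assert len(records) == 1
        assert records[0].occupancy == pytest.approx(70.0)
        assert records[0].residue == "UNK7"

    def test_never_present_gives_no_record(self):
        rec, frag = self._setup()
        frames = np.stack([frag.coords + [5, 0, 0]] * 4)
        assert hbond_occupancy(rec, frag, frames) == []

    def test_always_present_is_hundred(self):
        rec, frag = self._setup()
        frames = np.stack([frag.coords] * 5)
        assert hbond_occupancy(rec, frag, frames)[0].occupancy == 100.0


class TestHydScore:
    def test_full_contact_below_r_on(self):
        rec, frag = _pair(0.0, 0.0, 4.0)
        assert hyd_score(rec, frag) == pytest.approx(1.0)

    def test_midpoint_of_switch(self):
        rec, frag = _pair(0.0, 0.0, 5.25)
        assert hyd_score(rec, frag) == pytest.approx(0.5)

    def test_polar_pair_scores_zero(self):
        rec, frag = _pair(0.0, 0.0, 4.0, rec_el="O")
        assert hyd_score(rec, frag) == 0.0

    def test_monotone_in_radial_distance(self, toy_receptor):
        frag = simple_fragment([[0.0, 0.0, 0.0]], ["C"])
        scores = [hyd_score(toy_receptor, frag, np.array([[0.0, 0.0, z]]))
                  for z in np.linspace(6.0, 25.0, 40)]
        diffs = np.diff(scores)
        assert np.all(diffs <= 1e-12)

    def test_frame_scores_match_scalar(self, toy_receptor, binder_fragment):
        frames = np.stack([binder_fragment.coords + [0, 0, z]
                           for z in (7.0, 9.0, 12.0)])
        batch = frame_hyd_scores(toy_receptor, binder_fragment, frames)
        single = [hyd_score(toy_receptor, binder_fragment, f) for f in frames]
        np.testing.assert_allclose(batch, single, atol=1e-12)

    def test_switch_window_validation(self):
        with pytest.raises(ValueError):
            HydParams(r_on=6.0, r_off=4.5)
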