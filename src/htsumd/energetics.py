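"""Per-frame scoring primitives.

Three quantities are computed for every fragment pose against the rigid
receptor:

* ``interaction_energy`` — a fast end-point estimate of the binding energy
  standing behind the scoring interface where a rescoring adapter (e.g. a real
  MM/GBSA implementation) could be plugged in.  It sums a screened Coulomb
  term with distance-dependent dielectric eps(r) = 4r,

      E_elec = 332.0637 * q_i q_j / (4 r^2)   [kcal/mol],

  a 12-6 Lennard-Jones term with Lorentz-Berthelot combination, and a
  nonpolar solvation reward -gamma * A_contact where the contact area is
  proxied by a switch function over apolar-apolar pairs.  All pair terms are
  truncated at the cutoff (default 9 A).  Lower is more favourable.

* ``detect_hbonds`` — geometric hydrogen bonds: donor-acceptor heavy-atom
  distance < 3.0 A and donor-H-acceptor angle (at the hydrogen) > 120 deg,
  both directions searched.  Boundary values are excluded (strict
  inequalities).

* ``hyd_score`` — dimensionless hydrophobic-contact score (higher is better):
  sum over apolar-apolar receptor/fragment pairs of a linear switch S(r)
  equal to 1 below r_on (4.5 A), falling linearly to 0 at r_off (6.0 A).

Frames with any receptor-fragment pair below 0.5 A are steric clashes: they
raise :class:`~htsumd.errors.ClashError` and are excluded from cluster
averages rather than scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _elements as elem
from .errors import ClashError
from .systems import AtomSet, Fragment, Receptor

COULOMB_K = 332.0637  # kcal * A / (mol * e^2)
CLASH_DISTANCE = 0.5  # A


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria (strict inequalities)."""

    max_da_distance: float = 3.0   # donor-acceptor heavy-atom distance, A
    min_dha_angle: float = 120.0   # donor-H-acceptor angle at the H, deg

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise ValueError("distance criterion must be positive")
        if not 0 < self.min_dha_angle <= 180:
            raise ValueError("angle criterion must be in (0, 180]")


@dataclass(frozen=True)
class HBondRecord:
    """A donor-acceptor contact aggregated over the frames of a cluster."""

    donor_atom: int
    acceptor_atom: int
    residue: str               # receptor residue label, e.g. "GLU92"
    occupancy: float           # % of cluster frames where the bond is present

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 100.0:
            raise ValueError("occupancy must be a percentage")


@dataclass(frozen=True)
class HydParams:
    """Linear switch window for the hydrophobic-contact score."""

    r_on: float = 4.5
    r_off: float = 6.0
    apolar_elements: frozenset = elem.APOLAR_ELEMENTS

    def __post_init__(self) -> None:
        if not 0 < self.r_on < self.r_off:
            raise ValueError("require 0 < r_on < r_off")


@dataclass(frozen=True)
class EnergyModel:
    """Parameters of the interaction-energy surrogate."""

    coulomb_k: float = COULOMB_K
    cutoff: float = 9.0
    gamma: float = 0.02           # kcal/mol/A^2, nonpolar solvation coefficient
    contact_area: float = 12.0    # A^2 assigned to one full apolar contact
    use_lj: bool = True
    use_coulomb: bool = True
    hyd: HydParams = field(default_factory=HydParams)


def _pair_tables(receptor: AtomSet, fragment: AtomSet):
    """Precomputed per-pair LJ/charge/apolar tables (receptor x fragment)."""
    sr = np.array([elem.lj_sigma(e) for e in receptor.elements])
    sf = np.array([elem.lj_sigma(e) for e in fragment.elements])
    er = np.array([elem.lj_epsilon(e) for e in receptor.elements])
    ef = np.array([elem.lj_epsilon(e) for e in fragment.elements])
    sigma = 0.5 * (sr[:, None] + sf[None, :])
    eps = np.sqrt(er[:, None] * ef[None, :])
    qq = receptor.charges[:, None] * fragment.charges[None, :]
    ap_r = np.array([p == "apolar" and e.upper() != "H"
                     for p, e in zip(receptor.polarity, receptor.elements)])
    ap_f = np.array([p == "apolar" and e.upper() != "H"
                     for p, e in zip(fragment.polarity, fragment.elements)])
    apolar = ap_r[:, None] & ap_f[None, :]
    return sigma, eps, qq, apolar


def _switch(r: np.ndarray, r_on: float, r_off: float) -> np.ndarray:
    s = np.clip((r_off - r) / (r_off - r_on), 0.0, 1.0)
    s[r <= r_on] = 1.0
    return s


def interaction_energy(receptor: Receptor, fragment: Fragment,
                       fragment_coords: np.ndarray | None = None,
                       model: EnergyModel | None = None) -> float:
    """Surrogate receptor-fragment interaction energy (kcal/mol; lower is
    more favourable).  Raises :class:`ClashError` below 0.5 A separation."""
    model = model or EnergyModel()
    coords = fragment.coords if fragment_coords is None else fragment_coords
    r = np.linalg.norm(
        receptor.coords[:, None, :] - coords[None, :, :], axis=2)
    if np.any(r < CLASH_DISTANCE):
        raise ClashError(f"atom pair below {CLASH_DISTANCE} A")
    sigma, eps, qq, apolar = _pair_tables(receptor, fragment)
    within = r < model.cutoff
    e = 0.0
    if model.use_coulomb:
        with np.errstate(divide="ignore"):
            e += float(np.sum(np.where(
                within, model.coulomb_k * qq / (4.0 * r * r), 0.0)))
    if model.use_lj:
        sr6 = np.where(within, (sigma / r) ** 6, 0.0)
        e += float(np.sum(4.0 * eps * (sr6 * sr6 - sr6)))
    # nonpolar solvation reward via the apolar contact-area proxy
    s = _switch(r, model.hyd.r_on, model.hyd.r_off)
    area = model.contact_area * float(np.sum(s[apolar & within]))
    e -= model.gamma * area
    return e


def frame_energies(receptor: Receptor, fragment: Fragment,
                   frames: np.ndarray,
                   model: EnergyModel | None = None) -> np.ndarray:
    """Vectorised per-frame energies; clash frames come back as NaN."""
    model = model or EnergyModel()
    frames = np.asarray(frames, dtype=float)
    sigma, eps, qq, apolar = _pair_tables(receptor, fragment)
    r = np.linalg.norm(
        receptor.coords[None, :, None, :] - frames[:, None, :, :], axis=3)
    clash = np.any(r.reshape(len(frames), -1) < CLASH_DISTANCE, axis=1)
    within = r < model.cutoff
    rr = np.where(r > 0, r, np.inf)
    e = np.zeros(len(frames))
    if model.use_coulomb:
        e += np.sum(np.where(within, model.coulomb_k * qq / (4 * rr * rr), 0.0),
                    axis=(1, 2))
    if model.use_lj:
        sr6 = np.where(within, (sigma / rr) ** 6, 0.0)
        e += np.sum(4.0 * eps * (sr6 * sr6 - sr6), axis=(1, 2))
    s = np.clip((model.hyd.r_off - r) / (model.hyd.r_off - model.hyd.r_on),
                0.0, 1.0)
    e -= model.gamma * model.contact_area * np.sum(
        np.where(apolar[None] & within, s, 0.0), axis=(1, 2))
    e[clash] = np.nan
    return e


def _hbond_one_direction(d_heavy: np.ndarray, d_h: np.ndarray,
                         a_coords: np.ndarray,
                         criteria: HBondCriteria) -> list[tuple[int, int]]:
    """Indices (donor_pair_idx, acceptor_idx) satisfying both criteria."""
    if not len(d_heavy) or not len(a_coords):
        return []
    da = np.linalg.norm(d_heavy[:, None, :] - a_coords[None, :, :], axis=2)
    hd = d_heavy - d_h                                    # H -> donor vectors
    ha = a_coords[None, :, :] - d_h[:, None, :]           # H -> acceptor
    cosang = np.sum(hd[:, None, :] * ha, axis=2) / (
        np.linalg.norm(hd, axis=1)[:, None] * np.linalg.norm(ha, axis=2)
        + 1e-300)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ok = (da < criteria.max_da_distance) & (ang > criteria.min_dha_angle)
    return [(int(i), int(j)) for i, j in zip(*np.nonzero(ok))]


def detect_hbonds(receptor: Receptor, fragment: Fragment,
                  fragment_coords: np.ndarray | None = None,
                  criteria: HBondCriteria | None = None
                  ) -> list[tuple[int, int, int, str]]:
    """All hydrogen bonds for one pose, both directions.

    Returns tuples ``(donor_atom, h_atom, acceptor_atom, direction)`` with
    ``direction`` either ``"frag->rec"`` (fragment donates) or ``"rec->frag"``.
    Atom indices refer to the donating / accepting molecule respectively.
    """
    criteria = criteria or HBondCriteria()
    coords = fragment.coords if fragment_coords is None else np.asarray(
        fragment_coords, dtype=float)
    out: list[tuple[int, int, int, str]] = []

    fd = fragment.donor_pairs()
    ra = receptor.acceptor_indices()
    if len(fd) and len(ra):
        hits = _hbond_one_direction(coords[fd[:, 0]], coords[fd[:, 1]],
                                    receptor.coords[ra], criteria)
        out += [(int(fd[i, 0]), int(fd[i, 1]), int(ra[j]), "frag->rec")
                for i, j in hits]

    rd = receptor.donor_pairs()
    fa = fragment.acceptor_indices()
    if len(rd) and len(fa):
        hits = _hbond_one_direction(receptor.coords[rd[:, 0]],
                                    receptor.coords[rd[:, 1]],
                                    coords[fa], criteria)
        out += [(int(rd[i, 0]), int(rd[i, 1]), int(fa[j]), "rec->frag")
                for i, j in hits]
    return out


def _residue_label(receptor: Receptor, atom: int) -> str:
    return f"{receptor.res_names[atom]}{int(receptor.res_numbers[atom])}"


def hbond_occupancy(receptor: Receptor, fragment: Fragment,
                    frames: np.ndarray,
                    criteria: HBondCriteria | None = None
                    ) -> list[HBondRecord]:
    """Aggregate per-frame hydrogen bonds over a set of frames.

    One record per distinct (donor atom, acceptor atom) pair ever observed;
    occupancy is the percentage of frames in which the pair satisfies the
    criteria.  The residue label names the receptor residue involved.
    """
    frames = np.asarray(frames, dtype=float)
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    counts: dict[tuple[int, int, str], int] = {}
    labels: dict[tuple[int, int, str], str] = {}
    for f in frames:
        seen = set()
        for donor, _h, acceptor, direction in detect_hbonds(
                receptor, fragment, f, criteria):
            key = (donor, acceptor, direction)
            if key in seen:
                continue
            seen.add(key)
            counts[key] = counts.get(key, 0) + 1
            rec_atom = acceptor if direction == "frag->rec" else donor
            labels[key] = _residue_label(receptor, rec_atom)
    return [HBondRecord(donor_atom=k[0], acceptor_atom=k[1],
                        residue=labels[k],
                        occupancy=100.0 * c / len(frames))
            for k, c in sorted(counts.items())]


def hyd_score(receptor: Receptor, fragment: Fragment,
              fragment_coords: np.ndarray | None = None,
              params: HydParams | None = None) -> float:
    """Hydrophobic-contact score for one pose (dimensionless, higher better)."""
    params = params or HydParams()
    coords = fragment.coords if fragment_coords is None else fragment_coords
    r = np.linalg.norm(
        receptor.coords[:, None, :] - np.asarray(coords)[None, :, :], axis=2)
    _, _, _, apolar = _pair_tables(receptor, fragment)
    return float(np.sum(_switch(r, params.r_on, params.r_off)[apolar]))


def frame_hyd_scores(receptor: Receptor, fragment: Fragment,
                     frames: np.ndarray,
                     params: HydParams | None = None) -> np.ndarray:
    """Vectorised hydrophobic score per frame."""
    params = params or HydParams()
    frames = np.asarray(frames, dtype=float)
    _, _, _, apolar = _pair_tables(receptor, fragment)
    r = np.linalg.norm(
        receptor.coords[None, :, None, :] - frames[:, None, :, :], axis=3)
    s = np.clip((params.r_off - r) / (params.r_off - params.r_on), 0.0, 1.0)
    return np.sum(np.where(apolar[None], s, 0.0), axis=(1, 2))
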