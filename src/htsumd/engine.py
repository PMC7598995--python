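"""The supervised-MD loop.

Supervised MD accelerates binding-pathway sampling without energetic bias:
short dynamics segments ("steps") are run, the fragment-site mass-center
distance d_cm is monitored at a few checkpoints inside each step, and a
tabu-like rule keeps only the steps in which the ligand approaches the site
(negative least-squares slope of d_cm over the checkpoints).  Rejected steps
are re-simulated from the previous coordinates with a fresh, deterministically
derived noise stream.  Once d_cm falls below the supervision-off distance the
supervision is switched off and plain dynamics continues to the step budget.

The built-in :class:`ToyBrownianBackend` propagates the fragment's atoms by
overdamped (Brownian) dynamics on the gradient of the interaction-energy
surrogate plus harmonic bonds, with seeded Gaussian noise; the receptor is
rigid.  One nominal "300 ps" step maps to ``checkpoints x substeps`` toy
integrator substeps.  Any backend honouring ``segment(coords, substeps, seed)
-> coords`` (bit-reproducible in the seed) can be substituted, e.g. an adapter
around a real MD engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
from numba import njit

from .energetics import EnergyModel, frame_energies
from .errors import BackendError
from .systems import Fragment, Receptor, SimSystem, SiteDefinition

OUTCOME_BOUND = "bound"
OUTCOME_UNBOUND = "unbound"
OUTCOME_BUDGET = "budget-exhausted"


@dataclass(frozen=True)
class SuMDConfig:
    """Knobs of the supervised loop.

    ``step_ps`` is nominal bookkeeping (the short-step duration of the
    protocol); for the toy backend one step is ``checkpoints * substeps``
    integrator substeps.
    """

    step_ps: float = 300.0
    checkpoints: int = 5
    substeps: int = 12
    slope_threshold: float = 0.0
    max_consecutive_rejections: int = 20
    supervision_off_distance: float = 5.0   # A
    max_accepted_steps: int = 200
    replicas: int = 3
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.checkpoints < 2:
            raise ValueError("need at least 2 checkpoints per step")
        if self.max_accepted_steps <= 0 or self.max_consecutive_rejections <= 0:
            raise ValueError("budgets must be positive")


@dataclass
class SupervisionState:
    """Mutable loop state (exposed mainly for inspection and tests)."""

    coords: np.ndarray
    d_history: list = field(default_factory=list)
    accepted_steps: int = 0
    attempted_steps: int = 0
    consecutive_rejections: int = 0
    supervision_active: bool = True


@dataclass
class Trajectory:
    """Ordered accepted frames of one replica with per-frame observables."""

    frames: np.ndarray            # (F, n_atoms, 3)
    d_cm: np.ndarray              # (F,)
    energies: np.ndarray          # (F,), NaN for clash-flagged frames
    supervised_steps: np.ndarray  # (accepted_steps,) bool
    checkpoints: int
    outcome: str
    replica_id: int = 0
    seed: int = 0
    fragment_id: str = "frag"
    attempted_steps: int = 0

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.d_cm):
            raise ValueError("d_cm length must match frame count")
        if len(self.frames) != self.accepted_steps * self.checkpoints:
            raise ValueError("frame count must be accepted_steps * checkpoints")

    @property
    def accepted_steps(self) -> int:
        return len(self.supervised_steps)

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.frames).tobytes())
        h.update(np.ascontiguousarray(self.d_cm).tobytes())
        h.update(self.outcome.encode())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# observables and the acceptance rule
# ---------------------------------------------------------------------------

def d_cm(fragment_coords: np.ndarray, masses: np.ndarray,
         site: SiteDefinition | np.ndarray) -> float:
    """Distance between the fragment's mass-weighted centroid and the site
    center (the supervised observable)."""
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    center = site.center if isinstance(site, SiteDefinition) else np.asarray(site)
    com = (masses[:, None] * np.asarray(fragment_coords)).sum(0) / masses.sum()
    return float(np.linalg.norm(com - center))


def supervise(d_cm_checkpoints, slope_threshold: float = 0.0) -> bool:
    """Tabu-like acceptance: keep the step iff the least-squares slope of
    d_cm versus checkpoint index is below the threshold (default 0)."""
    d = np.asarray(d_cm_checkpoints, dtype=float)
    if len(d) < 2:
        raise ValueError("need at least 2 checkpoint distances")
    x = np.arange(len(d), dtype=float)
    slope = np.polyfit(x, d, 1)[0]
    return bool(slope < slope_threshold)


def derive_seed(*parts: int) -> int:
    """Deterministic seed derivation for (base, fragment, replica, step,
    attempt, checkpoint) tuples; always below 2**31."""
    state = np.random.SeedSequence(list(parts)).generate_state(1)[0]
    return int(state) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# toy Brownian backend (numba kernel)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _integrate(coords, rec_xyz, qq4, sigma, eps, apolar, bonds, bond_r0,
               kbond, nsub, drift, noise_sigma, cutoff, g_contact,
               r_on, r_off, max_disp, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    n = coords.shape[0]
    m = rec_xyz.shape[0]
    nb = bonds.shape[0]
    cut2 = cutoff * cutoff
    sw = 1.0 / (r_off - r_on)
    out = coords.copy()
    force = np.zeros((n, 3))
    for _ in range(nsub):
        for i in range(n):
            force[i, 0] = 0.0
            force[i, 1] = 0.0
            force[i, 2] = 0.0
        # receptor-fragment nonbonded forces
        for i in range(n):
            xi = out[i, 0]
            yi = out[i, 1]
            zi = out[i, 2]
            for j in range(m):
                dx = xi - rec_xyz[j, 0]
                dy = yi - rec_xyz[j, 1]
                dz = zi - rec_xyz[j, 2]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 > cut2 or r2 < 1e-12:
                    continue
                r = np.sqrt(r2)
                # screened Coulomb E = A / r^2 -> F = 2A/r^4 * d
                c = 2.0 * qq4[i, j] / (r2 * r2)
                # 12-6 LJ
                sr2 = (sigma[i, j] * sigma[i, j]) / r2
                sr6 = sr2 * sr2 * sr2
                c += 4.0 * eps[i, j] * (12.0 * sr6 * sr6 - 6.0 * sr6) / r2
                # hydrophobic switch (attractive inside the window)
                if apolar[i, j] and r_on < r < r_off:
                    c -= g_contact * sw / r
                force[i, 0] += c * dx
                force[i, 1] += c * dy
                force[i, 2] += c * dz
        # harmonic bonds
        for k in range(nb):
            a = bonds[k, 0]
            b = bonds[k, 1]
            dx = out[a, 0] - out[b, 0]
            dy = out[a, 1] - out[b, 1]
            dz = out[a, 2] - out[b, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < 1e-9:
                continue
            f = -kbond * (r - bond_r0[k]) / r
            force[a, 0] += f * dx
            force[a, 1] += f * dy
            force[a, 2] += f * dz
            force[b, 0] -= f * dx
            force[b, 1] -= f * dy
            force[b, 2] -= f * dz
        # Euler-Maruyama update with per-atom displacement clamp
        for i in range(n):
            ux = drift * force[i, 0] + noise_sigma * np.random.normal(0.0, 1.0)
            uy = drift * force[i, 1] + noise_sigma * np.random.normal(0.0, 1.0)
            uz = drift * force[i, 2] + noise_sigma * np.random.normal(0.0, 1.0)
            nrm = np.sqrt(ux * ux + uy * uy + uz * uz)
            if nrm > max_disp:
                s = max_disp / nrm
                ux *= s
                uy *= s
                uz *= s
            out[i, 0] += ux
            out[i, 1] += uy
            out[i, 2] += uz
    return out


class Backend(Protocol):
    """Dynamics backend contract: bit-reproducible given (coords, seed)."""

    def segment(self, coords: np.ndarray, substeps: int,
                seed: int) -> np.ndarray: ...


@dataclass
class ToyBrownianBackend:
    """Overdamped Langevin dynamics of the fragment on the surrogate energy.

    ``drift`` is the mobility-times-timestep prefactor (A^2 mol/kcal per
    substep) and ``noise_sigma`` the per-atom per-component Gaussian step
    (A per substep); their ratio sets an effective temperature
    kT = noise_sigma^2 / (2 * drift).  ``max_disp`` caps the per-substep
    atomic displacement for numerical robustness on the steep LJ wall.
    """

    receptor: Receptor
    fragment: Fragment
    model: EnergyModel = field(default_factory=EnergyModel)
    drift: float = 0.06
    noise_sigma: float = 0.45
    bond_k: float = 10.0
    max_disp: float = 0.5

    def __post_init__(self) -> None:
        from .energetics import _pair_tables

        sigma, eps, qq, apolar = _pair_tables(self.receptor, self.fragment)
        # kernel tables are indexed (fragment atom, receptor atom)
        self._sigma = np.ascontiguousarray(sigma.T)
        self._eps = np.ascontiguousarray(eps.T)
        self._qq4 = np.ascontiguousarray(
            (self.model.coulomb_k * qq / 4.0).T)
        self._apolar = np.ascontiguousarray(apolar.T)
        self._rec_xyz = np.ascontiguousarray(self.receptor.coords)
        self._bonds = np.ascontiguousarray(self.fragment.bonds)
        ref = self.fragment.coords
        self._bond_r0 = np.array(
            [np.linalg.norm(ref[a] - ref[b]) for a, b in self._bonds])
        self._g_contact = self.model.gamma * self.model.contact_area

    def segment(self, coords: np.ndarray, substeps: int,
                seed: int) -> np.ndarray:
        out = _integrate(
            np.ascontiguousarray(coords, dtype=np.float64), self._rec_xyz,
            self._qq4, self._sigma, self._eps, self._apolar, self._bonds,
            self._bond_r0, self.bond_k, substeps, self.drift,
            self.noise_sigma, self.model.cutoff, self._g_contact,
            self.model.hyd.r_on, self.model.hyd.r_off, self.max_disp,
            np.uint32(seed))
        if not np.all(np.isfinite(out)):
            raise BackendError("backend produced non-finite coordinates")
        return out


def dynamics_step(coords: np.ndarray, seed: int, backend: Backend,
                  checkpoints: int = 5, substeps: int = 12) -> np.ndarray:
    """Run one SuMD step, returning ``checkpoints`` evenly spaced frames."""
    frames = np.empty((checkpoints,) + np.shape(coords))
    cur = np.asarray(coords, dtype=float)
    for c in range(checkpoints):
        cur = backend.segment(cur, substeps, derive_seed(seed, c))
        if not np.all(np.isfinite(cur)):
            raise BackendError("backend produced non-finite coordinates")
        frames[c] = cur
    return frames


# ---------------------------------------------------------------------------
# the supervised loop
# ---------------------------------------------------------------------------

def run_sumd(system: SimSystem, site: SiteDefinition | None = None,
             config: SuMDConfig | None = None,
             backend: Backend | None = None, replica_id: int = 0,
             model: EnergyModel | None = None,
             score_energies: bool = True) -> Trajectory:
    """Run one supervised replica to completion.

    Deterministic: every noise stream derives from ``(config.base_seed,
    system.seed, replica_id, step, attempt)``.
    """
    config = config or SuMDConfig()
    site = site or system.site
    model = model or EnergyModel()
    if backend is None:
        backend = ToyBrownianBackend(system.receptor, system.fragment,
                                     model=model)
    masses = system.fragment.masses
    state = SupervisionState(coords=np.array(system.start_coords, dtype=float))
    frames: list[np.ndarray] = []
    dists: list[float] = []
    supervised_flags: list[bool] = []
    reached = False
    unbound = False

    step = 0
    while state.accepted_steps < config.max_accepted_steps and not unbound:
        attempt = 0
        accepted = False
        while not accepted and not unbound:
            step_seed = derive_seed(config.base_seed, system.seed, replica_id,
                                    step, attempt)
            cand = dynamics_step(state.coords, step_seed, backend,
                                 config.checkpoints, config.substeps)
            cand_d = [d_cm(f, masses, site) for f in cand]
            state.attempted_steps += 1
            if not state.supervision_active or supervise(
                    cand_d, config.slope_threshold):
                accepted = True
            else:
                # rejected: restore previous coordinates (cand is discarded)
                # and re-draw the noise stream deterministically
                state.consecutive_rejections += 1
                attempt += 1
                if (state.consecutive_rejections
                        >= config.max_consecutive_rejections):
                    unbound = True
        if not accepted:
            break
        supervised_flags.append(state.supervision_active)
        state.consecutive_rejections = 0
        state.accepted_steps += 1
        state.coords = cand[-1]
        frames.extend(cand)
        dists.extend(cand_d)
        state.d_history.append(cand_d)
        if cand_d[-1] <= config.supervision_off_distance:
            reached = True
            state.supervision_active = False
        step += 1

    if unbound:
        outcome = OUTCOME_UNBOUND
    elif reached:
        outcome = OUTCOME_BOUND
    else:
        outcome = OUTCOME_BUDGET

    frame_arr = (np.array(frames) if frames
                 else np.empty((0, system.fragment.n_atoms, 3)))
    if score_energies and len(frame_arr):
        energies = frame_energies(system.receptor, system.fragment,
                                  frame_arr, model)
    else:
        energies = np.full(len(frame_arr), np.nan)
    return Trajectory(frames=frame_arr, d_cm=np.array(dists),
                      energies=energies,
                      supervised_steps=np.array(supervised_flags, dtype=bool),
                      checkpoints=config.checkpoints, outcome=outcome,
                      replica_id=replica_id, seed=system.seed,
                      fragment_id=system.fragment.fragment_id,
                      attempted_steps=state.attempted_steps)


@dataclass(frozen=True)
class RunManifestEntry:
    fragment_id: str
    fragment_index: int
    replica: int
    seed: int


def schedule_replicas(library, config: SuMDConfig | None = None
                      ) -> list[RunManifestEntry]:
    """One run entry per (fragment, replica), with a derived seed; the
    manifest is trivially partitionable across workers."""
    config = config or SuMDConfig()
    if not len(library):
        raise ValueError("empty fragment library")
    manifest = []
    for fi, frag in enumerate(library):
        fid = getattr(frag, "fragment_id", str(frag))
        for rep in range(config.replicas):
            manifest.append(RunManifestEntry(
                fragment_id=fid, fragment_index=fi, replica=rep,
                seed=derive_seed(config.base_seed, fi, rep)))
    return manifest
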