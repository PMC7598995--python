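"""Seeded generators for everything the tests and examples need.

The toy receptor is a hollow bead shell with a single open channel (the
"cleft") leading to a floor that carries four sub-pockets, each a polar
anchor bead ringed by apolar lining beads — an abstract analogue of a
protein-protein-interaction groove with contiguous hydrophobic pockets.  It
is *not* a protein model: beads are single atoms, the shell is rigid, and
the cleft is axially symmetric.  What it provides is exactly what the
pipeline consumes: a mass-weighted site center reachable through a
collision-free path, short-range surrogate-energy attraction inside the
cleft (the funnel), and hydrogen-bond partners at the pockets.

The planted library mixes designed binders (a hydroxyl-like donor tip with
strong complementary charges plus an apolar body sized to the pocket) with
three decoy families: weakly polar fragments (same donor geometry, half the
charge, less apolar bulk — they bind shallowly and populate the cluster
universe without topping the ranks), fully apolar fragments (no hydrogen
bond possible, removed by the occupancy gate) and polarity-mismatched
acceptor-only fragments (nothing to donate to an all-acceptor cleft).
Ground-truth labels are fixed at design time, before any pipeline stage
runs.

Titrations are forward-simulated from the exact single-site quadratic model
with Gaussian shift noise; the generating Kd and saturated shifts are
returned beside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .nmr import Titration, bound_fraction
from .systems import (Fragment, Receptor, SiteDefinition, define_binding_site,
                      make_atom_set)


# ---------------------------------------------------------------------------
# toy receptor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyReceptorSpec:
    n_shell: int = 150
    shell_radius: float = 10.0          # A
    cone_half_angle_deg: float = 60.0   # opening angle of the cleft funnel
    floor_z: float = 3.5                # cleft depth = shell_radius - floor_z
    floor_radius: float = 6.0
    n_pockets: int = 6
    pocket_roles: tuple = ("acceptor",) * 6
    pocket_ring_radius: float = 3.6
    anchor_charge: float = -0.8
    surface_site_charge: float = -0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.floor_z >= self.shell_radius:
            raise ValidationError("cleft floor must sit inside the shell")
        if len(self.pocket_roles) != self.n_pockets:
            raise ValidationError("one role per pocket required")
        if self.n_pockets < 1:
            raise ValidationError("need at least one pocket")
        if not 10.0 <= self.cone_half_angle_deg <= 80.0:
            raise ValidationError("cone half-angle must be in [10, 80] deg")


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * math.pi * i / phi
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def make_toy_receptor(spec: ToyReceptorSpec | None = None
                      ) -> tuple[Receptor, SiteDefinition]:
    """Deterministic pocketed toy receptor plus its binding-site definition
    (mass-weighted centroid of the pocket-anchor residues)."""
    spec = spec or ToyReceptorSpec()
    elements: list[str] = []
    coords: list[list[float]] = []
    charges: list[float] = []
    res_numbers: list[int] = []
    res_names: list[str] = []

    def add(element, xyz, charge, name):
        elements.append(element)
        coords.append(list(xyz))
        charges.append(charge)
        res_numbers.append(len(res_numbers) + 1)
        res_names.append(name)
        return res_numbers[-1]

    # hollow shell with a conical opening around +z (the cleft mouth)
    half = math.radians(spec.cone_half_angle_deg)
    for p in _fibonacci_sphere(spec.n_shell) * spec.shell_radius:
        theta = math.acos(p[2] / spec.shell_radius)
        if theta < half:
            continue
        add("C", p, 0.0, "SHL")

    # funnel wall: rings narrowing from the shell rim down to the floor edge,
    # so the fragment-site distance decreases monotonically on the descent
    rim_r = spec.shell_radius * math.sin(half)
    rim_z = spec.shell_radius * math.cos(half)
    floor_edge_r = spec.floor_radius + 0.8
    floor_edge_z = spec.floor_z + 1.0
    for t in (0.25, 0.5, 0.75):
        r = rim_r + t * (floor_edge_r - rim_r)
        z = rim_z + t * (floor_edge_z - rim_z)
        k = 10
        for j in range(k):
            a = 2.0 * math.pi * (j + 3.0 * t) / k
            add("C", (r * math.cos(a), r * math.sin(a), z), 0.0, "WAL")

    # cleft floor: apolar lining ring + center bead
    for j in range(8):
        a = 2.0 * math.pi * j / 8
        add("C", (spec.floor_radius * math.cos(a),
                  spec.floor_radius * math.sin(a), spec.floor_z),
            0.0, "FLR")
    add("C", (0.0, 0.0, spec.floor_z), 0.0, "FLR")

    # weak polar "surface sites" on the floor periphery, interleaved between
    # the sub-pockets: donor-bearing fragments pause there while roaming the
    # cleft, producing the background of metastable pathway clusters a real
    # recognition trajectory shows
    for j in range(spec.n_pockets):
        a = 2.0 * math.pi * j / spec.n_pockets
        add("O", (6.3 * math.cos(a), 6.3 * math.sin(a), spec.floor_z + 0.4),
            spec.surface_site_charge, "SRF")

    # sub-pocket anchors P1..Pn with their own apolar lining.  Pockets are
    # deliberately heterogeneous — anchor strength and lining richness both
    # decay from P1 to Pn — so cluster descriptors (energy, hydrophobic
    # contacts, residence time) vary together with genuine pocket quality
    # instead of independently, the way real sub-pockets differ
    pocket_residues = []
    h_extras = []
    n_p = spec.n_pockets
    for k in range(n_p):
        a = 2.0 * math.pi * (k + 0.5) / n_p
        x = spec.pocket_ring_radius * math.cos(a)
        y = spec.pocket_ring_radius * math.sin(a)
        role = spec.pocket_roles[k]
        elem = "O" if role == "acceptor" else "N"
        quality = 1.0 - k / max(n_p - 1, 1)          # 1 (best) .. 0 (worst)
        charge = spec.anchor_charge * (0.65 + 0.35 * quality)
        rid = add(elem, (x, y, spec.floor_z), charge, f"PK{k + 1}")
        pocket_residues.append(rid)
        if role == "donor":
            h_extras.append(((x, y, spec.floor_z + 1.0), rid))
        # apolar groove rails running radially outward from the anchor: the
        # binder's apolar tail settles between them, pinning its azimuth so
        # bound poses collapse into one tight cluster; richer pockets carry
        # more rail beads
        n_rails = 1 + int(round(2 * quality))        # 3 (best) .. 1 (worst)
        for rr in (4.6, 5.4, 6.2)[:n_rails] if n_rails < 3 else (4.6, 5.4,
                                                                 6.2):
            for da in (-0.28, 0.28):
                add("C", (rr * math.cos(a + da), rr * math.sin(a + da),
                          spec.floor_z + 0.1), 0.0, f"PK{k + 1}L")
    for xyz, rid in h_extras:
        elements.append("H")
        coords.append(list(xyz))
        charges.append(0.4)
        res_numbers.append(rid)
        res_names.append(res_names[rid - 1])

    receptor = make_atom_set(elements, np.array(coords), charges=charges,
                             res_numbers=res_numbers, res_names=res_names,
                             cls=Receptor)
    site = define_binding_site(receptor, pocket_residues, radius=10.0)
    return receptor, site


# ---------------------------------------------------------------------------
# planted fragment library
# ---------------------------------------------------------------------------

BINDER = "binder"
NON_BINDER = "non-binder"


@dataclass
class PlantedLibrary:
    fragments: list[Fragment]
    truth: dict[str, str]          # fragment id -> binder / non-binder
    seed: int
    design: dict[str, str] = field(default_factory=dict)

    @property
    def binder_ids(self) -> list[str]:
        return sorted(f for f, lab in self.truth.items() if lab == BINDER)


def _chain(rng, specs, fragment_id):
    """Build a jittered chain fragment from (element, charge) bead specs."""
    elements = [s[0] for s in specs]
    charges = [s[1] for s in specs]
    coords = np.zeros((len(specs), 3))
    x = 0.0
    for i in range(1, len(specs)):
        length = 1.0 if elements[i] == "H" or elements[i - 1] == "H" else 1.5
        x += length
        coords[i] = (x, 0.35 * ((-1) ** i), 0.0)
    coords += rng.normal(0.0, 0.03, coords.shape)
    bonds = [(i - 1, i) for i in range(1, len(specs))]
    # 1-3 restraint bonds keep the heavy-atom chain from folding (angle-term
    # proxy); hydrogens stay orientable so donors can point at acceptors
    bonds += [(i - 2, i) for i in range(2, len(specs))
              if elements[i] != "H" and elements[i - 2] != "H"]
    bonds = np.array(bonds, dtype=int)
    return make_atom_set(elements, coords, charges=charges, bonds=bonds,
                         cls=Fragment, fragment_id=fragment_id)


def _binder(rng, fid):
    # apolar body sized to the pocket lining plus a strongly polar donor tip
    return _chain(rng, [("C", 0.0), ("C", 0.0), ("C", 0.0),
                        ("O", -0.35), ("H", 0.45)], fid), "binder"


def _weak_polar(rng, fid):
    # same donor geometry, half the charge, less apolar bulk: binds shallowly
    return _chain(rng, [("C", 0.0), ("O", -0.20), ("H", 0.35)], fid), "weak"


def _apolar(rng, fid):
    n = 3 + int(rng.integers(0, 2))
    return _chain(rng, [("C", 0.0)] * n, fid), "apolar"


def _mismatch(rng, fid):
    # acceptor-only: nothing to donate to an all-acceptor cleft
    return _chain(rng, [("C", 0.0), ("C", 0.0), ("O", -0.30)], fid), "mismatch"


def make_planted_library(n: int = 40, binder_fraction: float = 0.125,
                         seed: int = 0) -> PlantedLibrary:
    """A screen-sized library with designed binders planted among decoys.

    Decoy composition (weak-polar : apolar : mismatched = 10 : 1 : 1) keeps
    the post-gate cluster universe populated the way a real fragment screen's
    is — many weak but genuine contacts below the eventual hits.
    """
    if not 0 < binder_fraction < 1:
        raise ValidationError("binder fraction must lie in (0, 1)")
    n_binders = int(round(n * binder_fraction))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    fragments: list[Fragment] = []
    truth: dict[str, str] = {}
    design: dict[str, str] = {}
    decoy_cycle = ([_weak_polar] * 10 + [_apolar, _mismatch])
    for i in range(n):
        fid = f"F{i + 1:03d}"
        if i < n_binders:
            frag, kind = _binder(rng, fid)
            truth[fid] = BINDER
        else:
            maker = decoy_cycle[(i - n_binders) % len(decoy_cycle)]
            frag, kind = maker(rng, fid)
            truth[fid] = NON_BINDER
        fragments.append(frag)
        design[fid] = kind
    return PlantedLibrary(fragments=fragments, truth=truth, seed=seed,
                          design=design)


# ---------------------------------------------------------------------------
# synthetic titrations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NmrSynthSpec:
    kd: float = 1500.0                     # uM, the generating constant
    protein_conc: float = 90.0             # uM
    ligand_conc: tuple = (0.0, 100.0, 300.0, 700.0, 1300.0, 2300.0,
                          3700.0, 5100.0)  # uM, the titration design
    delta_apo: tuple = (8.20, 8.52, 7.93)  # ppm per monitored peak
    delta_sat_shift: tuple = (0.25, -0.18, 0.30)  # ppm, full-saturation change
    noise_sd: float = 0.005                # ppm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValidationError("Kd must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise sd must be non-negative")


def synth_titration(spec: NmrSynthSpec | None = None
                    ) -> tuple[Titration, dict]:
    """Forward-model a titration; returns the data plus the ground truth."""
    spec = spec or NmrSynthSpec()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x71A]))
    conc = np.asarray(spec.ligand_conc, dtype=float)
    fb = bound_fraction(conc, spec.protein_conc, spec.kd)
    shifts = {}
    truth_sat = {}
    for i, (apo, dsat) in enumerate(zip(spec.delta_apo,
                                        spec.delta_sat_shift)):
        peak = f"peak{i + 1}"
        clean = apo + dsat * fb
        noise = rng.normal(0.0, spec.noise_sd, len(conc)) if spec.noise_sd \
            else np.zeros(len(conc))
        shifts[peak] = clean + noise
        truth_sat[peak] = apo + dsat
    titration = Titration(ligand_conc=conc, shifts=shifts,
                          protein_conc=spec.protein_conc)
    truth = {"kd": spec.kd, "delta_sat": truth_sat, "seed": spec.seed}
    return titration, truth
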