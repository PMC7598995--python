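"""Domain types and system-preparation rules.

A *system* here is what one supervised-MD replica runs on: a rigid receptor, a
single small fragment placed far from the binding site, a cubic box sized by a
padding rule, and the Na+/Cl- counterion counts that neutralise the net charge
and realise the requested salt concentration.

Atom typing is rule-based (element + connectivity):

===========  =======================================  =====================
property     rule                                     values
===========  =======================================  =====================
polarity     C, S -> apolar; N, O -> polar;           apolar / polar /
             nonzero formal charge -> charged         charged
H-bond role  N/O with >=1 attached H -> donor;        donor / acceptor /
             N/O without H -> acceptor; else none     none
===========  =======================================  =====================

Hydrogens are kept as explicit atoms; ``h_parent`` maps each H to its heavy
atom (from bonds when available, otherwise by a 1.3 A distance rule).
Coordinates are Angstrom throughout; residue numbering is 1-based as in PDB.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
import warnings

import numpy as np

from . import _elements as elem
from .errors import (
    EmptyStructureError,
    LookupResidueError,
    PlacementError,
    ValidationError,
)

AVOGADRO = 6.02214076e23

POLARITY_APOLAR = "apolar"
POLARITY_POLAR = "polar"
POLARITY_CHARGED = "charged"
ROLE_DONOR = "donor"
ROLE_ACCEPTOR = "acceptor"
ROLE_NONE = "none"


# ---------------------------------------------------------------------------
# atom typing rules
# ---------------------------------------------------------------------------

def infer_h_parents(elements: np.ndarray, coords: np.ndarray,
                    bonds: np.ndarray | None = None,
                    max_bond_length: float = 1.3) -> np.ndarray:
    """Map every hydrogen to its parent heavy atom index (-1 for heavy atoms).

    Uses the bond list when given, otherwise the nearest heavy atom within
    ``max_bond_length`` Angstrom.
    """
    n = len(elements)
    parents = np.full(n, -1, dtype=np.int64)
    is_h = np.array([e.upper() == "H" for e in elements])
    if bonds is not None and len(bonds):
        for a, b in np.asarray(bonds, dtype=np.int64):
            if is_h[a] and not is_h[b]:
                parents[a] = b
            elif is_h[b] and not is_h[a]:
                parents[b] = a
        return parents
    heavy = np.flatnonzero(~is_h)
    if not len(heavy):
        return parents
    for i in np.flatnonzero(is_h):
        d = np.linalg.norm(coords[heavy] - coords[i], axis=1)
        j = int(np.argmin(d))
        if d[j] <= max_bond_length:
            parents[i] = heavy[j]
    return parents


def assign_typing(elements: np.ndarray, formal_charges: np.ndarray,
                  h_parent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Polarity class and H-bond role per atom from the rule table above."""
    n = len(elements)
    polarity = np.array([POLARITY_APOLAR] * n, dtype=object)
    role = np.array([ROLE_NONE] * n, dtype=object)
    has_h = np.zeros(n, dtype=bool)
    has_h[h_parent[h_parent >= 0]] = True
    for i, e in enumerate(elements):
        eu = e.upper()
        if formal_charges[i] != 0:
            polarity[i] = POLARITY_CHARGED
        elif eu in elem.POLAR_ELEMENTS:
            polarity[i] = POLARITY_POLAR
        elif eu in elem.APOLAR_ELEMENTS or eu == "H":
            polarity[i] = POLARITY_APOLAR
        else:
            polarity[i] = POLARITY_POLAR
        if eu in elem.POLAR_ELEMENTS:
            role[i] = ROLE_DONOR if has_h[i] else ROLE_ACCEPTOR
    return polarity, role


def default_partial_charges(elements: np.ndarray,
                            h_parent: np.ndarray) -> np.ndarray:
    """Per-element fallback charges; polar hydrogens get the polar-H value."""
    q = np.zeros(len(elements))
    for i, e in enumerate(elements):
        eu = e.upper()
        if eu == "H":
            p = h_parent[i]
            polar = p >= 0 and elements[p].upper() in elem.POLAR_ELEMENTS
            q[i] = elem.POLAR_H_CHARGE if polar else elem.APOLAR_H_CHARGE
        else:
            q[i] = elem.PARTIAL_CHARGE.get(eu, 0.0)
    return q


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class AtomSet:
    """Shared atom schema for receptors and fragments (struct-of-arrays)."""

    elements: np.ndarray          # (n,) str
    coords: np.ndarray            # (n, 3) float, Angstrom
    res_numbers: np.ndarray       # (n,) int, 1-based
    res_names: np.ndarray         # (n,) str
    charges: np.ndarray           # (n,) float, partial charges in e
    formal_charges: np.ndarray    # (n,) int
    polarity: np.ndarray          # (n,) str
    hbond_role: np.ndarray        # (n,) str
    h_parent: np.ndarray          # (n,) int, heavy-atom index for each H

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite coordinates")
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError("coords must be (n, 3)")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def masses(self) -> np.ndarray:
        return np.array([elem.mass_of(e) for e in self.elements])

    @property
    def is_hydrogen(self) -> np.ndarray:
        return np.array([e.upper() == "H" for e in self.elements])

    def mass_center(self, coords: np.ndarray | None = None) -> np.ndarray:
        c = self.coords if coords is None else np.asarray(coords, dtype=float)
        m = self.masses
        return (m[:, None] * c).sum(axis=0) / m.sum()

    def donor_pairs(self) -> np.ndarray:
        """(k, 2) array of (donor-heavy, attached-H) index pairs."""
        pairs = [(int(p), i) for i, p in enumerate(self.h_parent)
                 if p >= 0 and self.hbond_role[p] == ROLE_DONOR]
        return (np.array(pairs, dtype=np.int64).reshape(-1, 2)
                if pairs else np.empty((0, 2), dtype=np.int64))

    def acceptor_indices(self) -> np.ndarray:
        return np.flatnonzero(self.hbond_role == ROLE_ACCEPTOR)

    @property
    def net_charge(self) -> int:
        return int(self.formal_charges.sum())


@dataclass
class Receptor(AtomSet):
    """Rigid macromolecular target; residues are indexable by number."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.n_atoms == 0:
            raise EmptyStructureError("receptor has zero atoms")
        # every donor heavy atom must carry at least one attached H
        donors = set(np.flatnonzero(self.hbond_role == ROLE_DONOR))
        parented = set(int(p) for p in self.h_parent if p >= 0)
        if not donors <= parented:
            raise ValidationError("donor heavy atom without attached hydrogen")

    @property
    def residue_index(self) -> dict[int, np.ndarray]:
        idx: dict[int, list[int]] = {}
        for i, r in enumerate(self.res_numbers):
            idx.setdefault(int(r), []).append(i)
        return {r: np.array(v, dtype=np.int64) for r, v in idx.items()}


@dataclass
class Fragment(AtomSet):
    """A small-molecule fragment: atoms plus a connected bond graph."""

    bonds: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))
    fragment_id: str = "frag"

    def __post_init__(self) -> None:
        super().__post_init__()
        self.bonds = np.asarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        if self.n_atoms == 0:
            raise EmptyStructureError("fragment has zero atoms")
        if np.any(self.masses <= 0):
            raise ValidationError("non-positive atomic mass")
        if self.n_atoms > 1 and not self._connected():
            raise ValidationError("fragment bond graph is not connected")
        if self.heavy_atom_count >= 20:
            warnings.warn(
                f"fragment {self.fragment_id} has {self.heavy_atom_count} "
                "heavy atoms; fragment libraries usually stay below 20",
                stacklevel=2)

    def _connected(self) -> bool:
        adj: dict[int, set[int]] = {i: set() for i in range(self.n_atoms)}
        for a, b in self.bonds:
            adj[int(a)].add(int(b))
            adj[int(b)].add(int(a))
        seen = {0}
        stack = [0]
        while stack:
            for j in adj[stack.pop()]:
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        return len(seen) == self.n_atoms

    @property
    def heavy_atom_count(self) -> int:
        return int((~self.is_hydrogen).sum())


@dataclass(frozen=True)
class SiteDefinition:
    """Binding-site target: the fixed endpoint of the supervised distance."""

    residue_ids: tuple[int, ...]
    center: np.ndarray            # (3,) mass-weighted centroid, Angstrom
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValidationError("site radius must be positive")


@dataclass(frozen=True)
class BoxSpec:
    """Cubic simulation box plus counterion content."""

    edge: float                   # Angstrom
    padding: float = 13.0
    salt_molar: float = 0.1
    n_na: int = 0
    n_cl: int = 0

    @property
    def volume_l(self) -> float:
        return self.edge ** 3 * 1e-27


@dataclass
class SimSystem:
    """Receptor + fragment + start pose + box: the unit one replica runs on."""

    receptor: Receptor
    fragment: Fragment
    start_coords: np.ndarray
    site: SiteDefinition
    box: BoxSpec | None = None
    seed: int = 0
    min_separation: float = 50.0

    def __post_init__(self) -> None:
        self.start_coords = np.asarray(self.start_coords, dtype=float)
        d = float(np.linalg.norm(
            self.fragment.mass_center(self.start_coords) - self.site.center))
        if d < self.min_separation - 1e-6:
            raise ValidationError(
                f"start separation {d:.2f} A below the configured minimum "
                f"{self.min_separation:.2f} A")


def make_atom_set(elements, coords, *, res_numbers=None, res_names=None,
                  charges=None, formal_charges=None, bonds=None,
                  cls=AtomSet, **kw):
    """Build an AtomSet/Receptor/Fragment applying the typing rules."""
    elements = np.asarray(elements, dtype=object)
    coords = np.asarray(coords, dtype=float)
    n = len(elements)
    if res_numbers is None:
        res_numbers = np.ones(n, dtype=np.int64)
    if res_names is None:
        res_names = np.array(["UNK"] * n, dtype=object)
    if formal_charges is None:
        formal_charges = np.zeros(n, dtype=np.int64)
    h_parent = infer_h_parents(elements, coords, bonds)
    polarity, role = assign_typing(elements, formal_charges, h_parent)
    if charges is None:
        charges = default_partial_charges(elements, h_parent)
    kwargs = dict(elements=elements, coords=coords,
                  res_numbers=np.asarray(res_numbers, dtype=np.int64),
                  res_names=np.asarray(res_names, dtype=object),
                  charges=np.asarray(charges, dtype=float),
                  formal_charges=np.asarray(formal_charges, dtype=np.int64),
                  polarity=polarity, hbond_role=role, h_parent=h_parent, **kw)
    if cls is Fragment:
        kwargs["bonds"] = (np.empty((0, 2), dtype=np.int64)
                           if bonds is None else bonds)
    return cls(**kwargs)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def load_receptor(pdb_source) -> Receptor:
    """Parse PDB text (path, file object, or string) into a Receptor."""
    from .fileio import read_pdb

    return read_pdb(pdb_source)


def define_binding_site(receptor: Receptor, residue_ids,
                        radius: float = 10.0) -> SiteDefinition:
    """Site center = mass-weighted centroid of the selected residues' atoms."""
    residue_ids = tuple(int(r) for r in residue_ids)
    if not residue_ids:
        raise LookupResidueError("empty residue selection")
    index = receptor.residue_index
    sel: list[int] = []
    for r in residue_ids:
        if r not in index:
            raise LookupResidueError(f"residue {r} not in receptor")
        sel.extend(index[r].tolist())
    sel = np.array(sorted(sel), dtype=np.int64)
    m = receptor.masses[sel]
    center = (m[:, None] * receptor.coords[sel]).sum(axis=0) / m.sum()
    return SiteDefinition(residue_ids=residue_ids, center=center, radius=radius)


def _fibonacci_directions(n: int) -> np.ndarray:
    """n roughly uniform unit vectors (deterministic golden-spiral lattice)."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * math.pi * i / phi
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _seeded_rotation(seed: int) -> np.ndarray:
    """A uniformly random rotation matrix, deterministic in the seed."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9E3779B9]))
    a = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def place_fragment(receptor: Receptor, fragment: Fragment,
                   site: SiteDefinition, min_separation: float = 50.0,
                   electrostatic_cutoff: float = 9.0, seed: int = 0,
                   n_directions: int = 256) -> SimSystem:
    """Place the fragment mass center exactly ``min_separation`` from the site
    center along the first direction clear of receptor atoms.

    Directions are sampled on a Fibonacci sphere, rotated by a seed-derived
    rotation so replicas approach from different sides.  A direction is clear
    when no fragment atom lies within ``electrostatic_cutoff`` of any receptor
    atom.
    """
    if min_separation < electrostatic_cutoff:
        raise ValidationError(
            f"min_separation {min_separation} A below the electrostatic "
            f"cutoff {electrostatic_cutoff} A")
    dirs = _fibonacci_directions(n_directions) @ _seeded_rotation(seed).T
    com = fragment.mass_center()
    for d in dirs:
        target = site.center + min_separation * d
        cand = fragment.coords + (target - com)
        dmin = np.min(np.linalg.norm(
            receptor.coords[None, :, :] - cand[:, None, :], axis=2))
        if dmin > electrostatic_cutoff:
            return SimSystem(receptor=receptor, fragment=fragment,
                             start_coords=cand, site=site, seed=seed,
                             min_separation=min_separation)
    raise PlacementError(
        f"no collision-free direction among {n_directions} candidates")


def build_box(system: SimSystem, padding: float = 13.0) -> BoxSpec:
    """Cubic edge = largest per-axis coordinate extent + 2 * padding."""
    if padding <= 0:
        raise ValidationError("padding must be positive")
    coords = np.vstack([system.receptor.coords, system.start_coords])
    extent = float(np.max(coords.max(axis=0) - coords.min(axis=0)))
    return BoxSpec(edge=extent + 2.0 * padding, padding=padding)


def counterion_counts(box: BoxSpec, net_charge: int,
                      concentration: float = 0.1) -> tuple[int, int]:
    """Neutralise first, then add whole Na+/Cl- pairs to reach the target
    molarity: ``n_pairs = round(c * V[L] * N_A)``."""
    if concentration < 0:
        raise ValidationError("negative salt concentration")
    n_pairs = int(round(concentration * box.volume_l * AVOGADRO))
    n_na = n_pairs + max(-net_charge, 0)
    n_cl = n_pairs + max(net_charge, 0)
    return n_na, n_cl


def prepare_system(receptor: Receptor, fragment: Fragment,
                   site: SiteDefinition, *, min_separation: float = 50.0,
                   electrostatic_cutoff: float = 9.0, padding: float = 13.0,
                   salt_molar: float = 0.1, seed: int = 0) -> SimSystem:
    """Full preparation: placement, box sizing, counterion counts."""
    system = place_fragment(receptor, fragment, site, min_separation,
                            electrostatic_cutoff, seed=seed)
    box = build_box(system, padding)
    net = receptor.net_charge + fragment.net_charge
    n_na, n_cl = counterion_counts(box, net, salt_molar)
    system.box = replace(box, salt_molar=salt_molar, n_na=n_na, n_cl=n_cl)
    return system
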