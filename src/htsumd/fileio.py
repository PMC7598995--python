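"""File-format adapters.

Kept deliberately minimal and text-only: fixed-column PDB (ATOM/HETATM,
MODEL/ENDMDL, round-trips coordinates at the format's 3-decimal precision),
SDF V2000 for fragments (coordinates, elements, bonds, ``M  CHG`` formal
charges, molecule title as fragment id), and CSV for peak lists, titrations
and trajectory sidecars.  The toy bead structures this package generates are
not valence-sane molecules, so the SDF path does no chemistry beyond the
connection table.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, EmptyStructureError
from .nmr import Peak, Titration
from .systems import Fragment, Receptor, make_atom_set


def _as_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    p = Path(str(source))
    if "\n" not in str(source) and p.exists():
        return p.read_text()
    return str(source)


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _parse_pdb_atoms(text: str):
    """Yield per-model atom lists from ATOM/HETATM records."""
    models: list[list[dict]] = [[]]
    for ln, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "ENDMDL":
            models.append([])
            continue
        if rec not in ("ATOM", "HETATM"):
            continue
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            resno = int(line[22:26])
        except ValueError as exc:
            raise ParseError(f"malformed ATOM record: {exc}", line=ln) from None
        element = line[76:78].strip() or line[12:16].strip()[:1]
        charge_field = line[78:80].strip()
        formal = 0
        if charge_field:
            try:
                mag = int(charge_field[0])
                formal = -mag if charge_field.endswith("-") else mag
            except ValueError:
                raise ParseError(
                    f"bad charge field {charge_field!r}", line=ln) from None
        models[-1].append(dict(
            element=element, x=x, y=y, z=z, resno=resno,
            resname=line[17:20].strip() or "UNK", formal=formal))
    return [m for m in models if m]


def read_pdb(source) -> Receptor:
    """Parse PDB text (first model) into a Receptor."""
    models = _parse_pdb_atoms(_as_text(source))
    if not models:
        raise EmptyStructureError("no ATOM/HETATM records found")
    atoms = models[0]
    return make_atom_set(
        [a["element"] for a in atoms],
        np.array([[a["x"], a["y"], a["z"]] for a in atoms]),
        res_numbers=[a["resno"] for a in atoms],
        res_names=[a["resname"] for a in atoms],
        formal_charges=[a["formal"] for a in atoms],
        cls=Receptor)


def read_pdb_models(source) -> list[np.ndarray]:
    """Coordinate arrays of every model in a multi-model PDB."""
    models = _parse_pdb_atoms(_as_text(source))
    return [np.array([[a["x"], a["y"], a["z"]] for a in m]) for m in models]


def _format_atom(i, element, xyz, resno, resname) -> str:
    for v in xyz:
        if not -999.999 <= v <= 9999.999:
            raise ParseError(f"coordinate {v} overflows the PDB field")
    if not 0 <= resno <= 9999:
        raise ParseError(f"residue number {resno} overflows the PDB field")
    name = element[:4]
    return (f"ATOM  {i % 100000:5d} {name:<4s}{resname[:3]:>3s} A"
            f"{resno:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"  1.00  0.00          {element[:2]:>2s}")


def write_pdb(structure, path=None, frames=None) -> str:
    """Write a Receptor/Fragment (or a set of frames of one) as PDB text."""
    lines: list[str] = []
    frame_list = [structure.coords] if frames is None else list(frames)
    multi = len(frame_list) > 1
    for mi, coords in enumerate(frame_list, start=1):
        if multi:
            lines.append(f"MODEL     {mi:4d}")
        for i in range(structure.n_atoms):
            lines.append(_format_atom(
                i + 1, str(structure.elements[i]), np.asarray(coords)[i],
                int(structure.res_numbers[i]), str(structure.res_names[i])))
        lines.append("ENDMDL" if multi else "TER")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# SDF V2000
# ---------------------------------------------------------------------------

def read_sdf(source) -> list[Fragment]:
    """Parse an SDF (V2000) into Fragments; the title line is the id."""
    text = _as_text(source)
    blocks = [b for b in text.split("$$$$") if b.strip()]
    fragments: list[Fragment] = []
    for mi, block in enumerate(blocks):
        lines = block.lstrip("\n").splitlines()
        if len(lines) < 4:
            raise ParseError(f"molecule {mi}: truncated header")
        title = lines[0].strip() or f"mol{mi}"
        counts = lines[3]
        try:
            n_atoms = int(counts[0:3])
            n_bonds = int(counts[3:6])
        except (ValueError, IndexError):
            raise ParseError(f"molecule {mi} ({title}): bad counts line") \
                from None
        if len(lines) < 4 + n_atoms + n_bonds:
            raise ParseError(f"molecule {mi} ({title}): truncated block")
        coords = np.zeros((n_atoms, 3))
        elements = []
        for i in range(n_atoms):
            line = lines[4 + i]
            try:
                coords[i] = [float(line[0:10]), float(line[10:20]),
                             float(line[20:30])]
            except ValueError:
                raise ParseError(
                    f"molecule {mi} ({title}): bad atom line {i + 1}") \
                    from None
            elements.append(line[31:34].strip())
        bonds = np.zeros((n_bonds, 2), dtype=int)
        for i in range(n_bonds):
            line = lines[4 + n_atoms + i]
            try:
                bonds[i] = [int(line[0:3]) - 1, int(line[3:6]) - 1]
            except ValueError:
                raise ParseError(
                    f"molecule {mi} ({title}): bad bond line {i + 1}") \
                    from None
        formal = np.zeros(n_atoms, dtype=int)
        for line in lines[4 + n_atoms + n_bonds:]:
            if line.startswith("M  CHG"):
                fields = line.split()
                k = int(fields[2])
                for j in range(k):
                    formal[int(fields[3 + 2 * j]) - 1] = int(
                        fields[4 + 2 * j])
        frag = make_atom_set(elements, coords, formal_charges=formal,
                             bonds=bonds, cls=Fragment, fragment_id=title)
        fragments.append(frag)
    if not fragments:
        raise EmptyStructureError("no molecules in SDF input")
    return fragments


def write_sdf(fragments, path=None) -> str:
    """Write fragments as a V2000 SDF (formal charges via ``M  CHG``)."""
    out = io.StringIO()
    for frag in fragments:
        out.write(f"{frag.fragment_id}\n  htsumd\n\n")
        out.write(f"{frag.n_atoms:3d}{len(frag.bonds):3d}  0  0  0  0  0  0"
                  "  0  0999 V2000\n")
        for i in range(frag.n_atoms):
            x, y, z = frag.coords[i]
            out.write(f"{x:10.4f}{y:10.4f}{z:10.4f} "
                      f"{str(frag.elements[i]):<3s} 0  0  0  0  0  0  0  0"
                      "  0  0  0  0\n")
        for a, b in frag.bonds:
            out.write(f"{a + 1:3d}{b + 1:3d}  1  0  0  0  0\n")
        charged = [(i + 1, int(c)) for i, c in enumerate(frag.formal_charges)
                   if c]
        if charged:
            out.write(f"M  CHG{len(charged):3d}" + "".join(
                f"{i:4d}{c:4d}" for i, c in charged) + "\n")
        out.write("M  END\n$$$$\n")
    text = out.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# CSV adapters
# ---------------------------------------------------------------------------

def write_trajectory_csv(trajectory, path) -> None:
    """Sidecar table: one row per frame (d_cm, energy, step bookkeeping)."""
    n = len(trajectory.frames)
    steps = np.repeat(np.arange(trajectory.accepted_steps),
                      trajectory.checkpoints)[:n]
    pd.DataFrame({
        "frame": np.arange(n),
        "step": steps,
        "d_cm": trajectory.d_cm,
        "energy": trajectory.energies,
        "supervised": trajectory.supervised_steps[steps] if n else [],
    }).to_csv(path, index=False)


def read_peaklist_csv(source) -> dict[str, Peak]:
    """``residue,d1H,d15N`` rows into a residue-keyed peak dict."""
    df = pd.read_csv(source)
    need = {"residue", "d1H", "d15N"}
    if not need <= set(df.columns):
        raise ParseError(f"peak list needs columns {sorted(need)}")
    return {str(r.residue): Peak(str(r.residue), float(r.d1H), float(r.d15N))
            for r in df.itertuples()}


def read_titration_csv(source, protein_conc: float) -> Titration:
    """Wide table ``conc_uM,<peak1>,<peak2>,...`` into a Titration."""
    df = pd.read_csv(source)
    if "conc_uM" not in df.columns:
        raise ParseError("titration table needs a conc_uM column")
    peaks = [c for c in df.columns if c != "conc_uM"]
    return Titration(
        ligand_conc=df["conc_uM"].to_numpy(dtype=float),
        shifts={p: df[p].to_numpy(dtype=float) for p in peaks},
        protein_conc=protein_conc)


def write_titration_csv(titration: Titration, path) -> None:
    df = pd.DataFrame({"conc_uM": titration.ligand_conc})
    for peak, vals in titration.shifts.items():
        df[peak] = vals
    df.to_csv(path, index=False)
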