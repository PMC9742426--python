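"""Topology/trajectory I/O.

Reading is delegated to MDAnalysis (PDB, GRO, XTC, DCD, ...); the result is
converted into the package's own :class:`~hydrashell.trajectory.Trajectory`
model.  Writing uses small hand-rolled text writers for multi-model PDB and
GRO so the output is plain text and round-trips through the reader.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import EmptyInputError, FormatError, GeometryError
from .trajectory import AtomRecord, Frame, Trajectory, WATER_RESNAMES

_PROTEIN_RESNAMES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS HSD HSE HSP ILE LEU LYS MET PHE PRO "
    "SER THR TRP TYR VAL MSE".split()
)

_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "SE": 78.971, "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078,
    "ZN": 65.38, "FE": 55.845,
}


def _guess_element(name: str, resname: str) -> str:
    """Element from an atom name, PDB-style: strip digits, try two-letter
    symbols for halogens/metals in non-protein residues, else first letter."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    two = stripped[:2].upper()
    if resname.upper() not in _PROTEIN_RESNAMES and two in _ELEMENT_MASSES and two not in (
        "CA",  # ambiguous with C-alpha; calcium is rare in our inputs
    ):
        if two in ("CL", "BR", "SE", "NA", "MG", "ZN", "FE"):
            return two
    return stripped[0].upper()


def _classify_segment(resname: str) -> str:
    r = resname.upper()
    if r in WATER_RESNAMES:
        return "water"
    if r in _PROTEIN_RESNAMES:
        return "protein"
    return "other"


def read_trajectory(topology_path: str | Path,
                    coords_path: str | Path | None = None,
                    format_hint: str | None = None,
                    dt: float | None = None) -> Trajectory:
    """Read a topology (PDB or GRO) plus optional coordinate set (multi-model
    PDB, GRO, XTC, DCD) into a :class:`Trajectory`.

    ``dt`` overrides/supplies the frame spacing when the format carries no
    timestamps (multi-model PDB).  Water residues are recognised by name
    (HOH/SOL/WAT/TIP3); everything in the standard amino-acid set is tagged
    ``protein``, the rest ``other``.
    """
    import MDAnalysis as mda

    topology_path = Path(topology_path)
    if not topology_path.exists():
        raise FileNotFoundError(topology_path)
    args = [str(topology_path)]
    if coords_path is not None:
        coords_path = Path(coords_path)
        if not coords_path.exists():
            raise FileNotFoundError(coords_path)
        args.append(str(coords_path))
    kwargs = {}
    if format_hint:
        kwargs["format"] = format_hint
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(*args, **kwargs)
        except Exception as exc:  # mda raises many flavours on mismatch
            raise FormatError(f"cannot read {args}: {exc}") from exc

        topology = []
        for i, atom in enumerate(u.atoms):
            resname = str(atom.resname).strip()
            try:
                element = str(atom.element).strip() or "X"
            except Exception:
                element = _guess_element(str(atom.name), resname)
            if element == "X":
                element = _guess_element(str(atom.name), resname)
            element = element.capitalize() if len(element) > 1 else element.upper()
            mass = float(getattr(atom, "mass", 0.0) or 0.0)
            if mass <= 0.0:
                mass = _ELEMENT_MASSES.get(element.upper(), 12.0)
            topology.append(AtomRecord(
                index=i,
                name=str(atom.name).strip(),
                element=element,
                is_hydrogen=element.upper() == "H",
                residue_index=int(atom.residue.ix),
                residue_name=resname,
                segment=_classify_segment(resname),
                mass=mass,
            ))

        frames = []
        for ts in u.trajectory:
            if ts.dimensions is None or not np.all(ts.dimensions[:3] > 0):
                raise GeometryError("frame has no valid box")
            if np.any(np.abs(ts.dimensions[3:6] - 90.0) > 1e-3):
                raise GeometryError("only orthorhombic boxes are supported")
            frames.append(Frame(
                coordinates=ts.positions.astype(float).copy(),
                box=ts.dimensions[:3].astype(float).copy(),
                time=float(ts.time),
            ))
    if not frames:
        raise EmptyInputError("no frames found")

    times = np.array([fr.time for fr in frames])
    src = coords_path if coords_path is not None else topology_path
    timeless = src.suffix.lower() in (".pdb", ".gro", ".ent")
    if len(frames) > 1 and (timeless or np.diff(times).min() <= 0):
        # format carries no physical timestamps (MDAnalysis fakes dt=1 ps)
        step = dt if dt is not None else 1.0
        for k, fr in enumerate(frames):
            fr.time = k * step
        dt_use = step
    else:
        dt_use = dt
    return Trajectory(topology, frames, dt=dt_use)


# ---------------------------------------------------------------------------
# Writers (plain text)
# ---------------------------------------------------------------------------

def write_pdb(traj: Trajectory, path: str | Path,
              frame_indices: Sequence[int] | None = None) -> None:
    """Write a multi-model PDB (coordinates to 1e-3 angstrom)."""
    path = Path(path)
    idxs = range(traj.n_frames) if frame_indices is None else frame_indices
    top = traj.topology
    with open(path, "w") as fh:
        for m, fi in enumerate(idxs, start=1):
            fr = traj.frames[fi]
            fh.write(f"MODEL     {m:4d}\n")
            box = fr.box
            fh.write(
                f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
                f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
            )
            for a in top:
                x, y, z = fr.coordinates[a.index]
                record = "ATOM  " if a.segment == "protein" else "HETATM"
                serial = (a.index + 1) % 100000
                resid = (a.residue_index + 1) % 10000
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                fh.write(
                    f"{record}{serial:5d} {name:<4.4s} {a.residue_name:<4.4s}"
                    f"A{resid:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2.2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_gro(traj: Trajectory, path: str | Path, frame_index: int = 0,
              title: str = "hydrashell system") -> None:
    """Write a single-frame GRO file (nm, 3 decimals -> 1e-2 angstrom)."""
    path = Path(path)
    fr = traj.frames[frame_index]
    with open(path, "w") as fh:
        fh.write(f"{title}, t= {fr.time:.3f}\n")
        fh.write(f"{traj.n_atoms:5d}\n")
        for a in traj.topology:
            x, y, z = fr.coordinates[a.index] / 10.0  # angstrom -> nm
            resid = (a.residue_index + 1) % 100000
            serial = (a.index + 1) % 100000
            fh.write(
                f"{resid:5d}{a.residue_name:<5.5s}{a.name:>5.5s}{serial:5d}"
                f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
            )
        bx, by, bz = fr.box / 10.0
        fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")


def write_xtc(traj: Trajectory, path: str | Path) -> None:
    """Write coordinates as XTC (binary; intended for scratch use only)."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(traj.n_atoms, trajectory=True)
        with mda.Writer(str(path), n_atoms=traj.n_atoms) as w:
            for fr in traj.frames:
                u.atoms.positions = fr.coordinates
                u.dimensions = [*fr.box, 90.0, 90.0, 90.0]
                u.trajectory.ts.time = fr.time
                w.write(u.atoms)
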