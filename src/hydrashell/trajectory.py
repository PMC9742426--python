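"""Core trajectory data model: topology records, frames, rigid-body
superposition, periodic re-imaging of waters, and protein-surface distance.

All coordinates are in angstroms, all times in picoseconds.  Only
orthorhombic boxes are supported; the minimum-image arithmetic is exact for
that case and triclinic input is rejected up front.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    DegenerateFitError,
    EmptyInputError,
    FormatError,
    GeometryError,
    SamplingError,
    SelectionError,
)

WATER_RESNAMES = frozenset({"HOH", "SOL", "WAT", "TIP3", "TIP3P", "SPC", "T3P"})

#: Per-element van der Waals radii (angstrom), Bondi set.  Used both by the
#: optional ``vdw`` surface metric and by SASA.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology.

    ``segment`` classifies the atom as ``protein``, ``water`` or ``other``;
    water oxygens (``segment == "water"`` and ``element == "O"``) are the
    particles every hydration analysis operates on.
    """

    index: int
    name: str
    element: str
    is_hydrogen: bool
    residue_index: int
    residue_name: str
    segment: str
    mass: float

    def __post_init__(self):
        if self.is_hydrogen != (self.element.upper() == "H"):
            raise FormatError(
                f"atom {self.index} ({self.name}): is_hydrogen inconsistent "
                f"with element {self.element!r}"
            )


@dataclass
class Frame:
    """A single snapshot: coordinates (n_atoms, 3) in angstrom, orthorhombic
    box lengths (3,) in angstrom, and a timestamp in ps."""

    coordinates: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise FormatError("coordinates must have shape (n_atoms, 3)")
        if self.box.shape != (3,):
            raise GeometryError("box must be 3 orthorhombic edge lengths")
        if not np.all(self.box > 0):
            raise GeometryError(f"box lengths must be positive, got {self.box}")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    def copy(self) -> "Frame":
        return Frame(self.coordinates.copy(), self.box.copy(), self.time)


class Trajectory:
    """An ordered sequence of frames over a fixed topology.

    Invariants enforced at construction: at least one frame, every frame has
    exactly one coordinate row per topology atom, timestamps are strictly
    increasing with uniform spacing (within 1e-6 ps).
    """

    def __init__(self, topology: Sequence[AtomRecord], frames: Sequence[Frame],
                 dt: float | None = None):
        self.topology = list(topology)
        self.frames = list(frames)
        if not self.frames:
            raise EmptyInputError("trajectory has zero frames")
        n = len(self.topology)
        for i, fr in enumerate(self.frames):
            if fr.n_atoms != n:
                raise FormatError(
                    f"frame {i} has {fr.n_atoms} atoms, topology has {n}"
                )
        times = np.array([fr.time for fr in self.frames])
        if len(times) > 1:
            steps = np.diff(times)
            if np.any(steps <= 0):
                raise SamplingError("timestamps must be strictly increasing")
            if steps.max() - steps.min() > 1e-6:
                raise SamplingError(
                    f"non-uniform frame spacing: dt ranges "
                    f"{steps.min():g}..{steps.max():g} ps"
                )
            inferred = float(steps.mean())
        else:
            inferred = None
        if dt is None:
            dt = inferred if inferred is not None else 1.0
        elif inferred is not None and abs(dt - inferred) > 1e-6:
            raise SamplingError(
                f"explicit dt={dt} ps disagrees with timestamps ({inferred} ps)"
            )
        self.dt = float(dt)
        self._coords = None

    # -- basic accessors -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coords_array(self) -> np.ndarray:
        """Stacked coordinates, shape (n_frames, n_atoms, 3).  Cached."""
        if self._coords is None:
            self._coords = np.stack([fr.coordinates for fr in self.frames])
        return self._coords

    # -- selections ------------------------------------------------------
    def select(self, predicate) -> np.ndarray:
        return np.array([a.index for a in self.topology if predicate(a)], dtype=int)

    def protein_indices(self) -> np.ndarray:
        return self.select(lambda a: a.segment == "protein")

    def protein_heavy_indices(self) -> np.ndarray:
        return self.select(lambda a: a.segment == "protein" and not a.is_hydrogen)

    def calpha_indices(self) -> np.ndarray:
        return self.select(lambda a: a.segment == "protein" and a.name == "CA")

    def water_oxygen_indices(self) -> np.ndarray:
        return self.select(
            lambda a: a.segment == "water" and a.element.upper() == "O"
        )

    def water_residue_groups(self) -> list[np.ndarray]:
        """Atom indices of each water molecule, grouped by residue."""
        groups: dict[int, list[int]] = {}
        for a in self.topology:
            if a.segment == "water":
                groups.setdefault(a.residue_index, []).append(a.index)
        return [np.array(v, dtype=int) for _, v in sorted(groups.items())]

    def copy(self) -> "Trajectory":
        return Trajectory(self.topology, [fr.copy() for fr in self.frames],
                          dt=self.dt)


# ---------------------------------------------------------------------------
# Rigid-body superposition (Kabsch)
# ---------------------------------------------------------------------------

def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rotation R and translation t mapping ``mobile`` onto
    ``reference`` in the least-squares sense: x -> R @ (x - cm) + cr.

    Returns (R, cm, cr) with cm/cr the centroids.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise DegenerateFitError("need >= 3 paired fit atoms")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    P = mobile - cm
    Q = reference - cr
    if np.linalg.matrix_rank(P, tol=1e-8) < 2:
        raise DegenerateFitError("fit atoms are collinear")
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, cm, cr


def superpose_frames(traj: Trajectory, fit_selection: Iterable[int],
                     reference: Frame) -> Trajectory:
    """Rigid-body fit every frame onto ``reference`` using ``fit_selection``
    (Kabsch least squares); the same map is applied to all atoms, waters
    included.  Returns a new trajectory; the input is untouched."""
    sel = np.asarray(list(fit_selection), dtype=int)
    if sel.size == 0:
        raise SelectionError("fit selection is empty")
    if sel.min() < 0 or sel.max() >= traj.n_atoms:
        raise SelectionError("fit selection index out of range")
    if sel.size < 3:
        raise DegenerateFitError("need >= 3 fit atoms")
    ref_xyz = reference.coordinates[sel]
    out = []
    for fr in traj.frames:
        R, cm, cr = kabsch_rotation(fr.coordinates[sel], ref_xyz)
        new_xyz = (fr.coordinates - cm) @ R.T + cr
        out.append(Frame(new_xyz, fr.box.copy(), fr.time))
    return Trajectory(traj.topology, out, dt=traj.dt)


def fit_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """RMSD after optimal superposition of two matched coordinate sets."""
    R, cm, cr = kabsch_rotation(mobile, reference)
    moved = (mobile - cm) @ R.T + cr
    return float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# Periodic re-imaging
# ---------------------------------------------------------------------------

def water_group_arrays(topology: Sequence[AtomRecord]):
    """Vectorization helper: flat water atom indices, the molecule id of
    each, and one reference (oxygen) atom per molecule."""
    groups: dict[int, list[int]] = {}
    oxy: dict[int, int] = {}
    for a in topology:
        if a.segment == "water":
            groups.setdefault(a.residue_index, []).append(a.index)
            if a.element.upper() == "O":
                oxy[a.residue_index] = a.index
    atom_idx, mol_of_atom, oxy_idx = [], [], []
    for m, (res, idxs) in enumerate(sorted(groups.items())):
        atom_idx.extend(idxs)
        mol_of_atom.extend([m] * len(idxs))
        oxy_idx.append(oxy.get(res, idxs[0]))
    return (np.array(atom_idx, dtype=int), np.array(mol_of_atom, dtype=int),
            np.array(oxy_idx, dtype=int))


def wrap_waters(frame: Frame, topology: Sequence[AtomRecord],
                protein_selection: Iterable[int] | None = None,
                groups=None) -> Frame:
    """Map each water molecule to the periodic image whose oxygen is nearest
    (minimum image, orthorhombic) to the protein's geometric centre.  The
    protein is untouched.  Returns a new frame.

    ``groups`` (from :func:`water_group_arrays`) may be passed to avoid
    re-deriving the molecule grouping on every call.
    """
    if not np.all(frame.box > 0):
        raise GeometryError("box lengths must be positive")
    if protein_selection is None:
        protein_selection = [a.index for a in topology if a.segment == "protein"]
    psel = np.asarray(list(protein_selection), dtype=int)
    if psel.size == 0:
        raise SelectionError("protein selection is empty")
    if groups is None:
        groups = water_group_arrays(topology)
    atom_idx, mol_of_atom, oxy_idx = groups
    center = frame.coordinates[psel].mean(axis=0)
    xyz = frame.coordinates.copy()
    if oxy_idx.size:
        L = frame.box
        shift = -L * np.round((xyz[oxy_idx] - center) / L)
        xyz[atom_idx] += shift[mol_of_atom]
    return Frame(xyz, frame.box.copy(), frame.time)


def wrap_trajectory(traj: Trajectory,
                    protein_selection: Iterable[int] | None = None) -> Trajectory:
    groups = water_group_arrays(traj.topology)
    frames = [wrap_waters(fr, traj.topology, protein_selection, groups=groups)
              for fr in traj.frames]
    return Trajectory(traj.topology, frames, dt=traj.dt)


# ---------------------------------------------------------------------------
# Surface distance
# ---------------------------------------------------------------------------

def surface_distance(points: np.ndarray, frame: Frame,
                     protein_heavy: Iterable[int],
                     metric: str = "center",
                     topology: Sequence[AtomRecord] | None = None) -> np.ndarray:
    """Distance from query point(s) to the protein surface.

    The surface is operationalised as the protein heavy-atom centres:
    ``metric="center"`` returns the nearest-centre distance; ``metric="vdw"``
    subtracts each atom's van der Waals radius (requires ``topology``) and
    clips at zero.
    """
    sel = np.asarray(list(protein_heavy), dtype=int)
    if sel.size == 0:
        raise SelectionError("protein heavy-atom selection is empty")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    centers = frame.coordinates[sel]
    if metric == "center":
        tree = cKDTree(centers)
        d, _ = tree.query(pts, k=1)
    elif metric == "vdw":
        if topology is None:
            raise SelectionError("metric='vdw' requires the topology")
        radii = np.array([VDW_RADII.get(topology[i].element.upper(), 1.7)
                          for i in sel])
        diff = pts[:, None, :] - centers[None, :, :]
        d = np.maximum(np.linalg.norm(diff, axis=2) - radii[None, :], 0.0).min(axis=1)
    else:
        raise SelectionError(f"unknown surface metric {metric!r}")
    d = np.asarray(d, dtype=float)
    if np.asarray(points).ndim == 1:
        return float(d[0])
    return d
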