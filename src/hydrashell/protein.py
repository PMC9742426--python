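"""Protein-dynamics metrics over a trajectory: RMSF, backbone N-H order
parameters S^2, radius of gyration, fitted RMSD series, and Shrake-Rupley
SASA."""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ParameterError, SelectionError
from .trajectory import (
    Frame,
    Trajectory,
    VDW_RADII,
    kabsch_rotation,
)

logger = logging.getLogger(__name__)


def compute_rmsf(traj: Trajectory, selection: Iterable[int] | None = None,
                 by_residue: bool = True):
    """Root-mean-square fluctuation about the time-average position.

    Assumes the trajectory is already superposed.  Returns a pandas Series
    keyed on residue index (``by_residue``) or atom index.
    """
    sel = (np.asarray(list(selection), dtype=int) if selection is not None
           else traj.protein_heavy_indices())
    if sel.size == 0:
        raise SelectionError("empty selection")
    if traj.n_frames == 1:
        logger.warning("single frame: RMSF is identically zero")
    xyz = traj.coords_array()[:, sel, :]
    mean = xyz.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((xyz - mean) ** 2, axis=2), axis=0))
    if not by_residue:
        return pd.Series(rmsf, index=sel, name="rmsf")
    res = np.array([traj.topology[i].residue_index for i in sel])
    return pd.Series(rmsf).groupby(res).mean().rename("rmsf")


def compute_order_parameters(traj: Trajectory,
                             vector_pairs: Sequence[tuple[int, int]],
                             window: int | None = None) -> pd.Series:
    """Generalized order parameter S^2 of bond vectors (e.g. backbone N-H),
    from the time-averaged second-rank tensor:

        S^2 = (3/2) * sum_ij <mu_i mu_j>^2 - 1/2

    over unit vectors mu(t).  Full-trajectory average by default; with
    ``window`` (frames) the tensor is averaged per non-overlapping window
    and the window S^2 values are averaged (comparison with ns-timescale
    NMR order parameters).  Values are clamped to [0, 1] (clamping is
    logged).  Returns a Series keyed on the residue index of the first
    atom of each pair.
    """
    if not vector_pairs:
        raise SelectionError("no vector pairs")
    if window is not None and window < 2:
        raise ParameterError("window must span >= 2 frames")

    def tensor_s2(mu):
        t = mu.T @ mu / mu.shape[0]
        return 1.5 * float(np.sum(t * t)) - 0.5

    out = {}
    n_clamped = 0
    for (a, b) in vector_pairs:
        v = traj.coords_array()[:, b, :] - traj.coords_array()[:, a, :]
        mu = v / np.linalg.norm(v, axis=1, keepdims=True)
        if window is None:
            s2 = tensor_s2(mu)
        else:
            vals = [tensor_s2(mu[k:k + window])
                    for k in range(0, len(mu) - window + 1, window)]
            s2 = float(np.mean(vals))
        if s2 < 0 or s2 > 1:
            n_clamped += 1
            s2 = min(max(s2, 0.0), 1.0)
        out[traj.topology[a].residue_index] = s2
    if n_clamped:
        logger.warning("clamped S^2 for %d of %d vectors", n_clamped,
                       len(vector_pairs))
    return pd.Series(out, name="s2")


def backbone_nh_pairs(traj: Trajectory) -> list[tuple[int, int]]:
    """(N, H) atom-index pairs per residue, matching backbone amide naming
    (H, HN or H1 bonded to N)."""
    pairs = []
    by_res: dict[int, dict[str, int]] = {}
    for a in traj.topology:
        if a.segment == "protein":
            by_res.setdefault(a.residue_index, {})[a.name] = a.index
    for res, atoms in sorted(by_res.items()):
        if "N" in atoms:
            for hname in ("H", "HN", "H1"):
                if hname in atoms:
                    pairs.append((atoms["N"], atoms[hname]))
                    break
    return pairs


def compute_rg(traj: Trajectory, selection: Iterable[int] | None = None,
               mass_weighted: bool = True) -> pd.Series:
    """Radius of gyration per frame (angstrom), indexed by time (ps)."""
    sel = (np.asarray(list(selection), dtype=int) if selection is not None
           else traj.protein_indices())
    if sel.size == 0:
        raise SelectionError("empty selection")
    masses = (np.array([traj.topology[i].mass for i in sel])
              if mass_weighted else np.ones(sel.size))
    total = masses.sum()
    if total <= 0:
        raise ParameterError("zero total mass")
    xyz = traj.coords_array()[:, sel, :]
    com = (xyz * masses[None, :, None]).sum(axis=1) / total
    d2 = np.sum((xyz - com[:, None, :]) ** 2, axis=2)
    rg = np.sqrt((d2 * masses[None, :]).sum(axis=1) / total)
    times = [fr.time for fr in traj.frames]
    return pd.Series(rg, index=times, name="rg")


def compute_rmsd_series(traj: Trajectory, reference: Frame,
                        fit_selection: Iterable[int],
                        measure_selection: Iterable[int] | None = None
                        ) -> pd.Series:
    """Per-frame RMSD to a reference after a Kabsch fit on
    ``fit_selection``; measured over ``measure_selection`` (defaults to the
    fit selection)."""
    fit = np.asarray(list(fit_selection), dtype=int)
    meas = (np.asarray(list(measure_selection), dtype=int)
            if measure_selection is not None else fit)
    if fit.size == 0 or meas.size == 0:
        raise SelectionError("empty selection")
    ref_fit = reference.coordinates[fit]
    ref_meas = reference.coordinates[meas]
    out = []
    for fr in traj.frames:
        R, cm, cr = kabsch_rotation(fr.coordinates[fit], ref_fit)
        moved = (fr.coordinates[meas] - cm) @ R.T + cr
        out.append(float(np.sqrt(np.mean(np.sum((moved - ref_meas) ** 2,
                                                axis=1)))))
    times = [fr.time for fr in traj.frames]
    return pd.Series(out, index=times, name="rmsd")


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley)
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden
    spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + math.sqrt(5.0)) * i
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def compute_sasa(frame: Frame, topology: Sequence, selection=None,
                 radii: dict[str, float] | None = None, probe: float = 1.4,
                 n_points: int = 960) -> tuple[float, pd.DataFrame]:
    """Solvent-accessible surface area by Shrake-Rupley sphere sampling.

    For each selected atom, the fraction of ``n_points`` quasi-uniform
    points on its probe-expanded sphere not buried inside any neighbour's
    expanded sphere, times 4*pi*(r+probe)^2.  Returns (total nm^2,
    per-residue table in nm^2).
    """
    if radii is None:
        radii = VDW_RADII
    if selection is None:
        selection = [a.index for a in topology
                     if a.segment == "protein" and not a.is_hydrogen]
    sel = np.asarray(list(selection), dtype=int)
    if sel.size == 0:
        raise SelectionError("empty selection")
    missing = sorted({topology[i].element.upper() for i in sel}
                     - set(radii.keys()))
    if missing:
        raise ParameterError(f"no radius for element(s): {', '.join(missing)}")
    r = np.array([radii[topology[i].element.upper()] for i in sel]) + probe
    xyz = frame.coordinates[sel]
    pts = _sphere_points(n_points)

    tree = cKDTree(xyz)
    max_r = r.max()
    areas = np.empty(sel.size)
    for i in range(sel.size):
        sphere = xyz[i] + r[i] * pts
        nb = [j for j in tree.query_ball_point(xyz[i], r[i] + max_r)
              if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in nb:
            d = np.linalg.norm(sphere - xyz[j], axis=1)
            # asymmetric boundary rule (with a rounding-safe band) so
            # exactly coincident spheres count once; for generic geometry
            # the boundary shell is measure-zero
            exposed &= (d >= r[j] - 1e-9) if j > i else (d > r[j] + 1e-9)
        areas[i] = exposed.mean() * 4.0 * math.pi * r[i] ** 2

    res = np.array([topology[i].residue_index for i in sel])
    table = pd.DataFrame({"residue_index": res, "sasa_nm2": areas / 100.0})
    table = table.groupby("residue_index", as_index=False).sum()
    return float(areas.sum() / 100.0), table
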