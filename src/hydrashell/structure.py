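"""Structural hydration analysis.

Bulk-normalized 3D water-oxygen density on a regular grid, hydration-site
(local-maximum) detection, a surface-referenced radial distribution G(r)
sampled in orientation-scanned cylinders, shell classification from the
G(r) minima, and per-residue water contact counts.

Conventions: the grid is fixed in the frame of the superposition reference;
"surface distance" is the nearest protein heavy-atom centre distance (see
:func:`hydrashell.trajectory.surface_distance`); densities are reported in
bulk units, where bulk is the mean raw density over grid nodes whose surface
distance lies in the 8.0–10.0 A shell.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import (
    EmptyInputError,
    NormalizationError,
    ParameterError,
    SelectionError,
)
from .trajectory import (
    Frame,
    Trajectory,
    surface_distance,
    water_group_arrays,
    wrap_waters,
)

logger = logging.getLogger(__name__)

#: fallback shell boundaries (angstrom) when G(r) minima cannot be located
FALLBACK_FIRST_BOUNDARY = 2.25
FALLBACK_SECOND_BOUNDARY = 3.5


@dataclass
class DensityGrid:
    origin: np.ndarray          # corner of node (0,0,0), angstrom
    step: float
    shape: tuple[int, int, int]
    values: np.ndarray          # normalized density, bulk units
    bulk_density: float         # raw counts / (A^3 * frame)
    n_frames: int
    node_surface_distance: np.ndarray | None = None

    def node_centers(self) -> np.ndarray:
        nx, ny, nz = self.shape
        ax = self.origin[0] + (np.arange(nx) + 0.5) * self.step
        ay = self.origin[1] + (np.arange(ny) + 0.5) * self.step
        az = self.origin[2] + (np.arange(nz) + 0.5) * self.step
        gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


@dataclass
class HydrationSite:
    id: int
    position: np.ndarray        # node centre of the local maximum
    peak_density: float         # bulk units
    surface_distance: float
    shell: str = "outer"        # first | second | outer


@dataclass
class SurfaceRDF:
    bin_centers: np.ndarray
    g: np.ndarray
    n_samples: np.ndarray
    peaks: list[tuple[float, float]] = field(default_factory=list)
    first_minimum: float | None = None
    second_minimum: float | None = None
    empty: bool = False

    def boundaries(self) -> tuple[float, float]:
        """Shell boundaries, falling back to fixed defaults when the minima
        could not be located on the curve."""
        if self.first_minimum is not None and self.second_minimum is not None:
            return self.first_minimum, self.second_minimum
        logger.warning("G(r) minima not found; using fallback shell "
                       "boundaries %.2f/%.2f A",
                       FALLBACK_FIRST_BOUNDARY, FALLBACK_SECOND_BOUNDARY)
        return FALLBACK_FIRST_BOUNDARY, FALLBACK_SECOND_BOUNDARY


# ---------------------------------------------------------------------------
# Density grid
# ---------------------------------------------------------------------------

def compute_density_grid(traj: Trajectory, step: float = 0.5,
                         padding: float = 12.0,
                         bulk_shell: tuple[float, float] = (8.0, 10.0),
                         reference: Frame | None = None,
                         wrap: bool = True) -> DensityGrid:
    """Bulk-normalized water-oxygen density over the superposed ensemble.

    Each (re-imaged) water oxygen increments the count of the grid node
    containing it; raw density is counts / (n_frames * step^3) and is
    divided by the bulk density, the mean raw density over nodes whose
    surface distance to the reference-frame protein lies in ``bulk_shell``.
    """
    if step <= 0:
        raise ParameterError("step must be > 0")
    wox = traj.water_oxygen_indices()
    if wox.size == 0:
        raise EmptyInputError("no water oxygens in topology")
    heavy = traj.protein_heavy_indices()
    if heavy.size == 0:
        raise SelectionError("no protein heavy atoms")
    ref = reference if reference is not None else traj.frames[0]

    prot_xyz = ref.coordinates[heavy]
    lo = prot_xyz.min(axis=0) - padding
    hi = prot_xyz.max(axis=0) + padding
    shape = tuple(int(np.ceil((hi[k] - lo[k]) / step)) for k in range(3))
    nx, ny, nz = shape
    n_nodes = nx * ny * nz

    # Only the water oxygens are binned, and re-imaging moves a molecule by
    # its oxygen's minimum-image shift, so the oxygens can be wrapped and
    # binned directly, vectorized over chunks of frames.
    counts = np.zeros(n_nodes, dtype=np.int64)
    psel = traj.protein_indices()
    shape_arr = np.array(shape)
    chunk = max(1, int(5_000_000 / max(wox.size, 1)))
    for c0 in range(0, traj.n_frames, chunk):
        frames = traj.frames[c0:c0 + chunk]
        pts = np.stack([fr.coordinates[wox] for fr in frames])  # (F, W, 3)
        if wrap:
            centers_f = np.stack([fr.coordinates[psel].mean(axis=0)
                                  for fr in frames])
            boxes = np.stack([fr.box for fr in frames])
            pts = pts - boxes[:, None, :] * np.round(
                (pts - centers_f[:, None, :]) / boxes[:, None, :])
        pts = pts.reshape(-1, 3)
        ijk = np.floor((pts - lo) / step).astype(int)
        ok = np.all((ijk >= 0) & (ijk < shape_arr), axis=1)
        ijk = ijk[ok]
        flat = np.ravel_multi_index((ijk[:, 0], ijk[:, 1], ijk[:, 2]), shape)
        counts += np.bincount(flat, minlength=n_nodes)

    raw = counts / (traj.n_frames * step ** 3)

    # bulk nodes: in the shell AND inside the box centred on the protein
    # (nodes outside the box can never receive wrapped waters)
    centers = _grid_centers(lo, step, shape)
    dsurf = _node_surface_distances(centers, prot_xyz)
    pcen = ref.coordinates[traj.protein_indices()].mean(axis=0)
    inside_box = np.all(np.abs(centers - pcen) <= ref.box[None, :] / 2.0,
                        axis=1)
    bulk_mask = ((dsurf >= bulk_shell[0]) & (dsurf <= bulk_shell[1])
                 & inside_box)
    if not bulk_mask.any():
        raise NormalizationError(
            f"no grid nodes with surface distance in {bulk_shell}; "
            f"box too small?")
    bulk_density = float(raw[bulk_mask].mean())
    if bulk_density <= 0:
        raise NormalizationError("bulk shell contains zero water counts")

    return DensityGrid(
        origin=lo, step=step, shape=shape,
        values=(raw / bulk_density).reshape(shape),
        bulk_density=bulk_density, n_frames=traj.n_frames,
        node_surface_distance=dsurf.reshape(shape),
    )


def _grid_centers(lo, step, shape):
    nx, ny, nz = shape
    ax = lo[0] + (np.arange(nx) + 0.5) * step
    ay = lo[1] + (np.arange(ny) + 0.5) * step
    az = lo[2] + (np.arange(nz) + 0.5) * step
    gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


def _node_surface_distances(centers, prot_xyz):
    tree = cKDTree(prot_xyz)
    d, _ = tree.query(centers, k=1)
    return d


# ---------------------------------------------------------------------------
# Hydration-site detection
# ---------------------------------------------------------------------------

def detect_hydration_sites(grid: DensityGrid, frame: Frame,
                           protein_heavy: Iterable[int],
                           min_density: float = 2.0,
                           radius: float = 1.4,
                           rdf: SurfaceRDF | None = None) -> list[HydrationSite]:
    """Detect hydration sites: grid nodes that are strict local maxima of
    the normalized density within ``radius`` and reach ``min_density``
    (bulk units), selected greedily in descending density with mutual
    exclusion at ``radius``.  Ties break toward the lower flat node index.
    """
    if radius <= 0:
        raise ParameterError("radius must be > 0")
    vals = grid.values
    shape = grid.shape
    cand = np.argwhere(vals >= min_density)
    if cand.size == 0:
        return []
    flat = np.ravel_multi_index((cand[:, 0], cand[:, 1], cand[:, 2]), shape)
    cv = vals.ravel()[flat]
    # descending density, ascending flat index on ties
    order = np.lexsort((flat, -cv))
    cand, flat, cv = cand[order], flat[order], cv[order]

    # stencil of node offsets within the exclusion ball
    r_nodes = int(math.floor(radius / grid.step))
    offs = np.array([
        (i, j, k)
        for i in range(-r_nodes, r_nodes + 1)
        for j in range(-r_nodes, r_nodes + 1)
        for k in range(-r_nodes, r_nodes + 1)
        if (i or j or k) and (i * i + j * j + k * k) * grid.step ** 2 <= radius ** 2
    ])

    accepted: list[HydrationSite] = []
    accepted_ijk: list[np.ndarray] = []
    shape_arr = np.array(shape)
    for ijk, fidx, v in zip(cand, flat, cv):
        # mutual exclusion against already accepted (higher-density) sites
        if accepted_ijk:
            d2 = np.sum((np.array(accepted_ijk) - ijk) ** 2, axis=1)
            if (d2 * grid.step ** 2 <= radius ** 2).any():
                continue
        nb = ijk + offs
        ok = np.all((nb >= 0) & (nb < shape_arr), axis=1)
        nb = nb[ok]
        nbv = vals[nb[:, 0], nb[:, 1], nb[:, 2]]
        nbf = np.ravel_multi_index((nb[:, 0], nb[:, 1], nb[:, 2]), shape)
        # strict maximum; exact ties resolved toward the lower flat index
        if np.any(nbv > v) or np.any((nbv == v) & (nbf < fidx)):
            continue
        pos = grid.origin + (ijk + 0.5) * grid.step
        accepted.append(HydrationSite(
            id=len(accepted), position=pos, peak_density=float(v),
            surface_distance=float(surface_distance(pos, frame, protein_heavy)),
        ))
        accepted_ijk.append(ijk)

    lo_b, hi_b = (rdf.boundaries() if rdf is not None
                  else (FALLBACK_FIRST_BOUNDARY, FALLBACK_SECOND_BOUNDARY))
    for s in accepted:
        s.shell = _shell_label(s.surface_distance, lo_b, hi_b)
    return accepted


# ---------------------------------------------------------------------------
# Surface-referenced G(r)
# ---------------------------------------------------------------------------

def compute_surface_rdf(traj: Trajectory, diameter: float = 4.0,
                        angle_step: float = 20.0, bin_width: float = 0.1,
                        r_max: float = 12.0,
                        bulk_range: tuple[float, float] = (8.0, 10.0),
                        reference: Frame | None = None,
                        wrap: bool = True,
                        volume_correction: bool = True,
                        volume_mc_points: int = 3_000_000) -> SurfaceRDF:
    """Surface-distance G(r) of water oxygens sampled inside cylinders.

    An infinite double-sided cylinder of the given diameter passes through
    the protein centre of mass; its axis is scanned over two Euler angles
    (alpha in [0,360), beta in [0,180), both stepped by ``angle_step``).
    Waters inside a cylinder contribute their surface distance once per
    orientation.

    With ``volume_correction`` (default) each bin's count is divided by the
    volume the cylinders actually sample at that surface distance,
    estimated by deterministic Monte-Carlo integration over the same
    cylinder set; without it raw counts are used (geometrically biased at
    small r, where a shell intersects proportionally more of a cylinder).
    Either way the curve is normalized so the mean over ``bulk_range`` is 1.
    """
    if bin_width <= 0:
        raise ParameterError("bin_width must be > 0")
    if r_max < 10.0:
        raise ParameterError("r_max must be >= 10 A to cover the bulk shell")
    wox = traj.water_oxygen_indices()
    heavy = traj.protein_heavy_indices()
    if heavy.size == 0:
        raise SelectionError("no protein heavy atoms")
    ref = reference if reference is not None else traj.frames[0]
    prot_xyz = ref.coordinates[heavy]
    tree = cKDTree(prot_xyz)
    masses = np.array([traj.topology[i].mass for i in traj.protein_indices()])
    pxyz = ref.coordinates[traj.protein_indices()]
    com = (pxyz * masses[:, None]).sum(axis=0) / masses.sum()

    alphas = np.deg2rad(np.arange(0.0, 360.0, angle_step))
    betas = np.deg2rad(np.arange(0.0, 180.0, angle_step))
    A, B = np.meshgrid(alphas, betas, indexing="ij")
    axes = np.column_stack([
        (np.cos(A) * np.sin(B)).ravel(),
        (np.sin(A) * np.sin(B)).ravel(),
        np.cos(B).ravel(),
    ])
    r_cyl2 = (diameter / 2.0) ** 2

    n_bins = int(math.ceil(r_max / bin_width))
    hist = np.zeros(n_bins, dtype=np.int64)
    groups = water_group_arrays(traj.topology) if wrap else None
    for fr in traj.frames:
        f = wrap_waters(fr, traj.topology, groups=groups) if wrap else fr
        w = f.coordinates[wox]
        if w.size == 0:
            continue
        v = w - com
        vv = np.sum(v * v, axis=1)
        proj = v @ axes.T                     # (n_w, n_dir)
        perp2 = vv[:, None] - proj ** 2
        inside_counts = np.sum(perp2 <= r_cyl2, axis=1)  # per water
        sel = inside_counts > 0
        if not sel.any():
            continue
        d, _ = tree.query(w[sel], k=1)
        b = np.floor(d / bin_width).astype(int)
        ok = b < n_bins
        hist += np.bincount(b[ok], weights=inside_counts[sel][ok],
                            minlength=n_bins).astype(np.int64)

    centers = (np.arange(n_bins) + 0.5) * bin_width
    if hist.sum() == 0:
        return SurfaceRDF(bin_centers=centers, g=np.zeros(n_bins),
                          n_samples=hist, empty=True)

    if volume_correction:
        vol = _cylinder_bin_volumes(axes, com, diameter / 2.0, prot_xyz,
                                    bin_width, n_bins,
                                    n_total=volume_mc_points)
        dens = np.divide(hist, vol, out=np.zeros(n_bins), where=vol > 0)
    else:
        dens = hist.astype(float)

    bulk_bins = (centers >= bulk_range[0]) & (centers <= bulk_range[1])
    bulk_mean = dens[bulk_bins].mean() if bulk_bins.any() else 0.0
    if bulk_mean <= 0:
        raise NormalizationError("no G(r) samples in the bulk range")
    g = dens / bulk_mean

    rdf = SurfaceRDF(bin_centers=centers, g=g, n_samples=hist)
    _locate_peaks(rdf)
    return rdf


def _cylinder_bin_volumes(axes: np.ndarray, com: np.ndarray, r_cyl: float,
                          prot_xyz: np.ndarray, bin_width: float,
                          n_bins: int, n_total: int = 3_000_000) -> np.ndarray:
    """Volume (summed over cylinders) each surface-distance bin samples,
    by Monte-Carlo integration with a fixed internal seed (deterministic).

    Points are drawn uniformly inside each cylinder over an axial extent
    that covers every location whose surface distance can fall below the
    histogram range."""
    rng = np.random.default_rng(0x5EED)
    n_dirs = len(axes)
    k = max(2000, n_total // n_dirs)
    reach = (np.max(np.linalg.norm(prot_xyz - com, axis=1))
             + n_bins * bin_width + 2 * r_cyl)

    # orthonormal frame per axis
    helper = np.where(np.abs(axes[:, 2:3]) < 0.9,
                      np.array([[0.0, 0.0, 1.0]]),
                      np.array([[1.0, 0.0, 0.0]]))
    v1 = np.cross(axes, helper)
    v1 /= np.linalg.norm(v1, axis=1, keepdims=True)
    v2 = np.cross(axes, v1)

    xi = rng.uniform(-reach, reach, (n_dirs, k))
    rad = r_cyl * np.sqrt(rng.random((n_dirs, k)))
    ang = rng.uniform(0.0, 2.0 * np.pi, (n_dirs, k))
    pts = (com[None, None, :]
           + xi[:, :, None] * axes[:, None, :]
           + (rad * np.cos(ang))[:, :, None] * v1[:, None, :]
           + (rad * np.sin(ang))[:, :, None] * v2[:, None, :]).reshape(-1, 3)
    tree = cKDTree(prot_xyz)
    d, _ = tree.query(pts, k=1)
    b = np.floor(d / bin_width).astype(int)
    ok = b < n_bins
    counts = np.bincount(b[ok], minlength=n_bins)
    vol_per_pt = (np.pi * r_cyl ** 2 * 2.0 * reach) / k
    return counts * vol_per_pt


def _moving_average(y: np.ndarray, w: int = 3) -> np.ndarray:
    kernel = np.ones(w) / w
    pad = w // 2
    yp = np.pad(y, pad, mode="edge")
    return np.convolve(yp, kernel, mode="valid")


def _locate_peaks(rdf: SurfaceRDF, smooth_window: int = 3,
                  min_height: float = 1.1) -> None:
    """Find the first two G(r) peaks and the minima bounding the shells on a
    moving-average-smoothed curve."""
    from scipy.signal import find_peaks

    s = _moving_average(rdf.g, smooth_window)
    idx, _ = find_peaks(s, height=min_height)
    # only peaks clearly below the bulk region qualify as shell peaks
    idx = [i for i in idx if rdf.bin_centers[i] < 7.0]
    rdf.peaks = [(float(rdf.bin_centers[i]), float(rdf.g[i])) for i in idx[:2]]
    if len(idx) >= 1:
        p1 = idx[0]
        if len(idx) >= 2:
            p2 = idx[1]
            valley = p1 + int(np.argmin(s[p1:p2 + 1]))
            rdf.first_minimum = float(rdf.bin_centers[valley])
            # second boundary: minimum within 2.5 A after the second peak
            hi = min(p2 + int(2.5 / (rdf.bin_centers[1] - rdf.bin_centers[0])),
                     len(s) - 1)
            valley2 = p2 + int(np.argmin(s[p2:hi + 1]))
            rdf.second_minimum = float(rdf.bin_centers[valley2])


# ---------------------------------------------------------------------------
# Shell classification
# ---------------------------------------------------------------------------

def _shell_label(distance: float, first_boundary: float,
                 second_boundary: float) -> str:
    if distance <= first_boundary:
        return "first"
    if distance <= second_boundary:
        return "second"
    return "outer"


def classify_shells(site_or_distance, rdf: SurfaceRDF | None) -> str:
    """Shell label for a site or a bare surface distance: closed boundaries
    at the G(r) first/second minima (fallback fixed boundaries when the
    curve yields none)."""
    if rdf is not None:
        lo, hi = rdf.boundaries()
    else:
        logger.warning("no G(r) available; using fallback shell boundaries")
        lo, hi = FALLBACK_FIRST_BOUNDARY, FALLBACK_SECOND_BOUNDARY
    d = (site_or_distance.surface_distance
         if isinstance(site_or_distance, HydrationSite)
         else float(site_or_distance))
    return _shell_label(d, lo, hi)


# ---------------------------------------------------------------------------
# Residue-water contacts
# ---------------------------------------------------------------------------

def residue_water_contacts(traj: Trajectory, cutoff: float = 3.5,
                           wrap: bool = True) -> tuple[pd.DataFrame, float]:
    """Mean number of distinct waters in direct contact with each residue.

    A water counts for residue r in a frame if its oxygen lies within
    ``cutoff`` of any heavy atom of r.  Returns the per-residue table and
    the overall mean over residues.
    """
    heavy = traj.protein_heavy_indices()
    if heavy.size == 0:
        raise SelectionError("no protein heavy atoms")
    wox = traj.water_oxygen_indices()

    res_of_atom = np.array([traj.topology[i].residue_index for i in heavy])
    residues = np.unique(res_of_atom)
    res_names = {a.residue_index: a.residue_name for a in traj.topology
                 if a.segment == "protein"}
    counts = np.zeros(len(residues), dtype=float)
    res_pos = {r: i for i, r in enumerate(residues)}

    groups = water_group_arrays(traj.topology) if wrap else None
    for fr in traj.frames:
        f = wrap_waters(fr, traj.topology, groups=groups) if wrap else fr
        if wox.size == 0:
            continue
        wtree = cKDTree(f.coordinates[wox])
        neighbours = wtree.query_ball_point(f.coordinates[heavy], cutoff)
        per_res: dict[int, set] = {}
        for ai, nb in enumerate(neighbours):
            if nb:
                per_res.setdefault(res_of_atom[ai], set()).update(nb)
        for r, waters in per_res.items():
            counts[res_pos[r]] += len(waters)

    means = counts / traj.n_frames
    table = pd.DataFrame({
        "residue_index": residues,
        "residue_name": [res_names[r] for r in residues],
        "mean_waters": means,
    })
    return table, float(means.mean())


def residue_hydration_classes(table: pd.DataFrame,
                              factor: float = 2.0) -> pd.DataFrame:
    """Per-residue-type hydration summary with a hyper-hydration flag for
    residues whose mean water count is >= ``factor`` times the protein-wide
    mean."""
    overall = table["mean_waters"].mean()
    out = table.copy()
    out["hyper_hydrated"] = out["mean_waters"] >= factor * overall
    summary = out.groupby("residue_name").agg(
        n=("mean_waters", "size"),
        mean_waters=("mean_waters", "mean"),
        n_hyper=("hyper_hydrated", "sum"),
    ).reset_index()
    return summary
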