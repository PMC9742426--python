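"""Synthetic water trajectories with planted hydration structure/dynamics.

The generator plants three ingredients on top of a rigid (or weakly
jittering) dummy scaffold in a periodic orthorhombic box:

* uniform bulk waters (i.i.d. per frame, or diffusing via Gaussian steps),
* discrete hydration sites whose occupancy follows a two-state Markov chain
  (geometric dwell in discrete frames -> exponential in the continuous
  limit, so the true residence time is analytic),
* optional shell enrichment: extra waters placed at prescribed distances
  from the scaffold surface to shape G(r) peaks.

Every stochastic draw flows through one ``numpy`` Generator, so equal seeds
give bit-identical trajectories.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import GeometryError, ParameterError
from .trajectory import AtomRecord, Frame, Trajectory


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class PlantedSite:
    """A planted hydration site.

    ``dwell_time`` is the mean of the exponential continuous-occupancy dwell;
    ``occupancy`` the stationary fraction of occupied frames.  While occupied
    the occupant water sits within ``capture_radius`` of the site centre —
    uniformly in the ball by default, or Gaussian (truncated at the radius)
    when ``placement_sigma`` is set, which concentrates the density peak on
    the site centre.
    """

    position: tuple[float, float, float]
    dwell_time: float
    occupancy: float = 1.0
    capture_radius: float = 1.0
    placement_sigma: float | None = None

    def __post_init__(self):
        if self.dwell_time <= 0:
            raise ParameterError("dwell_time must be > 0")
        if not (0 < self.occupancy <= 1):
            raise ParameterError("occupancy must be in (0, 1]")
        if self.capture_radius <= 0:
            raise ParameterError("capture_radius must be > 0")


@dataclass
class Scaffold:
    """Dummy protein-like scaffold.  ``single_sphere`` spreads ``n_atoms``
    points quasi-uniformly on a sphere (radius 0 / one atom = point
    scaffold); ``bead_chain`` is a straight chain of beads."""

    kind: str = "single_sphere"
    radius: float = 6.0
    n_atoms: int = 120
    n_beads: int = 20
    spacing: float = 3.8
    jitter: float = 0.0  # per-frame Gaussian jitter sigma (angstrom)

    def positions(self, center: np.ndarray) -> np.ndarray:
        if self.kind == "single_sphere":
            if self.n_atoms == 1 or self.radius == 0:
                return center[None, :] + 0.0
            # filled sphere: outer shell plus a mid-radius layer and a
            # centre atom, so interior points have small surface distances
            # (a hollow scaffold would fake large-distance vacuum)
            outer = self.radius * _fibonacci_sphere(self.n_atoms)
            mid = (self.radius / 2.0
                   * _fibonacci_sphere(max(self.n_atoms // 3, 8)))
            return center + np.vstack([outer, mid, np.zeros((1, 3))])
        if self.kind == "bead_chain":
            n = self.n_beads
            xs = (np.arange(n) - (n - 1) / 2.0) * self.spacing
            pts = np.zeros((n, 3))
            pts[:, 0] = xs
            return center + pts
        raise ParameterError(f"unknown scaffold kind {self.kind!r}")

    def max_extent(self) -> float:
        if self.kind == "single_sphere":
            return self.radius
        return (self.n_beads - 1) / 2.0 * self.spacing


@dataclass
class SyntheticSpec:
    scaffold: Scaffold
    n_bulk_waters: int
    box: float | tuple[float, float, float]
    n_frames: int
    dt: float
    sites: list[PlantedSite] = field(default_factory=list)
    shell_profile: list[tuple[float, float]] | None = None
    n_shell_waters: int = 0
    shell_jitter: float = 0.05
    seed: int = 0
    bulk_mode: str = "iid"  # or "diffusive"
    diffusion_step: float = 1.0
    exclusion: float = 2.5
    site_pool_size: int = 4

    def box_lengths(self) -> np.ndarray:
        b = np.asarray(self.box, dtype=float)
        if b.ndim == 0:
            b = np.repeat(b, 3)
        return b

    def validate(self):
        if self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2")
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")
        box = self.box_lengths()
        if np.any(box <= 0):
            raise GeometryError("box lengths must be positive")
        # a bulk region >= 10 A from the scaffold must exist; the box
        # corners are the farthest points from a centred scaffold
        center = box / 2.0
        scaffold_xyz = self.scaffold.positions(center)
        corners = np.array([[i * box[0], j * box[1], k * box[2]]
                            for i in (0, 1) for j in (0, 1) for k in (0, 1)])
        dmin = np.min(np.linalg.norm(
            corners[:, None, :] - scaffold_xyz[None], axis=2))
        if dmin < 10.0:
            raise GeometryError(
                f"box too small: nearest corner is {dmin:.1f} A from the "
                f"scaffold; need >= 10 A of bulk")


@dataclass
class GroundTruth:
    sites: list[PlantedSite]
    bulk_number_density: float  # waters per A^3 of accessible volume
    accessible_volume: float
    shell_profile: list[tuple[float, float]] | None
    scaffold_positions: np.ndarray

    def to_dict(self) -> dict:
        return {
            "sites": [
                {
                    "position": list(map(float, s.position)),
                    "dwell_time_ps": s.dwell_time,
                    "occupancy": s.occupancy,
                    "capture_radius": s.capture_radius,
                }
                for s in self.sites
            ],
            "bulk_number_density_per_A3": self.bulk_number_density,
            "accessible_volume_A3": self.accessible_volume,
            "shell_profile": self.shell_profile,
        }

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + math.sqrt(5.0)) * i
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def sample_occupancy(rng: np.random.Generator, n_frames: int,
                     p_exit: float, p_entry: float) -> tuple[np.ndarray, list]:
    """Two-state Markov occupancy sequence.

    Returns ``(occupied, runs)`` where ``occupied`` is a boolean array of
    length ``n_frames`` and ``runs`` a list of ``(state, start, length)``
    tuples.  Run lengths are geometric with the corresponding switch
    probability; the initial state is drawn from the stationary distribution.
    """
    if p_exit < 0 or p_entry < 0:
        raise ParameterError("rates must be non-negative")
    denom = p_exit + p_entry
    stat_occ = 1.0 if denom == 0 else p_entry / denom
    state = bool(rng.random() < stat_occ)
    occupied = np.zeros(n_frames, dtype=bool)
    runs = []
    t = 0
    while t < n_frames:
        p = p_exit if state else p_entry
        length = n_frames - t if p <= 0 else int(rng.geometric(p))
        length = min(length, n_frames - t)
        runs.append((state, t, length))
        if state:
            occupied[t:t + length] = True
        t += length
        state = not state
    return occupied, runs


def ideal_survival(dwell_time: float, taus: Sequence[float]) -> np.ndarray:
    """Closed-form continuous-occupancy survival exp(-tau/dwell) of a
    memoryless exit process."""
    if dwell_time <= 0:
        raise ParameterError("dwell_time must be > 0")
    taus = np.asarray(taus, dtype=float)
    if np.any(taus < 0):
        raise ParameterError("lags must be non-negative")
    return np.exp(-taus / dwell_time)


def place_sites_on_sphere(center: np.ndarray, scaffold_radius: float,
                          surface_distances: Sequence[float],
                          phase: float = 0.0) -> np.ndarray:
    """Deterministic site positions radially outward from a spherical
    scaffold, one per requested surface distance, spread on a golden-spiral
    lattice (so sites are mutually well separated)."""
    n = len(surface_distances)
    dirs = _fibonacci_sphere(max(n, 4))[:n]
    if phase:
        c, s = math.cos(phase), math.sin(phase)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        dirs = dirs @ rot.T
    radii = scaffold_radius + np.asarray(surface_distances, dtype=float)
    return np.asarray(center) + dirs * radii[:, None]


def _truncated_positions(rng, n, radius, sigma):
    """n offsets within a ball: uniform if sigma is None, else truncated
    Gaussian."""
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 16)
        if sigma is None:
            pts = rng.uniform(-radius, radius, (m, 3))
        else:
            pts = rng.normal(0.0, sigma, (m, 3))
        keep = pts[np.sum(pts * pts, axis=1) <= radius * radius]
        take = min(len(keep), n - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

def generate_system(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """Generate a deterministic synthetic trajectory plus its ground truth.

    Water layout in the topology: ``n_bulk_waters`` bulk molecules, then
    ``site_pool_size`` dedicated waters per planted site (the occupant is
    re-drawn from the pool on every re-entry; parked pool members behave
    like bulk), then ``n_shell_waters`` shell-enrichment waters.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    box = spec.box_lengths()
    center = box / 2.0
    scaffold_xyz = spec.scaffold.positions(center)
    n_scaffold = len(scaffold_xyz)

    # exclusion predicate for the bulk region
    if spec.scaffold.kind == "single_sphere":
        r_excl = spec.scaffold.radius + spec.exclusion

        r_excl2 = r_excl * r_excl

        def excluded(pts):
            diff = pts - center
            return np.einsum("ij,ij->i", diff, diff) < r_excl2

        accessible = float(np.prod(box)) - 4.0 / 3.0 * math.pi * r_excl ** 3
    else:
        tree = cKDTree(scaffold_xyz)

        def excluded(pts):
            d, _ = tree.query(pts, k=1)
            return d < spec.exclusion

        # Monte-Carlo accessible volume (deterministic: own substream)
        vrng = np.random.default_rng(spec.seed + 777)
        probe = vrng.random((200_000, 3)) * box
        accessible = float(np.prod(box)) * float(np.mean(~excluded(probe)))

    def sample_bulk(r, n):
        # uniform in the accessible region: resample rejected points in place
        pts = r.random((n, 3)) * box
        bad = np.flatnonzero(excluded(pts))
        while bad.size:
            pts[bad] = r.random((bad.size, 3)) * box
            bad = bad[excluded(pts[bad])]
        return pts

    def sample_bulk_chunked(r, n_total):
        """Bulk positions for many frames at once, in memory-bounded
        chunks."""
        out = np.empty((n_total, 3))
        pos = 0
        while pos < n_total:
            take = min(2_000_000, n_total - pos)
            out[pos:pos + take] = sample_bulk(r, take)
            pos += take
        return out

    # --- per-site occupancy chains and occupant positions (precomputed) ---
    n_sites = len(spec.sites)
    pool = spec.site_pool_size
    site_occ = np.zeros((n_sites, spec.n_frames), dtype=bool)
    site_member = np.full((n_sites, spec.n_frames), -1, dtype=int)
    site_pos = [None] * n_sites
    for s, site in enumerate(spec.sites):
        p_exit = min(spec.dt / site.dwell_time, 1.0)
        if site.occupancy >= 1.0:
            occ = np.ones(spec.n_frames, dtype=bool)
            runs = [(True, 0, spec.n_frames)]
        else:
            p_entry = p_exit * site.occupancy / (1.0 - site.occupancy)
            occ, runs = sample_occupancy(rng, spec.n_frames, p_exit,
                                         min(p_entry, 1.0))
        site_occ[s] = occ
        for state, start, length in runs:
            if state:
                site_member[s, start:start + length] = rng.integers(pool)
        n_occ = int(occ.sum())
        offs = _truncated_positions(rng, n_occ, site.capture_radius,
                                    site.placement_sigma)
        site_pos[s] = np.asarray(site.position) + offs

    # --- shell-water distance distribution --------------------------------
    if spec.n_shell_waters > 0:
        if not spec.shell_profile:
            raise ParameterError("n_shell_waters > 0 requires shell_profile")
        sp_d = np.array([d for d, _ in spec.shell_profile], dtype=float)
        sp_w = np.array([w for _, w in spec.shell_profile], dtype=float)
        sp_w = sp_w / sp_w.sum()

    # --- topology ---------------------------------------------------------
    topology: list[AtomRecord] = []
    for i in range(n_scaffold):
        topology.append(AtomRecord(
            index=i, name="CA", element="C", is_hydrogen=False,
            residue_index=i, residue_name="GLY", segment="protein",
            mass=12.011))
    n_waters = spec.n_bulk_waters + n_sites * pool + spec.n_shell_waters
    for w in range(n_waters):
        topology.append(AtomRecord(
            index=n_scaffold + w, name="OW", element="O", is_hydrogen=False,
            residue_index=n_scaffold + w, residue_name="SOL",
            segment="water", mass=15.999))

    # --- frames (vectorized across time) ----------------------------------
    nf = spec.n_frames
    n_atoms = n_scaffold + n_waters
    coords = np.empty((nf, n_atoms, 3))

    # scaffold
    if spec.scaffold.jitter > 0:
        coords[:, :n_scaffold] = scaffold_xyz[None] + rng.normal(
            0.0, spec.scaffold.jitter, (nf, n_scaffold, 3))
    else:
        coords[:, :n_scaffold] = scaffold_xyz[None]

    # bulk waters
    if spec.n_bulk_waters:
        if spec.bulk_mode == "iid":
            coords[:, n_scaffold:n_scaffold + spec.n_bulk_waters] = \
                sample_bulk_chunked(rng, nf * spec.n_bulk_waters).reshape(
                    nf, spec.n_bulk_waters, 3)
        else:
            bulk_xyz = sample_bulk(rng, spec.n_bulk_waters)
            for f in range(nf):
                if f > 0:
                    step = rng.normal(0.0, spec.diffusion_step,
                                      (spec.n_bulk_waters, 3))
                    trial = np.mod(bulk_xyz + step, box)
                    bad = excluded(trial)
                    trial[bad] = bulk_xyz[bad]  # reject moves into scaffold
                    bulk_xyz = trial
                coords[f, n_scaffold:n_scaffold + spec.n_bulk_waters] = bulk_xyz

    # site pools: parked members look like bulk; the occupant (if any) is
    # overwritten with its in-site position
    base = n_scaffold + spec.n_bulk_waters
    for s in range(n_sites):
        block = sample_bulk_chunked(rng, nf * pool).reshape(nf, pool, 3)
        occ_f = np.flatnonzero(site_occ[s])
        block[occ_f, site_member[s, occ_f]] = site_pos[s]
        coords[:, base + s * pool: base + (s + 1) * pool] = block

    # shell enrichment
    if spec.n_shell_waters:
        sbase = base + n_sites * pool
        n_tot = nf * spec.n_shell_waters
        which = rng.choice(len(sp_d), size=n_tot, p=sp_w)
        dist = sp_d[which]
        if spec.shell_jitter > 0:
            dist = np.abs(dist + rng.normal(0.0, spec.shell_jitter, n_tot))
        if (spec.scaffold.kind == "single_sphere" and n_scaffold > 1
                and spec.scaffold.radius > 0):
            # anchor on the outer shell only (the first n_atoms positions)
            # and point radially outward, so the planted surface distance
            # is exact
            anchors = rng.integers(spec.scaffold.n_atoms, size=n_tot)
            apos = scaffold_xyz[anchors]
            u = apos - center
            u /= np.linalg.norm(u, axis=1, keepdims=True)
        else:
            anchors = rng.integers(n_scaffold, size=n_tot)
            apos = scaffold_xyz[anchors]
            u = rng.normal(size=(n_tot, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
        coords[:, sbase:sbase + spec.n_shell_waters] = \
            (apos + u * dist[:, None]).reshape(nf, spec.n_shell_waters, 3)

    frames = [Frame(coords[f], box.copy(), time=f * spec.dt)
              for f in range(nf)]

    traj = Trajectory(topology, frames, dt=spec.dt)
    truth = GroundTruth(
        sites=list(spec.sites),
        bulk_number_density=spec.n_bulk_waters / accessible,
        accessible_volume=accessible,
        shell_profile=spec.shell_profile,
        scaffold_positions=scaffold_xyz,
    )
    return traj, truth
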