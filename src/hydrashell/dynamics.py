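"""Dynamical hydration analysis.

Per-site occupancy traces (which water, if any, occupies a hydration site
at each frame), occupancy-autocorrelation survival curves in two flavours —
*continuous* (the same water holds the site at every intermediate frame)
and *intermittent* (the same water is back at lag tau, gaps allowed) —
single-exponential residence-time fits with a "superstructured" flag above
1 ns, shell-wise summaries that exclude superstructured sites, and
protein–water hydrogen-bond lifetimes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .errors import ParameterError, SelectionError, UndefinedCurveError
from .structure import HydrationSite
from .trajectory import Trajectory

logger = logging.getLogger(__name__)

SUPERSTRUCTURED_THRESHOLD_PS = 1000.0


@dataclass
class OccupancyTrace:
    site_id: int
    occupants: np.ndarray       # water-oxygen atom index per frame, -1 = none
    capture_radius: float
    dt: float

    @property
    def n_frames(self) -> int:
        return len(self.occupants)


@dataclass
class SurvivalCurve:
    taus: np.ndarray            # ps
    p: np.ndarray
    mode: str                   # continuous | intermittent
    n_origins: np.ndarray


@dataclass
class ResidenceTime:
    tau: float                  # ps
    fit_rss: float
    superstructured: bool
    reliable: bool = True
    site_id: int | None = None
    shell: str | None = None


@dataclass
class HBondLifetime:
    donor: int
    acceptor: int
    mean_lifetime: float        # ps
    n_events: int


# ---------------------------------------------------------------------------
# Occupancy traces
# ---------------------------------------------------------------------------

def build_occupancy_trace(traj: Trajectory, site: HydrationSite,
                          capture_radius: float = 1.4) -> OccupancyTrace:
    """Occupant of a site per frame: the nearest water oxygen within
    ``capture_radius`` (ties break to the lower atom index), else -1."""
    if capture_radius <= 0:
        raise ParameterError("capture_radius must be > 0")
    wox = traj.water_oxygen_indices()
    if wox.size == 0:
        raise SelectionError("no water oxygens")
    pos = np.asarray(site.position, dtype=float)
    # (n_frames, n_water) distance matrix, vectorized over frames
    w_xyz = traj.coords_array()[:, wox, :]
    d = np.linalg.norm(w_xyz - pos[None, None, :], axis=2)
    j = np.argmin(d, axis=1)    # argmin takes the first (lowest index) on ties
    dmin = d[np.arange(len(j)), j]
    occ = np.where(dmin <= capture_radius, wox[j], -1)
    return OccupancyTrace(site_id=site.id, occupants=occ,
                          capture_radius=capture_radius, dt=traj.dt)


# ---------------------------------------------------------------------------
# Survival function
# ---------------------------------------------------------------------------

def survival_function(trace: OccupancyTrace, mode: str = "continuous",
                      max_lag: float | None = None) -> SurvivalCurve:
    """Occupancy autocorrelation P(tau), normalized over time origins so
    P(0) = 1.

    Origins are frames where the site is occupied.  ``continuous``: the same
    occupant must hold the site through every frame of [t, t+tau];
    ``intermittent``: only the endpoints must match.  Origins whose t+tau
    falls past the end of the trajectory are dropped.
    """
    occ = trace.occupants
    n = len(occ)
    if n == 0:
        raise UndefinedCurveError("empty trace")
    occupied = occ >= 0
    if not occupied.any():
        raise UndefinedCurveError(f"site {trace.site_id} never occupied")
    if mode not in ("continuous", "intermittent"):
        raise ParameterError(f"unknown survival mode {mode!r}")
    if max_lag is None:
        max_lag = min(5000.0, (n - 1) * trace.dt / 5.0)
    n_lags = min(int(np.floor(max_lag / trace.dt)), n - 1)
    lags = np.arange(n_lags + 1)

    n_origins = np.empty(n_lags + 1, dtype=np.int64)
    p = np.empty(n_lags + 1)
    if mode == "continuous":
        # run[t]: number of future consecutive frames with the same occupant
        # (run[t] >= k  <=>  the occupant of t survives through t+k)
        same = (occ[1:] == occ[:-1]) & occupied[:-1]
        false_pos = np.append(np.flatnonzero(~same), n - 1)  # sentinel
        t_idx = np.arange(n - 1)
        next_false = false_pos[np.searchsorted(false_pos, t_idx, side="left")]
        run = np.zeros(n, dtype=np.int64)
        run[: n - 1] = next_false - t_idx

        rv = run[occupied]
        hist = np.bincount(np.minimum(rv, n_lags), minlength=n_lags + 1)
        surv_count = np.cumsum(hist[::-1])[::-1]       # # origins run >= k
        occ_cum = np.cumsum(occupied)
        # origins with t <= n-1-k
        n_origins[:] = [occ_cum[n - 1 - k] for k in lags]
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_origins > 0, surv_count / n_origins, np.nan)
    else:
        for k in lags:
            a = occ[: n - k]
            b = occ[k:]
            orig = a >= 0
            n_origins[k] = int(orig.sum())
            p[k] = (np.nan if n_origins[k] == 0
                    else float(np.mean(b[orig] == a[orig])))
    return SurvivalCurve(taus=lags * trace.dt, p=p, mode=mode,
                         n_origins=n_origins)


# ---------------------------------------------------------------------------
# Residence-time fit
# ---------------------------------------------------------------------------

def fit_residence_time(curve: SurvivalCurve, noise_floor: float = 0.01,
                       min_origins: int = 10,
                       free_amplitude: bool = False) -> ResidenceTime:
    """Least-squares single-exponential fit p(tau) = exp(-tau/tau_res).

    The amplitude is fixed at 1 (P(0) = 1 by construction) unless
    ``free_amplitude``; lags where p has fallen below ``noise_floor`` or
    that have fewer than ``min_origins`` origins are excluded.  A curve that
    has not decayed below 0.9 at the last usable lag is flagged unreliable
    (tau is then a lower bound).
    """
    mask = (np.isfinite(curve.p) & (curve.p >= noise_floor)
            & (curve.n_origins >= min_origins))
    taus = curve.taus[mask]
    ps = curve.p[mask]
    if taus.size < 5:
        raise ParameterError("need >= 5 usable lag points for the fit")

    # initial guess from the log-linear slope
    pos = ps > 0
    slope = np.polyfit(taus[pos], np.log(ps[pos]), 1)[0]
    tau0 = -1.0 / slope if slope < 0 else taus[-1]
    tau0 = float(np.clip(tau0, 1e-6, 1e9))

    if free_amplitude:
        def model(t, tau, a):
            return a * np.exp(-t / tau)
        p0 = [tau0, 1.0]
    else:
        def model(t, tau):
            return np.exp(-t / tau)
        p0 = [tau0]
    popt, _ = curve_fit(model, taus, ps, p0=p0, maxfev=10_000)
    tau = float(popt[0])
    rss = float(np.sum((model(taus, *popt) - ps) ** 2))
    reliable = bool(ps[-1] <= 0.9)
    if not reliable:
        logger.warning("survival curve barely decays (p=%.3f at last lag); "
                       "tau=%.1f ps is a lower bound", ps[-1], tau)
    return ResidenceTime(
        tau=tau, fit_rss=rss,
        superstructured=tau > SUPERSTRUCTURED_THRESHOLD_PS,
        reliable=reliable,
    )


def shell_residence_summary(times: Sequence[ResidenceTime],
                            shells: Sequence[str] | None = None
                            ) -> pd.DataFrame:
    """Per-shell residence summary excluding superstructured sites
    (tau > 1 ns) from the mean/sd; the exclusion count is reported."""
    if shells is None:
        shells = [t.shell for t in times]
    rows = []
    for shell in ("first", "second", "outer"):
        vals = [t.tau for t, s in zip(times, shells)
                if s == shell and not t.superstructured]
        n_excl = sum(1 for t, s in zip(times, shells)
                     if s == shell and t.superstructured)
        n = len(vals)
        rows.append({
            "shell": shell,
            "n": n,
            "n_excluded": n_excl,
            "mean_tau_ps": float(np.mean(vals)) if n else np.nan,
            "sd_tau_ps": float(np.std(vals, ddof=1)) if n > 1 else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hydrogen-bond lifetimes
# ---------------------------------------------------------------------------

@dataclass
class HBondCriteria:
    distance: float = 3.5       # donor–acceptor heavy-atom cutoff, angstrom
    angle: float = 150.0        # donor-H...acceptor angle, degrees


def _polar_partners(traj: Trajectory):
    """Protein polar heavy atoms with their bonded hydrogens (bond = same
    residue, within 1.25 A in the first frame)."""
    fr0 = traj.frames[0]
    donors: dict[int, list[int]] = {}
    polar = [a for a in traj.topology
             if a.segment == "protein" and a.element.upper() in ("N", "O")]
    hyds = [a for a in traj.topology
            if a.segment == "protein" and a.is_hydrogen]
    for p in polar:
        hs = [h.index for h in hyds
              if h.residue_index == p.residue_index
              and np.linalg.norm(fr0.coordinates[h.index]
                                 - fr0.coordinates[p.index]) <= 1.25]
        donors[p.index] = hs
    return polar, donors


def hbond_lifetimes(traj: Trajectory, criteria: HBondCriteria | None = None
                    ) -> tuple[list[HBondLifetime], float]:
    """Protein–water hydrogen-bond lifetimes.

    An H-bond exists in a frame when the donor–acceptor heavy-atom distance
    is <= ``criteria.distance`` and (when hydrogens are available) some
    donor-H...acceptor angle is >= ``criteria.angle``.  Continuous bonded
    runs of a (protein atom, water oxygen) pair are events; an event bonded
    in L consecutive frames lasts (L-1)*dt.  The overall mean weights every
    event equally.
    """
    if criteria is None:
        criteria = HBondCriteria()
    polar, donor_h = _polar_partners(traj)
    if not polar:
        raise SelectionError("no protein N/O atoms")
    wox = traj.water_oxygen_indices()
    if wox.size == 0:
        raise SelectionError("no water oxygens")
    have_h = any(donor_h.values())
    if not have_h:
        logger.warning("no protein hydrogens; H-bonds use the distance "
                       "criterion only")
    polar_idx = np.array([a.index for a in polar])

    bonded_frames: dict[tuple[int, int], list[int]] = {}
    for f, fr in enumerate(traj.frames):
        xyz = fr.coordinates
        wtree = cKDTree(xyz[wox])
        near = wtree.query_ball_point(xyz[polar_idx], criteria.distance)
        for pi, nb in zip(polar_idx, near):
            for wj in nb:
                wa = int(wox[wj])
                if have_h and donor_h[pi]:
                    ok = False
                    for h in donor_h[pi]:
                        v1 = xyz[h] - xyz[pi]
                        v2 = xyz[wa] - xyz[h]
                        c = float(np.dot(v1, v2)
                                  / (np.linalg.norm(v1) * np.linalg.norm(v2)))
                        # angle donor-H...acceptor: 180 deg when collinear
                        ang = 180.0 - np.degrees(np.arccos(np.clip(c, -1, 1)))
                        if ang >= criteria.angle:
                            ok = True
                            break
                    if not ok:
                        continue
                bonded_frames.setdefault((int(pi), wa), []).append(f)

    results: list[HBondLifetime] = []
    all_events: list[float] = []
    for (pi, wa), frames_list in sorted(bonded_frames.items()):
        arr = np.asarray(frames_list)
        breaks = np.where(np.diff(arr) > 1)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(arr) - 1]])
        durations = (arr[ends] - arr[starts]) * traj.dt
        all_events.extend(durations.tolist())
        results.append(HBondLifetime(
            donor=pi, acceptor=wa,
            mean_lifetime=float(np.mean(durations)),
            n_events=len(durations),
        ))
    overall = float(np.mean(all_events)) if all_events else 0.0
    return results, overall
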