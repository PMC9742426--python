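"""Pipeline orchestration: superpose -> density grid -> G(r) -> hydration
sites -> shells -> residence times -> H-bonds -> protein metrics, collected
into a machine-readable, deterministic report."""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SCHEMA_VERSION, AnalysisConfig
from .dynamics import (
    HBondCriteria,
    build_occupancy_trace,
    fit_residence_time,
    hbond_lifetimes,
    shell_residence_summary,
    survival_function,
)
from .errors import (
    EmptyInputError,
    HydrashellError,
    SchemaError,
    UndefinedCurveError,
)
from .protein import (
    backbone_nh_pairs,
    compute_order_parameters,
    compute_rg,
    compute_rmsd_series,
    compute_rmsf,
    compute_sasa,
)
from .structure import (
    classify_shells,
    compute_density_grid,
    compute_surface_rdf,
    detect_hydration_sites,
    residue_water_contacts,
)
from .trajectory import Trajectory, superpose_frames, wrap_trajectory

logger = logging.getLogger(__name__)


@dataclass
class Report:
    data: dict

    def to_json(self) -> str:
        return json.dumps(self.data, indent=1, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Report":
        return cls(json.loads(Path(path).read_text()))


class _StageTimer:
    def __init__(self):
        self.timings: dict[str, float] = {}

    def run(self, name, fn, *args, **kwargs):
        t0 = _time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except HydrashellError as exc:
            raise type(exc)(
                f"stage '{name}' failed: {exc} "
                f"(check the corresponding config parameters)") from exc
        self.timings[name] = round(_time.perf_counter() - t0, 3)
        logger.info("stage %s: %.2fs", name, self.timings[name])
        return out


def _round(x, nd=6):
    if isinstance(x, float):
        return round(x, nd)
    return x


def run_analysis(config: AnalysisConfig,
                 traj: Trajectory | None = None,
                 out_dir: str | Path | None = None) -> Report:
    """Execute the full hydration analysis and return the report.

    ``traj`` may be passed directly (e.g. a synthetic system); otherwise
    the configured topology/trajectory files are read.  When ``out_dir``
    is given, intermediate products (density map, G(r), site tables,
    survival curves) are written there as plain text.
    """
    timer = _StageTimer()
    warnings_log: list[str] = []

    if traj is None:
        from .io import read_trajectory
        traj = timer.run("read", read_trajectory, config.topology,
                         config.trajectory, dt=config.dt)

    calphas = traj.calpha_indices()
    fit_sel = calphas if calphas.size >= 3 else traj.protein_heavy_indices()
    reference = traj.frames[0]
    if fit_sel.size >= 3:
        traj = timer.run("superpose", superpose_frames, traj, fit_sel,
                         reference)
    else:
        warnings_log.append("fewer than 3 fit atoms: superposition skipped")
    traj = timer.run("wrap", wrap_trajectory, traj)
    heavy = traj.protein_heavy_indices()

    has_waters = traj.water_oxygen_indices().size > 0
    grid = None
    if has_waters:
        grid = timer.run("density", compute_density_grid, traj,
                         step=config.grid_step, padding=config.grid_padding,
                         bulk_shell=config.bulk_shell)
    else:
        warnings_log.append("no water oxygens: hydration stages skipped")

    from .structure import SurfaceRDF
    if has_waters:
        rdf = timer.run("rdf", compute_surface_rdf, traj,
                        diameter=config.cylinder_diameter,
                        angle_step=config.angle_step,
                        bin_width=config.rdf_bin_width,
                        r_max=config.rdf_r_max,
                        bulk_range=config.bulk_shell, wrap=False)
    else:
        rdf = SurfaceRDF(bin_centers=np.array([]), g=np.array([]),
                         n_samples=np.array([], dtype=int), empty=True)
    if rdf.empty:
        warnings_log.append("G(r) empty: no waters found in any cylinder")
    if rdf.first_minimum is None:
        warnings_log.append("G(r) minima not found; fallback shell "
                            "boundaries used")

    sites = []
    if grid is not None:
        sites = timer.run("sites", detect_hydration_sites, grid,
                          traj.frames[0], heavy,
                          min_density=config.min_density,
                          radius=config.site_radius, rdf=rdf)

    residences = []
    curves = {}
    for site in sites:
        trace = build_occupancy_trace(traj, site,
                                      capture_radius=config.capture_radius)
        try:
            curve = survival_function(trace, mode=config.survival_mode,
                                      max_lag=config.max_lag)
            rt = fit_residence_time(curve)
        except (UndefinedCurveError, HydrashellError) as exc:
            warnings_log.append(f"site {site.id}: residence fit skipped "
                                f"({exc})")
            continue
        rt.site_id = site.id
        rt.shell = site.shell
        if not rt.reliable:
            warnings_log.append(f"site {site.id}: survival curve barely "
                                f"decays; tau is a lower bound")
        residences.append(rt)
        curves[site.id] = curve
    summary = shell_residence_summary(residences)

    if has_waters:
        contacts, contacts_mean = timer.run(
            "contacts", residue_water_contacts, traj,
            cutoff=config.contact_cutoff, wrap=False)
    else:
        contacts, contacts_mean = pd.DataFrame(
            columns=["residue_index", "residue_name", "mean_waters"]), 0.0

    hbond_mean = None
    n_hbond_pairs = 0
    if config.compute_hbonds and has_waters:
        try:
            hb, hbond_mean = timer.run(
                "hbonds", hbond_lifetimes, traj,
                HBondCriteria(config.hbond_distance, config.hbond_angle))
            n_hbond_pairs = len(hb)
        except HydrashellError as exc:
            warnings_log.append(f"H-bond analysis skipped: {exc}")

    rmsf = timer.run("rmsf", compute_rmsf, traj)
    rg = timer.run("rg", compute_rg, traj)
    rmsd = (timer.run("rmsd", compute_rmsd_series, traj, reference, fit_sel)
            if fit_sel.size >= 3 else None)
    s2 = None
    nh = backbone_nh_pairs(traj)
    if nh:
        s2 = compute_order_parameters(traj, nh)
    sasa_total = None
    if config.compute_sasa:
        sasa_total, _ = timer.run("sasa", compute_sasa, traj.frames[0],
                                  traj.topology, probe=config.sasa_probe,
                                  n_points=config.sasa_points)

    shell_counts = {sh: sum(1 for s in sites if s.shell == sh)
                    for sh in ("first", "second", "outer")}

    data = {
        "schema_version": SCHEMA_VERSION,
        "provenance": {
            "hydrashell_version": __version__,
            "config": config.to_dict(),
            "config_hash": config.hash(),
            "n_frames": traj.n_frames,
            "n_atoms": traj.n_atoms,
            "dt_ps": traj.dt,
            "warnings": warnings_log,
        },
        "grid": {
            "bulk_density_per_A3_frame": _round(grid.bulk_density, 8)
            if grid is not None else None,
            "step_A": grid.step if grid is not None else None,
            "shape": list(grid.shape) if grid is not None else None,
        },
        "rdf": {
            "empty": rdf.empty,
            "peaks": [[_round(p), _round(h)] for p, h in rdf.peaks],
            "first_minimum_A": _round(rdf.first_minimum)
            if rdf.first_minimum is not None else None,
            "second_minimum_A": _round(rdf.second_minimum)
            if rdf.second_minimum is not None else None,
        },
        "sites": {
            "counts_by_shell": shell_counts,
            "table": [
                {"id": s.id,
                 "position": [_round(float(v), 3) for v in s.position],
                 "peak_density": _round(s.peak_density),
                 "surface_distance_A": _round(s.surface_distance),
                 "shell": s.shell}
                for s in sites
            ],
        },
        "residence": {
            "per_site": [
                {"site_id": r.site_id, "shell": r.shell,
                 "tau_ps": _round(r.tau), "fit_rss": _round(r.fit_rss),
                 "superstructured": r.superstructured,
                 "reliable": r.reliable}
                for r in residences
            ],
            "shell_summary": json.loads(
                summary.to_json(orient="records")),
        },
        "hydration_contacts": {
            "overall_mean_waters_per_residue": _round(contacts_mean),
            "per_residue": json.loads(contacts.to_json(orient="records")),
        },
        "hbonds": {
            "overall_mean_lifetime_ps": _round(hbond_mean)
            if hbond_mean is not None else None,
            "n_pairs": n_hbond_pairs,
        },
        "protein_metrics": {
            "rmsf_mean_A": _round(float(rmsf.mean())),
            "rg_mean_A": _round(float(rg.mean())),
            "rmsd_final_A": _round(float(rmsd.iloc[-1]))
            if rmsd is not None else None,
            "sasa_nm2": _round(sasa_total) if sasa_total is not None else None,
            "s2_mean": _round(float(s2.mean())) if s2 is not None else None,
        },
    }
    report = Report(data)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from .exporters import (rdf_to_csv, sites_to_pdb, sites_to_table,
                                survival_to_csv, write_opendx)
        report.save(out_dir / "report.json")
        if grid is not None:
            write_opendx(grid, out_dir / "density.dx")
        if not rdf.empty:
            rdf_to_csv(rdf, out_dir / "gr.csv")
        sites_to_pdb(sites, out_dir / "sites.pdb")
        sites_to_table(sites).to_csv(out_dir / "sites.csv", index=False)
        for sid, curve in curves.items():
            survival_to_csv(curve, out_dir / f"survival_site{sid}.csv")
        contacts.to_csv(out_dir / "residue_contacts.csv", index=False)
        summary.to_csv(out_dir / "residence_summary.csv", index=False)
    return report


# ---------------------------------------------------------------------------
# Comparison
# ---------------------------------------------------------------------------

_COMPARE_KEYS = [
    ("first-shell MDHS", ("sites", "counts_by_shell", "first")),
    ("second-shell MDHS", ("sites", "counts_by_shell", "second")),
    ("mean waters per residue",
     ("hydration_contacts", "overall_mean_waters_per_residue")),
    ("H-bond lifetime (ps)", ("hbonds", "overall_mean_lifetime_ps")),
    ("Rg (A)", ("protein_metrics", "rg_mean_A")),
    ("SASA (nm^2)", ("protein_metrics", "sasa_nm2")),
]


def _dig(d, keys):
    for k in keys:
        if d is None:
            return None
        d = d.get(k)
    return d


def compare_systems(report_a: Report, report_b: Report) -> pd.DataFrame:
    """Side-by-side comparison of headline scalars of two reports."""
    va = report_a.data.get("schema_version")
    vb = report_b.data.get("schema_version")
    if va != vb or va != SCHEMA_VERSION:
        raise SchemaError(f"schema version mismatch: {va} vs {vb} "
                          f"(expected {SCHEMA_VERSION})")
    rows = []
    for label, keys in _COMPARE_KEYS:
        a = _dig(report_a.data, keys)
        b = _dig(report_b.data, keys)
        diff = (a - b) if (a is not None and b is not None) else None
        ratio = (a / b) if (a is not None and b not in (None, 0)) else None
        rows.append({"metric": label, "a": a, "b": b,
                     "difference": diff, "ratio": ratio})

    sa = {r["shell"]: r for r in report_a.data["residence"]["shell_summary"]}
    sb = {r["shell"]: r for r in report_b.data["residence"]["shell_summary"]}
    for shell in ("first", "second"):
        a = sa.get(shell, {}).get("mean_tau_ps")
        b = sb.get(shell, {}).get("mean_tau_ps")
        diff = (a - b) if (a is not None and b is not None) else None
        ratio = (a / b) if (a is not None and b not in (None, 0)) else None
        rows.append({"metric": f"{shell}-shell mean tau (ps)",
                     "a": a, "b": b, "difference": diff, "ratio": ratio})
    return pd.DataFrame(rows)
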