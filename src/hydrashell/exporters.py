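"""Plain-text exports: OpenDX density maps, CSV tables, and MDHS
pseudo-atom PDBs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .structure import DensityGrid, HydrationSite, SurfaceRDF


def write_opendx(grid: DensityGrid, path: str | Path) -> None:
    """OpenDX scalar field of the normalized density (node centres)."""
    nx, ny, nz = grid.shape
    o = grid.origin + grid.step / 2.0
    with open(Path(path), "w") as fh:
        fh.write("# hydrashell normalized water density (bulk units)\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {o[0]:.4f} {o[1]:.4f} {o[2]:.4f}\n")
        fh.write(f"delta {grid.step:.4f} 0 0\n")
        fh.write(f"delta 0 {grid.step:.4f} 0\n")
        fh.write(f"delta 0 0 {grid.step:.4f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        n = nx * ny * nz
        fh.write(f"object 3 class array type double rank 0 items {n} "
                 f"data follows\n")
        flat = grid.values.ravel()
        for i in range(0, n, 3):
            fh.write(" ".join(f"{v:.6g}" for v in flat[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


def grid_to_csv(grid: DensityGrid, path: str | Path,
                min_value: float = 0.0) -> None:
    """CSV of node centres and normalized values (optionally thresholded)."""
    nx, ny, nz = grid.shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    flat = grid.values.ravel()
    keep = flat >= min_value
    centers = grid.origin + (np.column_stack(
        [ii.ravel(), jj.ravel(), kk.ravel()]) + 0.5) * grid.step
    pd.DataFrame({
        "x": centers[keep, 0], "y": centers[keep, 1], "z": centers[keep, 2],
        "density": flat[keep],
    }).to_csv(path, index=False)


def sites_to_pdb(sites: Sequence[HydrationSite], path: str | Path) -> None:
    """One HETATM pseudo-atom per hydration site; B-factor carries the peak
    density (bulk units)."""
    with open(Path(path), "w") as fh:
        for s in sites:
            x, y, z = s.position
            fh.write(
                f"HETATM{(s.id + 1) % 100000:5d}  OW  HYD H{(s.id + 1) % 10000:4d}"
                f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}"
                f"{min(s.peak_density, 999.99):6.2f}           O\n"
            )
        fh.write("END\n")


def sites_to_table(sites: Sequence[HydrationSite]) -> pd.DataFrame:
    return pd.DataFrame([{
        "id": s.id,
        "x": s.position[0], "y": s.position[1], "z": s.position[2],
        "peak_density": s.peak_density,
        "surface_distance": s.surface_distance,
        "shell": s.shell,
    } for s in sites])


def sites_to_json(sites: Sequence[HydrationSite], path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        json.dump(sites_to_table(sites).to_dict(orient="records"), fh,
                  indent=1, sort_keys=True)


def rdf_to_csv(rdf: SurfaceRDF, path: str | Path) -> None:
    pd.DataFrame({
        "bin_center": rdf.bin_centers,
        "g": rdf.g,
        "n_samples": rdf.n_samples,
    }).to_csv(path, index=False)


def survival_to_csv(curve, path: str | Path) -> None:
    pd.DataFrame({
        "tau_ps": curve.taus,
        "p": curve.p,
        "n_origins": curve.n_origins,
    }).to_csv(path, index=False)
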