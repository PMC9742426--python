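"""Flat-bottom harmonic chemical-shift restraint energetics.

The restraint penalizes calculated backbone chemical shifts that deviate
from experiment by more than the experimental uncertainty:

    V = K * sum_i sum_j max(0, |d_exp - d_calc| - eps)^2

over the six backbone atom types (CA, CB, C, N, HN, HA).  The deviation
shrinkage makes the potential C^1 at the flat-bottom edge, so the
restraining force is zero (and continuous) inside the tolerance.  The
weight ramps linearly from zero to K_max over the equilibration window and
stays constant afterwards.

Energy/gradient evaluation only — no shift prediction, no MD coupling.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

logger = logging.getLogger(__name__)

ATOM_TYPES = ("CA", "CB", "C", "N", "HN", "HA")
_ATOM_ALIASES = {"H": "HN", "C'": "C", "CO": "C"}

DEFAULT_K_MAX = 300.0           # kJ/mol/ppm^2
DEFAULT_RAMP_DURATION = 10_000.0  # ps


@dataclass
class RestraintConfig:
    K_max: float = DEFAULT_K_MAX
    ramp_duration: float = DEFAULT_RAMP_DURATION
    ramp_shape: str = "linear"  # or "smoothstep"

    def __post_init__(self):
        if self.K_max < 0:
            raise ParameterError("K_max must be >= 0")
        if self.ramp_duration <= 0:
            raise ParameterError("ramp_duration must be > 0")
        if self.ramp_shape not in ("linear", "smoothstep"):
            raise ParameterError("ramp_shape must be linear or smoothstep")


class ShiftTable:
    """Experimental vs calculated shifts for the six backbone atom types.

    Backed by a DataFrame with columns ``residue``, ``atom_type``,
    ``delta_exp``, ``epsilon``, ``delta_calc``.  Rows without an
    experimental shift are unrestrained and skipped by the energy.
    """

    def __init__(self, df: pd.DataFrame,
                 default_epsilon: dict[str, float] | None = None):
        required = {"residue", "atom_type", "delta_exp"}
        if not required.issubset(df.columns):
            raise FormatError(f"shift table needs columns {sorted(required)}")
        df = df.copy()
        df["atom_type"] = (df["atom_type"].astype(str).str.strip()
                           .replace(_ATOM_ALIASES))
        bad = set(df["atom_type"]) - set(ATOM_TYPES)
        if bad:
            raise FormatError(f"unknown atom type(s): {sorted(bad)}; "
                              f"allowed: {ATOM_TYPES}")
        if "epsilon" not in df.columns:
            df["epsilon"] = np.nan
        if "delta_calc" not in df.columns:
            df["delta_calc"] = np.nan
        if default_epsilon:
            for at, eps in default_epsilon.items():
                fill = df["atom_type"].eq(at) & df["epsilon"].isna()
                df.loc[fill, "epsilon"] = eps
        n_default = int(df["epsilon"].isna().sum())
        if n_default:
            logger.info("%d shifts without uncertainty: eps defaults to 0 "
                        "(pure harmonic)", n_default)
        df["epsilon"] = df["epsilon"].fillna(0.0)
        if (df["epsilon"] < 0).any():
            raise ParameterError("epsilon must be >= 0")
        self.df = df.reset_index(drop=True)

    @property
    def n_residues(self) -> int:
        return int(self.df["residue"].nunique())

    def restrained(self) -> pd.DataFrame:
        return self.df[self.df["delta_exp"].notna()]


def restraint_energy(table: ShiftTable, K: float
                     ) -> tuple[float, pd.DataFrame]:
    """Total flat-bottom restraint energy (kJ/mol) and the per-shift
    breakdown.  Each restrained shift contributes K * max(0, |d|-eps)^2
    with d = delta_exp - delta_calc."""
    if K < 0:
        raise ParameterError("K must be >= 0")
    rows = table.restrained().copy()
    if rows["delta_calc"].isna().any():
        bad = rows[rows["delta_calc"].isna()]
        raise ParameterError(
            f"{len(bad)} restrained shift(s) lack delta_calc "
            f"(first: residue {bad.iloc[0]['residue']} "
            f"{bad.iloc[0]['atom_type']})")
    d = rows["delta_exp"].to_numpy() - rows["delta_calc"].to_numpy()
    excess = np.maximum(0.0, np.abs(d) - rows["epsilon"].to_numpy())
    rows["energy"] = K * excess ** 2
    return float(rows["energy"].sum()), rows


def restraint_gradient(table: ShiftTable, K: float) -> pd.DataFrame:
    """dV/d(delta_calc) per restrained shift (kJ/mol/ppm):
    -2*K*excess*sign(delta_exp - delta_calc) outside the flat bottom, zero
    inside (continuous at the edge)."""
    if K < 0:
        raise ParameterError("K must be >= 0")
    _, rows = restraint_energy(table, K)
    d = rows["delta_exp"].to_numpy() - rows["delta_calc"].to_numpy()
    excess = np.maximum(0.0, np.abs(d) - rows["epsilon"].to_numpy())
    rows["gradient"] = -2.0 * K * excess * np.sign(d)
    return rows


def ramp_schedule(t: float, config: RestraintConfig) -> float:
    """Restraint weight at time t (ps): ramp from 0 to K_max over
    ``ramp_duration``, constant afterwards.  Shape is linear by default;
    ``smoothstep`` gives a C^1 ramp with the same endpoints."""
    if t < 0:
        raise ParameterError("t must be >= 0")
    x = min(1.0, t / config.ramp_duration)
    if config.ramp_shape == "smoothstep":
        x = x * x * (3.0 - 2.0 * x)
    return config.K_max * x


def force_incidence_ratio(restraint_forces: np.ndarray,
                          total_forces: np.ndarray) -> float:
    """Diagnostic: mean |restraint force| / mean |total force| over backbone
    atoms, given externally supplied magnitudes."""
    rf = np.abs(np.asarray(restraint_forces, float))
    tf = np.abs(np.asarray(total_forces, float))
    if tf.size == 0 or np.mean(tf) == 0:
        raise ParameterError("total forces are empty or all zero")
    return float(np.mean(rf) / np.mean(tf))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_shift_csv(path: str | Path, **kwargs) -> ShiftTable:
    """CSV with columns residue, atom_type, delta_exp[, epsilon, delta_calc]."""
    return ShiftTable(pd.read_csv(path), **kwargs)


def read_nmrstar_shifts(path: str | Path, **kwargs) -> ShiftTable:
    """Minimal NMR-STAR reader: extracts the ``_Atom_chem_shift`` loop
    (Seq_ID / Atom_ID / Val / Val_err tags) as experimental shifts."""
    text = Path(path).read_text()
    lines = text.splitlines()
    tags: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    collecting = False
    for line in lines:
        s = line.strip()
        if s == "loop_":
            in_loop, collecting, tags = True, False, []
            continue
        if in_loop and s.startswith("_"):
            tags.append(s.split(".")[-1] if "." in s else s.lstrip("_"))
            continue
        if in_loop and s and not s.startswith("_"):
            if not collecting:
                if not any(t in ("Val", "Chem_shift_value") for t in tags):
                    in_loop = False
                    continue
                collecting = True
            if s in ("stop_",):
                in_loop = collecting = False
                continue
            rows.append(s.split())
        elif in_loop and s == "stop_":
            in_loop = collecting = False
    if not rows or not tags:
        raise FormatError(f"no chemical-shift loop found in {path}")

    def col(*names):
        for n in names:
            if n in tags:
                return tags.index(n)
        return None

    i_seq = col("Seq_ID", "Residue_seq_code")
    i_atom = col("Atom_ID", "Atom_name")
    i_val = col("Val", "Chem_shift_value")
    i_err = col("Val_err", "Chem_shift_value_error")
    if i_seq is None or i_atom is None or i_val is None:
        raise FormatError("chemical-shift loop lacks Seq_ID/Atom_ID/Val tags")

    recs = []
    for r in rows:
        if len(r) <= max(i_seq, i_atom, i_val):
            continue
        atom = r[i_atom]
        atom = _ATOM_ALIASES.get(atom, atom)
        if atom not in ATOM_TYPES:
            continue
        err = np.nan
        if i_err is not None and len(r) > i_err and r[i_err] not in (".", "?"):
            err = float(r[i_err])
        recs.append({"residue": int(r[i_seq]), "atom_type": atom,
                     "delta_exp": float(r[i_val]), "epsilon": err})
    if not recs:
        raise FormatError(f"no backbone shifts parsed from {path}")
    return ShiftTable(pd.DataFrame(recs), **kwargs)
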