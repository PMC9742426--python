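"""Shared test utilities: tiny trajectory builders and independent oracles
(quaternion superposition, 27-image wrapping, brute-force distances)."""

from __future__ import annotations

import numpy as np

from hydrashell.trajectory import AtomRecord, Frame, Trajectory


def protein_atom(index, residue_index=0, name="CA", element="C",
                 residue_name="GLY", mass=12.011):
    return AtomRecord(index=index, name=name, element=element,
                      is_hydrogen=element.upper() == "H",
                      residue_index=residue_index, residue_name=residue_name,
                      segment="protein", mass=mass)


def water_atom(index, residue_index, name="OW", element="O", mass=15.999):
    return AtomRecord(index=index, name=name, element=element,
                      is_hydrogen=element.upper() == "H",
                      residue_index=residue_index, residue_name="SOL",
                      segment="water", mass=mass)


def make_trajectory(coords_per_frame, topology, box=50.0, dt=2.0):
    """Trajectory from a list of (n_atoms, 3) arrays."""
    box = np.atleast_1d(np.asarray(box, float))
    if box.size == 1:
        box = np.repeat(box, 3)
    frames = [Frame(np.asarray(c, float), box.copy(), time=i * dt)
              for i, c in enumerate(coords_per_frame)]
    return Trajectory(topology, frames, dt=dt)


def static_trajectory(coords, topology, n_frames=3, box=50.0, dt=2.0):
    return make_trajectory([np.array(coords, float)] * n_frames, topology,
                           box=box, dt=dt)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def quaternion_superpose(mobile, reference):
    """Horn's closed-form quaternion superposition: returns the transformed
    mobile coordinates and the RMSD.  Independent of the Kabsch/SVD path."""
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    P = mobile - cm
    Q = reference - cr
    # correlation matrix and Davenport K-matrix
    S = P.T @ Q
    K = np.empty((4, 4))
    K[0, 0] = S[0, 0] + S[1, 1] + S[2, 2]
    K[0, 1] = K[1, 0] = S[1, 2] - S[2, 1]
    K[0, 2] = K[2, 0] = S[2, 0] - S[0, 2]
    K[0, 3] = K[3, 0] = S[0, 1] - S[1, 0]
    K[1, 1] = S[0, 0] - S[1, 1] - S[2, 2]
    K[1, 2] = K[2, 1] = S[0, 1] + S[1, 0]
    K[1, 3] = K[3, 1] = S[0, 2] + S[2, 0]
    K[2, 2] = -S[0, 0] + S[1, 1] - S[2, 2]
    K[2, 3] = K[3, 2] = S[1, 2] + S[2, 1]
    K[3, 3] = -S[0, 0] - S[1, 1] + S[2, 2]
    w, v = np.linalg.eigh(K)
    q = v[:, np.argmax(w)]  # unit quaternion (w, x, y, z)
    a, b, c, d = q
    R = np.array([
        [a * a + b * b - c * c - d * d, 2 * (b * c - a * d), 2 * (b * d + a * c)],
        [2 * (b * c + a * d), a * a - b * b + c * c - d * d, 2 * (c * d - a * b)],
        [2 * (b * d - a * c), 2 * (c * d + a * b), a * a - b * b - c * c + d * d],
    ])
    moved = P @ R.T + cr
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return moved, rmsd


def brute_force_min_image(point, center, box):
    """Minimum-image position of ``point`` relative to ``center`` by
    enumerating all 27 periodic images."""
    best = None
    best_d = np.inf
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                img = point + np.array([dx, dy, dz]) * box
                d = np.linalg.norm(img - center)
                if d < best_d:
                    best_d = d
                    best = img
    return best, best_d


def rotation_matrix(axis, angle):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = np.cos(angle / 2.0)
    b, c, d = -axis * np.sin(angle / 2.0)
    return np.array([
        [a * a + b * b - c * c - d * d, 2 * (b * c + a * d), 2 * (b * d - a * c)],
        [2 * (b * c - a * d), a * a + c * c - b * b - d * d, 2 * (c * d + a * b)],
        [2 * (b * d + a * c), 2 * (c * d - a * b), a * a + d * d - b * b - c * c],
    ])
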