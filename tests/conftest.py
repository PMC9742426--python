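import numpy as np
import pytest

from hydrashell.synthetic import (
    PlantedSite,
    Scaffold,
    SyntheticSpec,
    generate_system,
    place_sites_on_sphere,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_bulk_system():
    """A modest bulk-only system shared by several structural tests."""
    spec = SyntheticSpec(
        scaffold=Scaffold(kind="single_sphere", radius=6.0, n_atoms=120),
        n_bulk_waters=1500, box=36.0, n_frames=150, dt=2.0, seed=11,
    )
    return generate_system(spec)


def recovery_spec(seed, with_decoys=True, n_frames=4700):
    """Site-recovery system: a radius-4 sphere scaffold, realistic bulk
    density (~0.068 / A^3 so grid nodes collect ~40 counts), 5 strong
    planted sites and optionally 2 sub-threshold decoys.

    True normalized peak density: occupancy * 0.21 / (step^3 * rho_bulk)
    (0.21 = Gaussian sigma=0.3 mass in the peak node), i.e. ~12x bulk for
    occupancy 0.5 and ~1.2x bulk for the 0.049 decoys.
    """
    box = 30.0
    center = np.array([box / 2.0] * 3)
    distances = [1.7, 1.8, 1.9, 2.0, 2.1, 1.85, 1.95]
    occupancies = [0.5] * 5 + [0.049] * 2
    # decoys get a short dwell so their realised occupancy (hence peak
    # density) concentrates tightly below the 2x threshold
    dwells = [100.0] * 5 + [10.0] * 2
    if not with_decoys:
        distances, occupancies, dwells = (distances[:5], occupancies[:5],
                                          dwells[:5])
    positions = place_sites_on_sphere(center, 4.0, distances)
    sites = [
        PlantedSite(position=tuple(p), dwell_time=dw, occupancy=o,
                    capture_radius=0.8, placement_sigma=0.3)
        for p, o, dw in zip(positions, occupancies, dwells)
    ]
    spec = SyntheticSpec(
        scaffold=Scaffold(kind="single_sphere", radius=4.0, n_atoms=80),
        n_bulk_waters=1770, box=box, n_frames=n_frames, dt=2.0,
        sites=sites, seed=seed,
    )
    return spec, positions[:5]


def residence_spec(seed, dwell_times=(20.0, 80.0, 300.0, 2000.0),
                   n_frames=50_000, dt=2.0):
    """Residence-time recovery system: sparse bulk so occupancy traces are
    clean, sites well separated on a radius-6 shell around a point
    scaffold."""
    box = 36.0
    center = np.array([box / 2.0] * 3)
    positions = place_sites_on_sphere(center, 6.0,
                                      [0.0] * len(dwell_times))
    # long-dwell (superstructured) sites get higher occupancy so enough
    # dwell events fit into the trajectory for a stable tau estimate
    sites = [
        PlantedSite(position=tuple(p), dwell_time=d,
                    occupancy=0.85 if d > 1000.0 else 0.6,
                    capture_radius=0.8, placement_sigma=0.3)
        for p, d in zip(positions, dwell_times)
    ]
    spec = SyntheticSpec(
        scaffold=Scaffold(kind="single_sphere", radius=0.0, n_atoms=1),
        n_bulk_waters=30, box=box, n_frames=n_frames, dt=dt,
        sites=sites, seed=seed,
    )
    return spec, positions
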