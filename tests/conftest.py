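"""Shared fixtures: synthetic clouds and an equilibrated LJ bead fluid."""

import numpy as np
import pytest

from cgbeads.gmm import ClusterSummary
from cgbeads.potential import PotentialSpec
from cgbeads.sampler import GibbsConfig, SamplerState, hmc_update
from cgbeads.synthetic import BlobSpec, make_blob_cloud


@pytest.fixture(scope="session")
def blob_cloud():
    """Well-separated 5-blob recovery fixture (spacing 10 Å, sd 1 Å)."""
    cloud, centers, sd = make_blob_cloud(BlobSpec(5, 10.0, 1.0, 200, seed=0))
    return cloud, centers, sd


def simulate_lj_fluid(
    n_beads=64,
    lambdas=(-4.0, 4.0),
    container_s=np.sqrt(10.0),
    n_sweeps=12000,
    burn_in=1500,
    thin=4,
    seed=42,
):
    """Equilibrium samples of K beads from exp{-<lambda, f>} in a weak
    harmonic container (kappa = 1/container_s^2), generated with the HMC
    kernel: the container enters as a data term with one phantom point of
    unit weight per bead at the origin.

    Returns (frames, spec). The container's bias on the configurational-
    temperature identity is O(kappa r^2) ~ 1%, negligible against the 20%
    recovery tolerance.
    """
    lam = np.asarray(lambdas, dtype=float)
    spec = PotentialSpec((-6, -12), lam.copy())
    side = int(np.ceil(n_beads ** (1 / 3)))
    g = np.arange(side) * 1.2
    X = np.stack(np.meshgrid(g, g, g, indexing="ij"), -1).reshape(-1, 3)[:n_beads]
    X = X - X.mean(axis=0)
    summary = ClusterSummary(
        np.ones(n_beads), np.zeros((n_beads, 3)), np.zeros(n_beads)
    )
    config = GibbsConfig(
        n_beads=n_beads,
        n_sweeps=n_sweeps,
        burn_in=burn_in,
        hmc_leapfrog_steps=10,
        hmc_target_acceptance=0.85,
        seed=seed,
    )
    state = SamplerState(X.copy(), None, container_s, lam.copy(), 0, 0.02)
    rng = np.random.default_rng(seed)
    frames = []
    for it in range(n_sweeps):
        state.iteration = it
        state.X, _ = hmc_update(state, summary, spec, config, rng)
        if it >= burn_in and it % thin == 0:
            frames.append(state.X.copy())
    return np.array(frames), spec


@pytest.fixture(scope="session")
def lj_fluid():
    """Session-wide equilibrated K=64 LJ fluid at lambda* = (-4, 4)."""
    return simulate_lj_fluid()


@pytest.fixture(scope="session")
def lj_blob_model():
    """Full sampler run with potential estimation on a protein-density ball
    (heavy-atom-like density ~0.09 points/Å^3)."""
    from cgbeads.sampler import run
    from cgbeads.structure_io import AtomicPointCloud

    rng = np.random.default_rng(7)
    n = 3000
    radius = (n / 0.09 * 3 / (4 * np.pi)) ** (1 / 3)
    u = rng.standard_normal((n, 3))
    u /= np.linalg.norm(u, axis=1)[:, None]
    pts = u * radius * rng.uniform(0, 1, n)[:, None] ** (1 / 3)
    cloud = AtomicPointCloud(pts, source_id="synthetic-ball")
    config = GibbsConfig(n_beads=120, n_sweeps=500, burn_in=150, seed=1)
    model, trace = run(cloud, config)
    return model, trace
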