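"""Gibbs sampler for the bead model.

One sweep updates, in order: the atom-to-bead mapping Z (categorical), the
model precision s (Gamma), the bead positions X (Hamiltonian Monte Carlo on
the harmonic-plus-potential energy) and, optionally, the potential
coefficients lambda (configurational-temperature estimate from the current
configuration — a deterministic approximation to the conditional, not an
exact draw; its trace fluctuations reflect the fluctuations of X).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .exceptions import ConditioningError, InfeasibleConfigError
from .gmm import AssignmentMap, ClusterSummary, chi_square, summarize
from .potential import (
    PotentialSpec,
    energy,
    feature_gradients,
    feature_laplacians,
    lambda_to_lj,
)

__all__ = [
    "GibbsConfig",
    "SamplerState",
    "BeadModel",
    "Trace",
    "initialize",
    "sample_assignments",
    "sample_precision",
    "posterior_energy",
    "hmc_update",
    "estimate_lambda",
    "run",
]

# chunk size (in point-bead products) for the assignment step
_ASSIGN_CHUNK = 4_000_000

# floor for s when the fit is perfect (chi^2 = 0)
S_FLOOR = 1e-3


@dataclass
class GibbsConfig:
    """Run configuration for the Gibbs sampler."""

    n_beads: int
    n_sweeps: int = 1000
    burn_in: int = 200
    hmc_leapfrog_steps: int = 10
    hmc_target_acceptance: float = 0.8
    hmc_initial_step: float | None = None  # None: auto-scale from initial state
    lambda_update: bool = True
    lambda_prior: str | None = None  # None | "gaussian" | "laplace"
    lambda_prior_scale: float = 1.0
    init_lloyd_iterations: int = 8
    exponents: tuple = (-6, -12)
    pair_cutoff: float | None = None
    snapshot_every: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_beads < 1:
            raise ValueError("n_beads must be >= 1")
        if not 0 <= self.burn_in < self.n_sweeps:
            raise ValueError("require 0 <= burn_in < n_sweeps")
        if not 0.0 < self.hmc_target_acceptance < 1.0:
            raise ValueError("hmc_target_acceptance must lie in (0, 1)")
        if self.lambda_prior not in (None, "gaussian", "laplace"):
            raise ValueError("lambda_prior must be None, 'gaussian' or 'laplace'")


class _DualAveraging:
    """Nesterov dual-averaging step-size adaptation (standard HMC practice).

    Drives the average Metropolis acceptance probability to the target;
    ``current`` is used while adapting, ``averaged`` after freezing.
    """

    def __init__(self, initial_step: float, target: float, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = np.log(10.0 * initial_step)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.t = 0
        self.h_bar = 0.0
        self.log_step = np.log(initial_step)
        self.log_step_bar = np.log(initial_step)

    def update(self, accept_prob: float) -> None:
        self.t += 1
        frac = 1.0 / (self.t + self.t0)
        self.h_bar = (1.0 - frac) * self.h_bar + frac * (self.target - accept_prob)
        self.log_step = self.mu - np.sqrt(self.t) / self.gamma * self.h_bar
        eta = self.t ** -self.kappa
        self.log_step_bar = eta * self.log_step + (1.0 - eta) * self.log_step_bar

    @property
    def current(self) -> float:
        return float(np.exp(self.log_step))

    @property
    def averaged(self) -> float:
        return float(np.exp(self.log_step_bar))


@dataclass
class SamplerState:
    """Full parameter state of one Gibbs sweep."""

    X: np.ndarray
    assignment: AssignmentMap
    s: float
    lambdas: np.ndarray
    iteration: int = 0
    step_size: float = 0.1
    step_adapter: _DualAveraging | None = None


@dataclass
class BeadModel:
    """Posterior bead model: representative positions plus parameter summaries.

    ``positions`` is the last sampled configuration (the representative
    structure), ``positions_mean`` the post-burn-in average of the thinned
    snapshots; scalar parameters are posterior means with standard
    deviations over post-burn-in sweeps.
    """

    positions: np.ndarray
    assignment: AssignmentMap
    s: float
    s_sd: float = np.nan
    lambdas: np.ndarray = None
    lambdas_sd: np.ndarray = None
    sigma: float = np.nan
    sigma_sd: float = np.nan
    epsilon: float = np.nan
    epsilon_sd: float = np.nan
    r_cg: float = np.nan
    r_cg_sd: float = np.nan
    positions_mean: np.ndarray = None
    source_id: str = "unknown"

    @property
    def n_beads(self) -> int:
        return len(self.positions)


@dataclass
class Trace:
    """Per-sweep diagnostics and thinned bead snapshots."""

    s: np.ndarray
    lambdas: np.ndarray  # (n_sweeps, L)
    chi2: np.ndarray
    potential_energy: np.ndarray
    posterior_energy: np.ndarray
    accepted: np.ndarray
    step_size: np.ndarray
    sigma: np.ndarray
    epsilon: np.ndarray
    r_cg: np.ndarray
    rg: np.ndarray
    snapshots: np.ndarray  # (n_snapshots, K, 3)
    snapshot_sweeps: np.ndarray
    burn_in: int

    def __len__(self) -> int:
        return len(self.s)

    @property
    def post_burn_in(self) -> np.ndarray:
        return np.arange(len(self.s)) >= self.burn_in

    def acceptance_rate(self, after_burn_in: bool = True) -> float:
        mask = self.post_burn_in if after_burn_in else slice(None)
        return float(np.mean(self.accepted[mask]))

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            "sweep": np.arange(len(self.s)),
            "s": self.s,
            "chi2": self.chi2,
            "potential_energy": self.potential_energy,
            "posterior_energy": self.posterior_energy,
            "accepted": self.accepted.astype(int),
            "step_size": self.step_size,
            "sigma": self.sigma,
            "epsilon": self.epsilon,
            "r_cg": self.r_cg,
            "rg": self.rg,
        }
        for l in range(self.lambdas.shape[1]):
            data[f"lambda_{l + 1}"] = self.lambdas[:, l]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def initialize(cloud, config: GibbsConfig, rng=None) -> SamplerState:
    """Initial state: beads on K distinct cloud points, nearest-bead mapping.

    Bead seeds are drawn without replacement with probability proportional
    to point weight and jittered by 1e-3 Å to break exact coincidences;
    ``s`` is set from the resulting chi-square and lambda starts at zero.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    K, N = config.n_beads, len(cloud)
    if N < K:
        raise InfeasibleConfigError(f"need at least K={K} points, got N={N}")
    # k-means++-style spread-out seeding: first seed weight-proportional,
    # subsequent seeds proportional to w_n * squared distance to the nearest
    # chosen seed; guarantees every well-separated cluster is covered with
    # high probability (plain weight-proportional draws do not). Several
    # candidate seedings are drawn and the lowest-chi^2 one kept, since the
    # hard-assignment Gibbs chain escapes a doubled cluster only slowly.
    best_idx, best_cost = None, np.inf
    for _ in range(4):
        idx = np.empty(K, dtype=np.intp)
        idx[0] = rng.choice(N, p=cloud.weights / cloud.total_weight)
        d2 = np.sum((cloud.positions - cloud.positions[idx[0]]) ** 2, axis=1)
        for k in range(1, K):
            prob = cloud.weights * d2
            total = prob.sum()
            if total <= 0:  # all remaining points coincide with a seed
                prob = np.where(d2 >= 0, cloud.weights, 0.0)
                total = prob.sum()
            idx[k] = rng.choice(N, p=prob / total)
            d2 = np.minimum(
                d2, np.sum((cloud.positions - cloud.positions[idx[k]]) ** 2, axis=1)
            )
        cost = float(cloud.weights @ d2)
        if cost < best_cost:
            best_idx, best_cost = idx, cost
    idx = best_idx
    if K >= 3:
        # repair pathologically close seed pairs: a seed pair much closer
        # than the typical seed spacing seeds a runaway in the potential
        # estimate (it reads a glued pair as a deeply bound state)
        for _ in range(10):
            seeds = cloud.positions[idx]
            nn_dist, _ = cKDTree(seeds).query(seeds, k=2)
            nn = nn_dist[:, 1]
            r_min = 0.5 * np.median(nn)
            bad = np.where(nn < r_min)[0]
            if bad.size == 0:
                break
            keep_mask = np.ones(K, dtype=bool)
            seen = set()
            for b in bad:  # drop one member of each close pair
                if b not in seen:
                    partner = int(
                        np.argmin(
                            np.where(
                                np.arange(K) == b,
                                np.inf,
                                np.sum((seeds - seeds[b]) ** 2, axis=1),
                            )
                        )
                    )
                    seen.update((b, partner))
                    keep_mask[b] = False
            kept = idx[keep_mask]
            d2 = cKDTree(cloud.positions[kept]).query(cloud.positions)[0] ** 2
            redraw = []
            for _ in range(K - kept.size):
                prob = cloud.weights * d2
                j = int(rng.choice(N, p=prob / prob.sum()))
                redraw.append(j)
                d2 = np.minimum(
                    d2, np.sum((cloud.positions - cloud.positions[j]) ** 2, axis=1)
                )
            idx = np.concatenate([kept, np.array(redraw, dtype=np.intp)])
    X = cloud.positions[idx].copy()
    # Lloyd refinement: move seeds to the weighted centroids of their
    # nearest-point cells. Centroidal spacing is regular, which starts the
    # configurational-temperature estimate of lambda on the physical branch;
    # seeding straight from atom positions leaves irregular close pairs that
    # the estimator reads as a hot, softly packed fluid and the chain can
    # lock into a glued-pair state.
    for _ in range(max(config.init_lloyd_iterations, 0)):
        _, z = cKDTree(X).query(cloud.positions)
        counts = np.bincount(z, weights=cloud.weights, minlength=K)
        occ = counts > 0
        for axis in range(3):
            wx = np.bincount(
                z, weights=cloud.weights * cloud.positions[:, axis], minlength=K
            )
            X[occ, axis] = wx[occ] / counts[occ]
    X = X + 1e-3 * rng.standard_normal((K, 3))
    _, nearest = cKDTree(X).query(cloud.positions)
    assignment = AssignmentMap(nearest, K)
    chi2 = chi_square(cloud, X, assignment)
    s = max(np.sqrt(chi2 / (3.0 * cloud.total_weight)), S_FLOOR)
    lambdas = np.zeros(len(config.exponents))
    step = config.hmc_initial_step
    if step is None:
        # leapfrog stability heuristic: the stiffest harmonic well has
        # curvature max(N_k)/s^2, so start safely below 2 s / sqrt(max N_k)
        counts = np.bincount(assignment.bead_index, weights=cloud.weights, minlength=K)
        step = 0.5 * s / np.sqrt(max(counts.max(), 1.0))
    return SamplerState(X, assignment, s, lambdas, 0, step)


def sample_assignments(cloud, X, s: float, rng) -> AssignmentMap:
    """Draw each point's bead from its categorical conditional.

    Probabilities are ``p_nk ∝ exp(-||x_n - X_k||^2 / 2 s^2)``; sampling uses
    the Gumbel-max trick on the (implicitly normalized) logits, chunked over
    points to bound memory.
    """
    if s <= 0:
        raise ValueError("s must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N, K = len(cloud), len(X)
    out = np.empty(N, dtype=np.intp)
    chunk = max(1, _ASSIGN_CHUNK // K)
    inv = 1.0 / (2.0 * s * s)
    for start in range(0, N, chunk):
        stop = min(start + chunk, N)
        logits = -inv * cdist(cloud.positions[start:stop], X, "sqeuclidean")
        gumbel = rng.gumbel(size=logits.shape)
        out[start:stop] = np.argmax(logits + gumbel, axis=1)
    return AssignmentMap(out, K)


def sample_precision(cloud, X, assignment: AssignmentMap, rng) -> float:
    """Draw s from its conditional: s^-2 ~ Gamma(3 W / 2, rate = chi^2 / 2).

    W is the total cloud weight (N for atoms), so the expected precision is
    3 W / chi^2. A perfect fit (chi^2 = 0) returns the floor value.
    """
    chi2 = chi_square(cloud, X, assignment)
    if chi2 <= 0.0:
        return S_FLOOR
    shape = 1.5 * cloud.total_weight
    precision = rng.gamma(shape, scale=2.0 / chi2)
    return max(precision**-0.5, S_FLOOR)


def posterior_energy(X, summary: ClusterSummary, s: float, spec: PotentialSpec):
    """Energy and gradient of the conditional posterior of X.

    ``U(X) = (1/2 s^2) sum_k N_k ||X_k - mu_k||^2 + <lambda, f(X)>``; empty
    clusters feel only the potential term.
    """
    X = np.asarray(X, dtype=float)
    occ = summary.occupied
    diff = np.zeros_like(X)
    diff[occ] = X[occ] - summary.centers[occ]
    weighted = summary.counts[:, None] * diff
    U = float(np.sum(weighted * diff) / (2.0 * s * s))
    grad = weighted / (s * s)
    if np.any(spec.lambdas):
        U += energy(X, spec)
        grads = feature_gradients(X, spec)
        grad = grad + np.tensordot(spec.lambdas, grads, axes=1)
    return U, grad


def hmc_update(
    state: SamplerState,
    summary: ClusterSummary,
    spec: PotentialSpec,
    config: GibbsConfig,
    rng,
):
    """One HMC proposal for the bead positions; returns (new X, accepted).

    Unit-mass momenta, leapfrog integration of (U, grad U), Metropolis
    accept/reject on the Hamiltonian difference. The step size adapts
    toward the target acceptance rate during burn-in (Robbins-Monro on the
    log step size) and is frozen afterwards. Non-finite energies during
    integration reject the proposal.
    """
    X0 = state.X
    if config.hmc_leapfrog_steps <= 0:
        return X0.copy(), True
    U0, grad = posterior_energy(X0, summary, state.s, spec)
    p = rng.standard_normal(X0.shape)
    H0 = U0 + 0.5 * np.sum(p * p)
    eps = state.step_size
    X = X0.copy()
    ok = True
    try:
        p = p - 0.5 * eps * grad
        for step in range(config.hmc_leapfrog_steps):
            X = X + eps * p
            U, grad = posterior_energy(X, summary, state.s, spec)
            if not np.isfinite(U):
                ok = False
                break
            if step < config.hmc_leapfrog_steps - 1:
                p = p - eps * grad
        if ok:
            p = p - 0.5 * eps * grad
    except (FloatingPointError, ValueError):
        ok = False
    if ok:
        H1 = U + 0.5 * np.sum(p * p)
        accept_prob = min(1.0, np.exp(min(H0 - H1, 0.0))) if np.isfinite(H1) else 0.0
    else:
        accept_prob = 0.0
    accepted = rng.uniform() < accept_prob
    if state.iteration < config.burn_in:
        if state.step_adapter is None:
            state.step_adapter = _DualAveraging(
                state.step_size, config.hmc_target_acceptance
            )
        state.step_adapter.update(accept_prob)
        state.step_size = (
            state.step_adapter.averaged
            if state.iteration == config.burn_in - 1
            else state.step_adapter.current
        )
    return (X if accepted else X0.copy()), bool(accepted)


def estimate_lambda(
    X,
    spec: PotentialSpec,
    prior: str | None = None,
    prior_scale: float = 1.0,
) -> np.ndarray:
    """Configurational-temperature estimate of the potential coefficients.

    Builds ``A_{ll'} = <grad f_l, grad f_l'>`` and ``b_l = Lap f_l`` from
    the current configuration and solves ``A lambda = b``. A stack of
    configurations (shape (F, K, 3)) may be passed instead, in which case A
    and b are ensemble averages — the appropriate estimator for weakly
    constrained systems, where single-configuration A and b are dominated
    by the closest pair and extremely heavy-tailed. With a Gaussian prior
    the ridge-regularized least-squares problem
    ``1/2 ||A lambda - b||^2 + ||lambda||^2 / (2 scale^2)`` is solved in
    closed form; a Laplace prior uses coordinate-descent lasso.
    """
    X = np.asarray(X, dtype=float)
    L = spec.n_features
    stack = X[None] if X.ndim == 2 else X
    A = np.zeros((L, L))
    b = np.zeros(L)
    for config_x in stack:
        grads = feature_gradients(config_x, spec)
        flat = grads.reshape(L, -1)
        A += flat @ flat.T
        b += feature_laplacians(config_x, spec)
    A /= len(stack)
    b /= len(stack)
    if prior is None:
        # symmetric scaling: feature magnitudes differ by orders of magnitude,
        # so test conditioning on the correlation-like scaled matrix
        d = np.sqrt(np.diag(A))
        if np.any(d == 0):
            raise ConditioningError("a feature has zero gradient everywhere")
        A_scaled = A / np.outer(d, d)
        cond = np.linalg.cond(A_scaled)
        if not np.isfinite(cond) or cond > 1e12:
            raise ConditioningError(
                f"feature Gram matrix is ill-conditioned (cond={cond:.2e}); "
                "consider a gaussian or laplace prior on lambda"
            )
        return np.linalg.solve(A_scaled, b / d) / d
    M = A.T @ A
    c = A.T @ b
    if prior == "gaussian":
        return np.linalg.solve(M + np.eye(L) / prior_scale**2, c)
    # laplace: coordinate descent on 1/2||A lam - b||^2 + sum |lam|/scale
    lam = np.zeros(L)
    penalty = 1.0 / prior_scale
    for _ in range(200):
        lam_old = lam.copy()
        for l in range(L):
            rho = c[l] - M[l] @ lam + M[l, l] * lam[l]
            lam[l] = np.sign(rho) * max(abs(rho) - penalty, 0.0) / M[l, l]
        if np.max(np.abs(lam - lam_old)) < 1e-12 * (1.0 + np.max(np.abs(lam))):
            break
    return lam


def run(cloud, config: GibbsConfig, progress: bool = False):
    """Run the full Gibbs sampler; returns (BeadModel, Trace).

    Sweep order: Z -> s -> X (HMC) -> lambda. The returned model carries
    the last configuration as representative structure and posterior means
    (with standard deviations) of s, lambda and the derived LJ constants
    over post-burn-in sweeps.
    """
    rng = np.random.default_rng(config.seed)
    spec = PotentialSpec(config.exponents, pair_cutoff=config.pair_cutoff)
    state = initialize(cloud, config, rng)
    n, L = config.n_sweeps, spec.n_features

    tr = {
        "s": np.empty(n),
        "lambdas": np.empty((n, L)),
        "chi2": np.empty(n),
        "potential_energy": np.empty(n),
        "posterior_energy": np.empty(n),
        "accepted": np.zeros(n, dtype=bool),
        "step_size": np.empty(n),
        "sigma": np.full(n, np.nan),
        "epsilon": np.full(n, np.nan),
        "r_cg": np.full(n, np.nan),
        "rg": np.empty(n),
    }
    snapshots, snapshot_sweeps = [], []

    iterator = range(n)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="gibbs")
    for sweep in iterator:
        state.iteration = sweep
        state.assignment = sample_assignments(cloud, state.X, state.s, rng)
        state.s = sample_precision(cloud, state.X, state.assignment, rng)
        summary = summarize(cloud, state.assignment)
        spec.lambdas = state.lambdas
        state.X, accepted = hmc_update(state, summary, spec, config, rng)
        if config.lambda_update:
            state.lambdas = estimate_lambda(
                state.X, spec, config.lambda_prior, config.lambda_prior_scale
            )

        spec.lambdas = state.lambdas
        tr["s"][sweep] = state.s
        tr["lambdas"][sweep] = state.lambdas
        tr["chi2"][sweep] = chi_square(cloud, state.X, state.assignment)
        e_pot = energy(state.X, spec) if np.any(state.lambdas) else 0.0
        tr["potential_energy"][sweep] = e_pot
        tr["posterior_energy"][sweep] = posterior_energy(
            state.X, summary, state.s, spec
        )[0]
        tr["accepted"][sweep] = accepted
        tr["step_size"][sweep] = state.step_size
        if L == 2 and spec.is_lj():
            lj = lambda_to_lj(state.lambdas)
            if lj.defined:
                tr["sigma"][sweep] = lj.sigma
                tr["epsilon"][sweep] = lj.epsilon
                tr["r_cg"][sweep] = lj.r_cg
        centered = state.X - state.X.mean(axis=0)
        tr["rg"][sweep] = np.sqrt(np.mean(np.sum(centered**2, axis=1)))
        if sweep % config.snapshot_every == 0 or sweep == n - 1:
            snapshots.append(state.X.copy())
            snapshot_sweeps.append(sweep)

    trace = Trace(
        snapshots=np.array(snapshots),
        snapshot_sweeps=np.array(snapshot_sweeps),
        burn_in=config.burn_in,
        **tr,
    )
    keep = trace.post_burn_in
    snap_keep = trace.snapshot_sweeps >= config.burn_in

    def _summ(values):
        values = values[keep]
        good = np.isfinite(values)
        if not good.any():
            return np.nan, np.nan
        return float(np.mean(values[good])), float(np.std(values[good]))

    s_mean, s_sd = _summ(tr["s"])
    lam_mean = tr["lambdas"][keep].mean(axis=0)
    lam_sd = tr["lambdas"][keep].std(axis=0)
    sigma_mean, sigma_sd = _summ(tr["sigma"])
    eps_mean, eps_sd = _summ(tr["epsilon"])
    rcg_mean, rcg_sd = _summ(tr["r_cg"])
    model = BeadModel(
        positions=state.X.copy(),
        assignment=state.assignment,
        s=s_mean,
        s_sd=s_sd,
        lambdas=lam_mean,
        lambdas_sd=lam_sd,
        sigma=sigma_mean,
        sigma_sd=sigma_sd,
        epsilon=eps_mean,
        epsilon_sd=eps_sd,
        r_cg=rcg_mean,
        r_cg_sd=rcg_sd,
        positions_mean=(
            trace.snapshots[snap_keep].mean(axis=0)
            if snap_keep.any()
            else state.X.copy()
        ),
        source_id=cloud.source_id,
    )
    return model, trace
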