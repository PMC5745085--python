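"""Exact stochastic simulation of the dimerization networks, plus the
synthetic-data generator.

The stochastic twin serves as an independent oracle for the deterministic
integrator: in a finite reaction volume Omega the species become integer
molecule counts (``n = c * Omega * N_A``) and the networks become jump
processes simulated with the direct Gillespie method.  Because the synthesis
rate is piecewise constant, each simulation is run segment-by-segment over
intervals where all propensities are time-homogeneous, so the plain direct
method stays exact across the window boundaries.

Reaction channels (primed):

* production   ``0 -> N``        propensity ``lambda_N(t) * Omega * N_A``
* degradation  ``N -> 0``        propensity ``beta_N * n_N``
* degradation  ``V -> 0``        propensity ``beta_V * n_V``
* pairing      ``N + V -> D``    propensity ``lambda_D/(Omega*N_A) * n_N * n_V``

Cold-start drops the V channels; its homodimerization channel has propensity
``lambda_D/(Omega*N_A) * n_N * (n_N - 1)`` and removes ONE N per D formed, so
that its mean field reproduces the deterministic cold-start equations
(dN/dt gains ``-lambda_D*N**2``, dD/dt gains ``+lambda_D*N**2``) rather than
the 2-to-1 stoichiometry of a standard homodimerization — oracle fidelity to
the deterministic scheme takes precedence over chemical convention here.

The synthetic-data generator is deterministic-trajectory based: observed
dimer values are the ODE solution perturbed by i.i.d. multiplicative
lognormal noise, the observation model the recovery stage assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model import AVOGADRO, KineticParameters, ModelKind, M_PER_NM
from .simulate import Trajectory, integrate

__all__ = [
    "DEFAULT_OMEGA",
    "StochasticConfig",
    "CountTrajectory",
    "EnsembleSummary",
    "SyntheticDataset",
    "ssa_run",
    "ssa_ensemble",
    "generate_noisy_trajectories",
]

#: Default reaction volume (L): maps 100 nM to 1e5 molecules, i.e.
#: Omega = 1e5 / (100e-9 * N_A) ~ 1.66e-12 L (desk-scale runtimes with
#: fluctuations small enough for mean-field comparison).
DEFAULT_OMEGA = 1e5 / (100e-9 * AVOGADRO)

_SEED_MOD = 2**31 - 1


@dataclass
class StochasticConfig:
    """Finite-volume simulation settings.

    ``omega`` (L) sets the count<->concentration conversion through
    ``n = c * omega * N_A``; ``record_times`` (s, strictly increasing) is
    the output grid shared by all replicates.
    """

    record_times: np.ndarray
    omega: float = DEFAULT_OMEGA
    seed: int = 0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        self.record_times = np.asarray(self.record_times, dtype=float)
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.record_times.ndim != 1 or not np.all(
            np.diff(self.record_times) > 0
        ):
            raise ValueError("record_times must be strictly increasing")

    @property
    def volume_factor(self) -> float:
        """Molecules per molar: Omega * N_A."""
        return self.omega * AVOGADRO

    def replicate_seeds(self) -> np.ndarray:
        """Deterministic per-replicate seeds derived from ``seed``."""
        ss = np.random.SeedSequence(self.seed)
        return (ss.generate_state(self.n_replicates) % _SEED_MOD).astype(np.int64)


@dataclass
class CountTrajectory:
    """One SSA realization recorded on ``config.record_times``."""

    times: np.ndarray
    n_N: np.ndarray
    n_V: np.ndarray
    n_D: np.ndarray
    model: ModelKind
    params: KineticParameters
    config: StochasticConfig

    def concentrations(self, species: str) -> np.ndarray:
        """Counts converted to molar for species 'N', 'V' or 'D'."""
        counts = {"N": self.n_N, "V": self.n_V, "D": self.n_D}[species]
        return counts / self.config.volume_factor


@dataclass
class EnsembleSummary:
    """Per-time ensemble mean and standard error (M) across replicates."""

    times: np.ndarray
    mean: dict[str, np.ndarray]
    se: dict[str, np.ndarray]
    n_replicates: int


@dataclass
class SyntheticDataset:
    """Noisy observations of the dimer trajectory with known ground truth.

    ``observations`` has shape (n_replicates, n_times) in molar; the noise
    is multiplicative lognormal, ``obs = D_true(t) * exp(eps)`` with
    ``eps ~ Normal(0, sigma**2)`` i.i.d. per replicate and time.
    """

    times: np.ndarray
    observations: np.ndarray
    sigma: float
    true_params: KineticParameters
    seed: int
    model: ModelKind = ModelKind.PRIMED_HETERODIMER

    @property
    def observations_nM(self) -> np.ndarray:
        return self.observations / M_PER_NM


@njit(cache=True)
def _ssa_kernel(
    seed,
    primed,
    prod_a_on,
    beta_N,
    beta_V,
    c_dim,
    n_V0,
    n_N0,
    t_on,
    t_off,
    t_end,
    record_times,
):  # pragma: no cover - exercised via ssa_run
    np.random.seed(seed)
    n_rec = record_times.shape[0]
    out = np.zeros((3, n_rec), dtype=np.int64)
    nN = n_N0
    nV = n_V0
    nD = 0
    ri = 0
    t = 0.0
    bounds = np.array([0.0, t_on, t_off, t_end])
    for seg in range(3):
        t0 = bounds[seg]
        t1 = bounds[seg + 1]
        if t1 <= t0:
            continue
        a_prod = prod_a_on if seg == 1 else 0.0
        t = t0
        while True:
            a_degN = beta_N * nN
            a_degV = beta_V * nV if primed else 0.0
            if primed:
                a_dim = c_dim * nN * nV
            else:
                a_dim = c_dim * nN * (nN - 1)
            a_tot = a_prod + a_degN + a_degV + a_dim
            if a_tot <= 0.0:
                # nothing can fire: jump to the segment boundary
                while ri < n_rec and record_times[ri] <= t1:
                    out[0, ri] = nN
                    out[1, ri] = nV
                    out[2, ri] = nD
                    ri += 1
                t = t1
                break
            t_next = t - np.log(np.random.random()) / a_tot
            if t_next >= t1:
                while ri < n_rec and record_times[ri] <= t1:
                    out[0, ri] = nN
                    out[1, ri] = nV
                    out[2, ri] = nD
                    ri += 1
                t = t1
                break
            # record the pre-event state at times strictly before the event
            while ri < n_rec and record_times[ri] < t_next:
                out[0, ri] = nN
                out[1, ri] = nV
                out[2, ri] = nD
                ri += 1
            u = np.random.random() * a_tot
            if u < a_prod:
                nN += 1
            elif u < a_prod + a_degN:
                nN -= 1
            elif u < a_prod + a_degN + a_degV:
                nV -= 1
            else:
                if primed:
                    nN -= 1
                    nV -= 1
                else:
                    nN -= 1  # as-written stoichiometry: one N per dimer
                nD += 1
            t = t_next
    while ri < n_rec:
        out[0, ri] = nN
        out[1, ri] = nV
        out[2, ri] = nD
        ri += 1
    return out


def _run_one(
    model: ModelKind,
    params: KineticParameters,
    config: StochasticConfig,
    seed: int,
    n_N0: int = 0,
) -> np.ndarray:
    vol = config.volume_factor
    primed = model is ModelKind.PRIMED_HETERODIMER
    n_V0 = int(round(params.V0 * vol)) if primed else 0
    return _ssa_kernel(
        seed,
        primed,
        params.lambda_N_on * vol,
        params.beta_N,
        params.beta_V,
        params.lambda_D / vol,
        n_V0,
        n_N0,
        params.t_on,
        params.t_off,
        params.t_end,
        config.record_times,
    )


def ssa_run(
    model: ModelKind,
    params: KineticParameters,
    config: StochasticConfig,
    replicate: int = 0,
    n_N0: int = 0,
) -> CountTrajectory:
    """One exact SSA realization; deterministic given (config.seed, replicate).

    ``replicate`` selects which of the config's derived per-replicate seeds
    drives the run, so ensembles and single runs share the same stream.
    ``n_N0`` optionally preloads Nodal monomers at t = 0 (the networks
    themselves start at zero N; the override exists for oracle tests on
    minimal reaction sets).
    """
    model = ModelKind(model)
    if not 0 <= replicate < config.n_replicates:
        raise ValueError("replicate index out of range")
    if np.any(config.record_times < 0) or np.any(
        config.record_times > params.t_end
    ):
        raise ValueError("record_times must lie within [0, t_end]")
    seed = int(config.replicate_seeds()[replicate])
    counts = _run_one(model, params, config, seed, n_N0=n_N0)
    return CountTrajectory(
        times=config.record_times.copy(),
        n_N=counts[0],
        n_V=counts[1],
        n_D=counts[2],
        model=model,
        params=params,
        config=config,
    )


def ssa_ensemble(
    model: ModelKind,
    params: KineticParameters,
    config: StochasticConfig,
) -> EnsembleSummary:
    """Mean and standard error of concentration across SSA replicates."""
    model = ModelKind(model)
    if config.n_replicates < 2:
        raise ValueError("ensemble requires n_replicates >= 2")
    seeds = config.replicate_seeds()
    vol = config.volume_factor
    n_rec = config.record_times.size
    acc = np.zeros((config.n_replicates, 3, n_rec))
    for i, seed in enumerate(seeds):
        acc[i] = _run_one(model, params, config, int(seed))
    conc = acc / vol
    mean = conc.mean(axis=0)
    se = conc.std(axis=0, ddof=1) / np.sqrt(config.n_replicates)
    species = ("N", "V", "D")
    return EnsembleSummary(
        times=config.record_times.copy(),
        mean={s: mean[i] for i, s in enumerate(species)},
        se={s: se[i] for i, s in enumerate(species)},
        n_replicates=config.n_replicates,
    )


def default_observation_times(params: KineticParameters) -> np.ndarray:
    """Sensitivity-aware observation design for dimer-based recovery.

    The dimerization rate only shapes the dimer curve transiently: within a
    minute or two of production onset, free Nodal relaxes onto its
    quasi-steady balance and D thereafter tracks cumulative production
    almost independently of lambda_D.  The default design therefore samples
    densely (every 30 s) for the first ten minutes after ``t_on`` and then
    coarsely (every 15 min) out to ``t_end``, which keeps all rate
    parameters identifiable from the dimer readout alone.
    """
    dense = np.arange(params.t_on + 30.0, params.t_on + 600.0 + 1, 30.0)
    coarse = np.arange(params.t_on + 900.0, params.t_end + 1, 900.0)
    return np.unique(np.concatenate([dense, coarse]))


def generate_noisy_trajectories(
    params: KineticParameters,
    sigma: float,
    n_reps: int,
    obs_times: np.ndarray,
    seed: int,
    model: ModelKind = ModelKind.PRIMED_HETERODIMER,
) -> SyntheticDataset:
    """Synthetic observed dimer trajectories with lognormal noise.

    The noiseless curve is the deterministic dimer trajectory of ``model``
    under ``params``; each observation multiplies it by ``exp(eps)`` with
    ``eps ~ Normal(0, sigma**2)``.  Fully reproducible from ``seed``.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    obs_times = np.asarray(obs_times, dtype=float)
    if np.any(obs_times < 0) or np.any(obs_times > params.t_end):
        raise ValueError("obs_times must lie within [0, t_end]")
    if not np.all(np.diff(obs_times) > 0):
        raise ValueError("obs_times must be strictly increasing")
    model = ModelKind(model)
    grid = np.unique(
        np.concatenate(
            [[0.0, params.t_on, params.t_off, params.t_end], obs_times]
        )
    )
    traj = integrate(model, params, grid=grid)
    d_true = np.interp(obs_times, traj.times, traj.D)
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, sigma, size=(n_reps, obs_times.size)) if sigma > 0 else (
        np.zeros((n_reps, obs_times.size))
    )
    observations = d_true[None, :] * np.exp(eps)
    return SyntheticDataset(
        times=obs_times,
        observations=observations,
        sigma=sigma,
        true_params=params,
        seed=seed,
        model=model,
    )
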