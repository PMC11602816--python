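"""Particle-based 'ground truth': 1D Brownian dynamics with Doi reactions.

Particles diffuse on ``[0, L]`` with reflecting boundaries.  Species A is
produced at a point source, converts to B in place (first-order network)
or dimerizes pairwise within the Doi radius (dimerization network), and B
is degraded.  Long-run binned concentration profiles are the reference
against which the lattice models are scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from mgrdme import _kernels
from mgrdme.model import DIMERIZATION, FIRST_ORDER, MultiGridModel

__all__ = ["ParticleState", "BDConfig", "BDResult", "bd_step", "bd_simulate", "pair_candidates"]


@dataclass
class ParticleState:
    """Positions of the A and B particles on ``[0, L]`` and the time."""

    xA: np.ndarray
    xB: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.xA = np.asarray(self.xA, dtype=float)
        self.xB = np.asarray(self.xB, dtype=float)

    def validate_against(self, model: MultiGridModel) -> None:
        for name, x in (("xA", self.xA), ("xB", self.xB)):
            if x.size and (x.min() < 0 or x.max() > model.L):
                raise ValueError(f"{name} positions must lie in [0, {model.L}]")


@dataclass
class BDConfig:
    """Timestep, horizon, seed and placement/boundary conventions.

    ``source`` is ``"origin"`` (new A exactly at x=0, the delta-source
    convention) or ``"first_compartment"`` (uniform on the first
    A-compartment, matching the lattice production reaction).  ``product``
    places the dimerization product at the ``"midpoint"`` of the reacting
    pair or at the ``"reactant"`` position.
    """

    dt: float
    t_end: float
    seed: int | None = None
    burn_in: float = 0.0
    source: Literal["origin", "first_compartment"] = "origin"
    product: Literal["midpoint", "reactant"] = "midpoint"
    n_batches: int = 20

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.t_end <= self.burn_in:
            raise ValueError("t_end must exceed burn_in")

    def validate_against(self, model: MultiGridModel) -> None:
        if model.network == DIMERIZATION and model.doi_lambda is not None:
            if model.doi_lambda * self.dt > 0.1:
                warnings.warn(
                    f"lambda*dt = {model.doi_lambda * self.dt:.3g} > 0.1; "
                    "per-step Doi firing probabilities are coarse, reduce dt",
                    stacklevel=2,
                )
            if model.doi_rho is not None:
                step_sd = np.sqrt(2.0 * model.D_A * self.dt)
                if step_sd > model.doi_rho / 2.0:
                    warnings.warn(
                        f"rms displacement per step ({step_sd:.3g}) exceeds "
                        f"rho/2 ({model.doi_rho / 2.0:.3g}); pairs may tunnel "
                        "through the reaction radius, reduce dt",
                        stacklevel=2,
                    )


def pair_candidates(positions: np.ndarray, rho: float) -> list[tuple[int, int]]:
    """All unordered index pairs of sorted ``positions`` within distance rho.

    Sorted sweep, O(n + #pairs).
    """
    positions = np.asarray(positions, dtype=float)
    pairs: list[tuple[int, int]] = []
    n = positions.size
    for i in range(n - 1):
        j = i + 1
        while j < n and positions[j] - positions[i] <= rho:
            pairs.append((i, j))
            j += 1
    return pairs


def _reflect(x: np.ndarray, L: float) -> np.ndarray:
    # fold into [0, L]: triangle map of period 2L
    y = np.mod(x, 2.0 * L)
    return np.where(y > L, 2.0 * L - y, y)


def bd_step(
    state: ParticleState,
    model: MultiGridModel,
    config: BDConfig,
    rng: np.random.Generator,
) -> ParticleState:
    """Advance the particle system by one timestep ``config.dt``.

    Order of operations: diffusion (reflected Gaussian displacements),
    production (Poisson(k1 dt) new A at the source), reaction (exact
    per-step exponential event probabilities), degradation of B.  This is
    the readable reference stepper; :func:`bd_simulate` runs the same
    scheme in a compiled kernel.
    """
    dt = config.dt
    L = model.L
    xA = _reflect(state.xA + np.sqrt(2.0 * model.D_A * dt) * rng.standard_normal(state.xA.size), L)
    xB = _reflect(state.xB + np.sqrt(2.0 * model.D_B * dt) * rng.standard_normal(state.xB.size), L)

    n_new = rng.poisson(model.k1 * dt)
    if n_new:
        if config.source == "origin":
            new = np.zeros(n_new)
        else:
            new = rng.uniform(0.0, model.h_A, size=n_new)
        xA = np.concatenate([xA, new])

    if model.network == FIRST_ORDER:
        conv = rng.random(xA.size) < 1.0 - np.exp(-model.k2 * dt)
        xB = np.concatenate([xB, xA[conv]])
        xA = xA[~conv]
    else:
        lam, rho = model.doi_lambda, model.doi_rho
        if lam is None or rho is None:
            raise ValueError("dimerization BD requires doi_lambda and doi_rho")
        order = np.argsort(xA)
        xs = xA[order]
        pairs = pair_candidates(xs, rho)
        if pairs:
            p_fire = 1.0 - np.exp(-lam * dt)
            alive = np.ones(xs.size, dtype=bool)
            new_B = []
            # random processing order; a consumed particle invalidates its
            # remaining candidate pairs
            for k in rng.permutation(len(pairs)):
                i, j = pairs[k]
                if alive[i] and alive[j] and rng.random() < p_fire:
                    alive[i] = alive[j] = False
                    if config.product == "midpoint":
                        new_B.append(0.5 * (xs[i] + xs[j]))
                    else:
                        new_B.append(xs[i])
            xs = xs[alive]
            if new_B:
                xB = np.concatenate([xB, new_B])
        xA = xs

    keep = rng.random(xB.size) >= 1.0 - np.exp(-model.k3 * dt)
    xB = xB[keep]
    return ParticleState(xA=xA, xB=xB, t=state.t + dt)


@dataclass
class BDResult:
    """Time-averaged binned concentrations with batch-means standard errors.

    Profiles are concentrations (mean count per bin divided by bin width)
    on the model's A grid (``conc_A``, length K_A) and B grid (``conc_B``,
    length K_B).  ``A_total`` / ``B_total`` are time-averaged population
    sizes.
    """

    model: MultiGridModel
    config: BDConfig
    conc_A: np.ndarray
    conc_A_se: np.ndarray
    conc_B: np.ndarray
    conc_B_se: np.ndarray
    A_total: float
    A_total_se: float
    B_total: float
    B_total_se: float
    final_state: ParticleState | None = None

    @property
    def mean_counts_A(self) -> np.ndarray:
        return self.conc_A * self.model.h_A

    @property
    def mean_counts_B(self) -> np.ndarray:
        return self.conc_B * self.model.h_B


def _batch_stats(batch_sums: np.ndarray, batch_steps: np.ndarray):
    """Mean and batch-means SE from per-batch sums (first axis = batches)."""
    valid = batch_steps > 0
    steps = batch_steps[valid].astype(float)
    if batch_sums.ndim == 2:
        means = batch_sums[valid] / steps[:, None]
    else:
        means = batch_sums[valid] / steps
    mean = means.mean(axis=0)
    nb = means.shape[0]
    if nb > 1:
        se = means.std(axis=0, ddof=1) / np.sqrt(nb)
    else:
        se = np.full_like(np.asarray(mean, dtype=float), np.nan)
    return mean, se


def bd_simulate(
    model: MultiGridModel,
    config: BDConfig,
    initial: ParticleState | None = None,
    rng: np.random.Generator | None = None,
) -> BDResult:
    """Long-run Brownian dynamics with binned time-averaged profiles.

    Accumulates per-compartment occupancies on the model's A and B grids
    after ``config.burn_in``, split into ``config.n_batches`` batches for
    standard errors.  Reproducible given ``config.seed``.
    """
    config.validate_against(model)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if initial is None:
        initial = ParticleState(np.empty(0), np.empty(0))
    initial.validate_against(model)

    n_steps = int(round(config.t_end / config.dt))
    burn_steps = int(round(config.burn_in / config.dt))
    if burn_steps >= n_steps:
        raise ValueError("burn_in leaves no accumulation window")
    nb = config.n_batches
    batch_histA = np.zeros((nb, model.K_A))
    batch_histB = np.zeros((nb, model.K_B))
    batch_totA = np.zeros(nb)
    batch_totB = np.zeros(nb)
    batch_steps = np.zeros(nb, dtype=np.int64)

    dimer = model.network == DIMERIZATION
    lam = model.doi_lambda if dimer else 0.0
    rho = model.doi_rho if dimer else 0.0
    if dimer and (lam is None or rho is None):
        raise ValueError("dimerization BD requires doi_lambda and doi_rho")

    xA_fin, xB_fin = _kernels.bd_kernel(
        np.asarray(initial.xA, dtype=float),
        np.asarray(initial.xB, dtype=float),
        model.L,
        model.D_A,
        model.D_B,
        model.k1,
        model.k2,
        model.k3,
        float(lam),
        float(rho),
        not dimer,
        config.dt,
        n_steps,
        burn_steps,
        config.source == "origin",
        model.h_A,
        config.product == "midpoint",
        model.K_A,
        model.K_B,
        nb,
        batch_histA,
        batch_histB,
        batch_totA,
        batch_totB,
        batch_steps,
        rng,
    )

    countA, countA_se = _batch_stats(batch_histA, batch_steps)
    countB, countB_se = _batch_stats(batch_histB, batch_steps)
    totA, totA_se = _batch_stats(batch_totA, batch_steps)
    totB, totB_se = _batch_stats(batch_totB, batch_steps)
    return BDResult(
        model=model,
        config=config,
        conc_A=countA / model.h_A,
        conc_A_se=countA_se / model.h_A,
        conc_B=countB / model.h_B,
        conc_B_se=countB_se / model.h_B,
        A_total=float(totA),
        A_total_se=float(totA_se),
        B_total=float(totB),
        B_total_se=float(totB_se),
        final_state=ParticleState(xA_fin, xB_fin, t=n_steps * config.dt),
    )
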