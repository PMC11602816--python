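"""Spatial error metrics, simulation-cost functions and Pareto analysis.

The error of a lattice solution is the L1 distance between its piecewise
constant concentration profile and a reference profile (analytic for the
first-order network, Brownian-dynamics-estimated for dimerization).  The
cost of a design point is the total stationary event propensity, which
sets the Gillespie iteration rate.  Sweeping design points ``(K_B, gamma)``
and extracting the Pareto front exposes the error/cost trade-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.integrate import quad

from mgrdme.model import FIRST_ORDER, MultiGridModel
from mgrdme.stationary import AnalyticProfile, analytic_profile, solve_stationary_means

__all__ = [
    "ConcentrationProfile",
    "ErrorCostRecord",
    "piecewise_profile",
    "l1_error",
    "total_count_error",
    "cost_first_order",
    "cost_dimerization",
    "sweep",
    "pareto_front",
]

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class ConcentrationProfile:
    """Piecewise-constant concentration over ``[0, L)``.

    ``values[i]`` holds on ``[edges[i], edges[i+1])``; optional per-bin
    standard errors propagate Monte-Carlo uncertainty of estimated
    profiles.
    """

    edges: np.ndarray
    values: np.ndarray
    values_se: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", np.asarray(self.edges, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.edges.size != self.values.size + 1:
            raise ValueError("edges must have len(values) + 1 entries")
        if not (np.diff(self.edges) > 0).all():
            raise ValueError("edges must be strictly increasing")

    @property
    def L(self) -> float:
        return float(self.edges[-1])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def counts(self) -> np.ndarray:
        """Mean molecule count per compartment (value times width)."""
        return self.values * self.widths

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        idx = np.clip(np.searchsorted(self.edges, x, side="right") - 1, 0, self.values.size - 1)
        out = self.values[idx]
        return float(out) if out.ndim == 0 else out

    def integral(self) -> float:
        return float(np.sum(self.counts))


def piecewise_profile(
    counts: np.ndarray, h: float, values_se: np.ndarray | None = None
) -> ConcentrationProfile:
    """Concentration profile from mean compartment counts on a uniform grid.

    Bin ``i`` covers ``[(i-1)h, ih)`` with value ``counts[i]/h``.
    """
    counts = np.asarray(counts, dtype=float)
    if h <= 0:
        raise ValueError(f"compartment size h must be > 0, got {h}")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    edges = h * np.arange(counts.size + 1)
    se = None if values_se is None else np.asarray(values_se, dtype=float) / h
    return ConcentrationProfile(edges=edges, values=counts / h, values_se=se)


def _l1_piecewise(reference: ConcentrationProfile, approx: ConcentrationProfile) -> float:
    edges = np.union1d(reference.edges, approx.edges)
    mid = 0.5 * (edges[:-1] + edges[1:])
    return float(np.sum(np.abs(reference(mid) - approx(mid)) * np.diff(edges)))


def l1_error(
    reference: AnalyticProfile | ConcentrationProfile | Callable,
    approx: ConcentrationProfile,
    quad_epsabs: float | None = None,
) -> float:
    """L1 distance between a reference profile and a piecewise approximation.

    ``int_0^L |reference(x) - approx(x)| dx``.  For a piecewise reference
    the integral is computed exactly on the merged breakpoint grid; for an
    analytic (callable) reference, per-compartment adaptive quadrature is
    used with absolute tolerance ``quad_epsabs`` per compartment (default
    ``1e-9 * max|approx|``, far below plotted differences).
    """
    if isinstance(reference, ConcentrationProfile):
        if not math.isclose(reference.L, approx.L, rel_tol=1e-9):
            raise ValueError(
                f"profile domains differ: [0, {reference.L}] vs [0, {approx.L}]"
            )
        return _l1_piecewise(reference, approx)
    scale = max(float(np.max(np.abs(approx.values))), 1.0)
    if quad_epsabs is None:
        quad_epsabs = 1e-9 * scale
    total = 0.0
    for lo, hi, v in zip(approx.edges[:-1], approx.edges[1:], approx.values):
        val, _ = quad(lambda x: abs(float(reference(x)) - v), lo, hi, epsabs=quad_epsabs, limit=200)
        total += val
    return total


def total_count_error(
    reference: AnalyticProfile | Callable, approx: ConcentrationProfile
) -> float:
    """Absolute difference in total molecule number over ``[0, L]``."""
    ref_total, _ = quad(lambda x: float(reference(x)), 0.0, approx.L, epsabs=1e-10, limit=200)
    return abs(approx.integral() - ref_total)


def cost_first_order(model: MultiGridModel) -> float:
    """Stationary-propensity cost of a first-order design point.

    ``3 k1 + 2 (D_A/h_A^2) (k1/k2) + 2 (D_B/h_B^2) (k1/k3)``: the total
    reaction propensity plus the diffusion-propensity bound, evaluated at
    the closed-form stationary totals.
    """
    if model.network != FIRST_ORDER:
        raise ValueError("cost_first_order requires the first-order network")
    return (
        3.0 * model.k1
        + 2.0 * model.d_A * model.k1 / model.k2
        + 2.0 * model.d_B * model.k1 / model.k3
    )


def cost_dimerization(model: MultiGridModel, A_total_est: float, B_total_est: float) -> float:
    """Stationary-propensity cost of a dimerization design point.

    ``2 d_A A_total + 2 d_B B_total + k1 + k2 A_total (A_total - 1) +
    k3 B_total`` with simulation-estimated stationary totals (no closed
    form exists for the dimerization network).
    """
    if A_total_est < 0 or B_total_est < 0:
        raise ValueError("estimated totals must be non-negative")
    return (
        2.0 * model.d_A * A_total_est
        + 2.0 * model.d_B * B_total_est
        + model.k1
        + model.k2 * A_total_est * (A_total_est - 1.0)
        + model.k3 * B_total_est
    )


@dataclass(frozen=True)
class ErrorCostRecord:
    """One ``(K_B, gamma)`` design point with its error and cost."""

    K_B: int
    gamma: float
    K_A: int
    err: float
    cost: float
    method: str  # "standard" (gamma == 1) or "multigrid"
    err_se: float | None = None
    err_A: float | None = None
    err_total: float | None = None

    def __post_init__(self) -> None:
        if self.err < 0:
            raise ValueError("err must be >= 0")
        if self.cost <= 0:
            raise ValueError("cost must be > 0")
        if (self.method == "standard") != (self.gamma == 1):
            raise ValueError("method 'standard' iff gamma == 1")


def _record_method(gamma: float) -> str:
    return "standard" if gamma == 1 else "multigrid"


def sweep(
    design_points: Iterable[tuple[int, float]],
    model_template: MultiGridModel,
    reference: AnalyticProfile | ConcentrationProfile | None = None,
    ssa_options: dict | None = None,
) -> list[ErrorCostRecord]:
    """Error and cost over a list of ``(K_B, gamma)`` design points.

    First-order network: each point is solved exactly and scored against
    the analytic B profile (computed from the template if ``reference`` is
    None).  Dimerization network: each point is estimated by Gillespie SSA
    (options ``t_end``, ``burn_in``, ``seeds`` in ``ssa_options``) and
    scored against the supplied reference (typically a BD-estimated
    profile); the cost uses the SSA-estimated stationary totals.
    """
    records: list[ErrorCostRecord] = []
    first_order = model_template.network == FIRST_ORDER
    if first_order and reference is None:
        reference = analytic_profile(model_template, "B")
    if reference is None:
        raise ValueError("a reference profile is required for the dimerization network")

    for K_B, gamma in design_points:
        K_A = K_B / gamma
        if abs(K_A - round(K_A)) > 1e-9:
            raise ValueError(f"gamma {gamma} does not divide K_B {K_B}")
        model = model_template.with_grids(K_A=int(round(K_A)), K_B=int(K_B))
        if first_order:
            sol = solve_stationary_means(model)
            profile = piecewise_profile(sol.Bbar, model.h_B)
            err = l1_error(reference, profile)
            records.append(
                ErrorCostRecord(
                    K_B=int(K_B),
                    gamma=float(gamma),
                    K_A=model.K_A,
                    err=err,
                    cost=cost_first_order(model),
                    method=_record_method(gamma),
                )
            )
        else:
            from mgrdme.ssa import estimate_steady_state, simulate

            opts = dict(ssa_options or {})
            t_end = opts.get("t_end", 1000.0)
            burn_in = opts.get("burn_in", 100.0)
            seeds = opts.get("seeds", (0, 1, 2))
            means_m = []
            means_n = []
            for seed in seeds:
                traj = simulate(
                    model, t_end=t_end, seed=seed, record="none",
                    burn_in=burn_in, init=opts.get("init", "poisson"),
                )
                mean_n, _, mean_m, _ = estimate_steady_state(traj)
                means_n.append(mean_n)
                means_m.append(mean_m)
            mean_n = np.mean(means_n, axis=0)
            mean_m = np.mean(means_m, axis=0)
            if len(seeds) > 1:
                se_m = np.std(means_m, axis=0, ddof=1) / math.sqrt(len(seeds))
            else:
                se_m = np.zeros_like(mean_m)
            profile = piecewise_profile(mean_m, model.h_B, values_se=se_m)
            err = l1_error(reference, profile)
            # error uncertainty: propagated sum of bin SEs times bin width
            err_se = float(np.sum(profile.values_se * profile.widths))
            A_tot, B_tot = float(mean_n.sum()), float(mean_m.sum())
            records.append(
                ErrorCostRecord(
                    K_B=int(K_B),
                    gamma=float(gamma),
                    K_A=model.K_A,
                    err=err,
                    err_se=err_se,
                    cost=cost_dimerization(model, A_tot, B_tot),
                    method=_record_method(gamma),
                )
            )
    return records


def pareto_front(records: Sequence[ErrorCostRecord]) -> list[ErrorCostRecord]:
    """Non-dominated subset under joint (err, cost) minimization.

    A record is dominated if another has err <= and cost <= with at least
    one strictly smaller; coordinates within 1e-12 count as equal, and tied
    records are all kept.  Sort-based scan, O(n log n).
    """
    if not records:
        raise ValueError("pareto_front requires at least one record")
    eps = _TIE_TOL
    order = sorted(range(len(records)), key=lambda i: (records[i].err, records[i].cost))
    keep = [False] * len(records)
    best_cost = math.inf  # min cost among strictly smaller-err records
    g = 0
    while g < len(order):
        # group records whose err ties the group head
        err0 = records[order[g]].err
        g_end = g
        while g_end < len(order) and records[order[g_end]].err <= err0 + eps:
            g_end += 1
        group = order[g:g_end]
        group_min = min(records[i].cost for i in group)
        for i in group:
            r = records[i]
            # survives its err-ties (cost within eps of the group minimum)
            # and every smaller-err record (strictly cheaper than all of them)
            if r.cost <= group_min + eps and r.cost < best_cost - eps:
                keep[i] = True
        best_cost = min(best_cost, group_min)
        g = g_end
    return [r for i, r in enumerate(records) if keep[i]]
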