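"""Exact stationary analysis of the compartment models.

For the first-order network the stationary law is a product of Poisson
distributions whose means solve two tridiagonal linear systems; analytic
infinite-domain concentration profiles are available in closed form.  A
brute-force generator on a truncated state space serves as a test oracle
for both networks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Literal

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.special import gammaln

from mgrdme.model import (
    DIMERIZATION,
    FIRST_ORDER,
    LatticeState,
    MultiGridModel,
    overlap_weights,
)

__all__ = [
    "StationarySolution",
    "AnalyticProfile",
    "diffusion_matrix_S",
    "solve_stationary_means",
    "poisson_product_pmf",
    "poisson_product_logpmf",
    "analytic_steady_state",
    "analytic_profile",
    "steady_state_propensities",
    "diffusion_propensity_exact",
    "truncated_generator",
    "GeneratorStationary",
]

_RESIDUAL_TOL = 1e-10
# below this relative size of D_A*k3 - D_B*k2 the closed-form B profile is
# evaluated through its confluent (equal-decay-length) limit
_DEGENERATE_RTOL = 1e-9


@dataclass(frozen=True)
class StationarySolution:
    """Stationary mean copy numbers per compartment.

    ``Abar`` has length ``K_A``, ``Bbar`` length ``K_B``.  For the
    first-order network these means fully characterise the stationary law
    (product-Poisson), and the totals obey ``A_total = k1/k2`` and
    ``B_total = k1/k3``.
    """

    Abar: np.ndarray
    Bbar: np.ndarray

    @property
    def A_total(self) -> float:
        return float(self.Abar.sum())

    @property
    def B_total(self) -> float:
        return float(self.Bbar.sum())


def diffusion_matrix_S(K: int) -> np.ndarray:
    """Symmetric tridiagonal jump-rate structure matrix (row sums 0).

    Off-diagonals are 1; the diagonal is -2 in the interior and -1 at both
    ends (one-sided jumps at the domain boundary).  ``K = 1`` gives the 1x1
    zero matrix.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    S = np.zeros((K, K))
    if K == 1:
        return S
    idx = np.arange(K - 1)
    S[idx, idx + 1] = 1.0
    S[idx + 1, idx] = 1.0
    S[np.arange(K), np.arange(K)] = -2.0
    S[0, 0] = -1.0
    S[-1, -1] = -1.0
    return S


def _solve_tridiagonal(A: sp.spmatrix, b: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        # singularity surfaces as a residual-check failure below
        warnings.simplefilter("ignore", spla.MatrixRankWarning)
        x = spla.spsolve(A.tocsc(), b)
    res = np.abs(A @ x - b).max()
    scale = max(1.0, np.abs(b).max())
    if not np.isfinite(x).all() or res > _RESIDUAL_TOL * scale:
        raise np.linalg.LinAlgError(
            f"stationary linear system solve failed (residual {res:.3e}); "
            "the system may be singular (all rates zero?)"
        )
    return x


def solve_stationary_means(model: MultiGridModel) -> StationarySolution:
    """Solve the stationary mean-count systems of the first-order network.

    ``(D_A/h_A^2 S_A - k2 I) Abar = -k1 e1`` and
    ``(D_B/h_B^2 S_B - k3 I) Bbar = -k2 W Abar`` with the overlap-weight
    matrix ``W`` (equal to ``M / gamma`` for integer ``gamma``).
    """
    if model.network != FIRST_ORDER:
        raise ValueError(
            "solve_stationary_means requires the first-order network; the "
            "dimerization network has no closed-form linear system "
            "(use ssa.simulate or stationary.truncated_generator)"
        )
    S_A = sp.csr_matrix(diffusion_matrix_S(model.K_A))
    S_B = sp.csr_matrix(diffusion_matrix_S(model.K_B))
    I_A = sp.identity(model.K_A, format="csr")
    I_B = sp.identity(model.K_B, format="csr")

    rhs_A = np.zeros(model.K_A)
    rhs_A[0] = -model.k1
    Abar = _solve_tridiagonal(model.d_A * S_A - model.k2 * I_A, rhs_A)

    W = overlap_weights(model)
    rhs_B = -model.k2 * (W @ Abar)
    Bbar = _solve_tridiagonal(model.d_B * S_B - model.k3 * I_B, rhs_B)
    return StationarySolution(Abar=Abar, Bbar=Bbar)


def poisson_product_logpmf(solution: StationarySolution, state: LatticeState) -> float:
    """Log of the product-Poisson stationary probability of ``state``."""
    if len(state.n) != len(solution.Abar) or len(state.m) != len(solution.Bbar):
        raise ValueError("state dimensions do not match the stationary solution")
    if (state.n < 0).any() or (state.m < 0).any():
        raise ValueError("copy numbers must be non-negative")
    logp = 0.0
    for mean, counts in ((solution.Abar, state.n), (solution.Bbar, state.m)):
        mean = np.asarray(mean, dtype=float)
        counts = np.asarray(counts)
        zero = mean == 0.0
        if (counts[zero] > 0).any():
            return -np.inf
        pos = ~zero
        logp += float(
            np.sum(counts[pos] * np.log(mean[pos]) - mean[pos] - gammaln(counts[pos] + 1.0))
        )
        # mean-zero compartments contribute exp(-0) = 1
    return logp


def poisson_product_pmf(solution: StationarySolution, state: LatticeState) -> float:
    """Stationary probability of ``state`` under the product-Poisson law."""
    return math.exp(poisson_product_logpmf(solution, state))


@dataclass(frozen=True)
class AnalyticProfile:
    """Analytic stationary concentration profile on the half-line.

    Wraps the closed-form solution of the first-order reaction-diffusion
    system on an unbounded domain with a point source at the origin; it is
    evaluated at ``|x|`` and decays to 0 at infinity.
    """

    species: Literal["A", "B"]
    func: Callable[[np.ndarray], np.ndarray]
    params: dict = field(default_factory=dict)

    def __call__(self, x):
        return self.func(np.abs(np.asarray(x, dtype=float)))


def _analytic_a(model: MultiGridModel):
    k1, k2, D_A = model.k1, model.k2, model.D_A
    alpha = math.sqrt(k2 / D_A)
    amp = k1 / math.sqrt(D_A * k2)

    def a_of_x(x):
        return amp * np.exp(-alpha * x)

    return a_of_x


def _analytic_b(model: MultiGridModel):
    k1, k2, k3 = model.k1, model.k2, model.k3
    D_A, D_B = model.D_A, model.D_B
    alpha = math.sqrt(k2 / D_A)
    beta = math.sqrt(k3 / D_B)
    denom = D_A * k3 - D_B * k2
    if abs(denom) <= _DEGENERATE_RTOL * (D_A * k3 + D_B * k2):
        # equal decay lengths (alpha == beta): confluent limit
        # b(x) = c (x + 1/alpha) exp(-alpha x) with c = k1 sqrt(k2/D_A) / (2 D_B alpha)
        c = k1 * math.sqrt(k2 / D_A) / (2.0 * D_B * beta)

        def b_of_x(x):
            return c * (x + 1.0 / beta) * np.exp(-beta * x)

        return b_of_x

    c1 = k1 * math.sqrt(k2 * D_A) / denom
    c2 = k1 * k2 * math.sqrt(D_B) / (-denom * math.sqrt(k3))

    def b_of_x(x):
        return c1 * np.exp(-alpha * x) + c2 * np.exp(-beta * x)

    return b_of_x


def analytic_profile(model: MultiGridModel, species: Literal["A", "B"]) -> AnalyticProfile:
    """Closed-form stationary concentration of A or B (first-order network).

    Warns when the infinite-domain profile is not negligible at ``x = L``
    (``a(L)/a(0) > 1e-3``), i.e. when the finite simulation domain is too
    short for the infinite-domain approximation to be a fair reference.
    """
    if model.network != FIRST_ORDER:
        raise ValueError(
            "no closed-form stationary profile for the dimerization network; "
            "use the brownian module to estimate the ground truth"
        )
    if species not in ("A", "B"):
        raise ValueError(f"species must be 'A' or 'B', got {species!r}")
    decay = math.sqrt(model.k2 / model.D_A) * model.L
    if math.exp(-decay) > 1e-3:
        warnings.warn(
            f"analytic profile not negligible at x=L (a(L)/a(0) = "
            f"{math.exp(-decay):.2e} > 1e-3); the finite-domain compartment "
            "model may deviate from the infinite-domain formula",
            stacklevel=2,
        )
    func = _analytic_a(model) if species == "A" else _analytic_b(model)
    return AnalyticProfile(species=species, func=func, params=model.to_dict())


def analytic_steady_state(model: MultiGridModel, species: Literal["A", "B"], x):
    """Evaluate the closed-form stationary concentration at position(s) x."""
    profile = analytic_profile(model, species)
    out = profile(x)
    return float(out) if np.isscalar(x) else out


def steady_state_propensities(
    model: MultiGridModel, solution: StationarySolution | None = None
) -> tuple[float, float]:
    """Total reaction propensity and diffusion-propensity upper bound.

    ``r_reac = k1 + k2 A_total + k3 B_total`` (equal to ``3 k1`` for the
    first-order network) and ``r_diff_bound = 2 d_A A_total + 2 d_B
    B_total``, the boundary-term-free bound used as the cost ingredient.
    """
    if solution is None:
        solution = solve_stationary_means(model)
    r_reac = model.k1 + model.k2 * solution.A_total + model.k3 * solution.B_total
    r_diff_bound = 2.0 * model.d_A * solution.A_total + 2.0 * model.d_B * solution.B_total
    return r_reac, r_diff_bound


def diffusion_propensity_exact(model: MultiGridModel, solution: StationarySolution) -> float:
    """Exact stationary diffusion propensity, with one-sided boundary terms."""
    A, B = solution.Abar, solution.Bbar
    return float(
        model.d_A * (2.0 * A.sum() - A[0] - A[-1])
        + model.d_B * (2.0 * B.sum() - B[0] - B[-1])
    )


@dataclass(frozen=True)
class GeneratorStationary:
    """Stationary law of the truncated master-equation generator.

    ``probs[s]`` is the stationary probability of the state with mixed-radix
    index ``s``; compartment counts are decoded with :meth:`decode`.
    """

    probs: np.ndarray
    caps_n: np.ndarray
    caps_m: np.ndarray

    @property
    def n_states(self) -> int:
        return self.probs.size

    def _radices(self) -> np.ndarray:
        return np.concatenate([self.caps_n + 1, self.caps_m + 1])

    def decode(self, s: int) -> tuple[np.ndarray, np.ndarray]:
        """Mixed-radix decode of flat state index ``s`` into ``(n, m)``."""
        radices = self._radices()
        digits = np.zeros(radices.size, dtype=np.int64)
        for k in range(radices.size - 1, -1, -1):
            digits[k] = s % radices[k]
            s //= radices[k]
        K_A = self.caps_n.size
        return digits[:K_A], digits[K_A:]

    def pmf(self, n, m) -> float:
        n = np.asarray(n, dtype=np.int64)
        m = np.asarray(m, dtype=np.int64)
        if (n > self.caps_n).any() or (m > self.caps_m).any() or (n < 0).any() or (m < 0).any():
            return 0.0
        radices = self._radices()
        s = 0
        for digit, radix in zip(np.concatenate([n, m]), radices):
            s = s * int(radix) + int(digit)
        return float(self.probs[s])

    def marginal_means(self) -> tuple[np.ndarray, np.ndarray]:
        """Stationary mean copy numbers per compartment."""
        K_A, K_B = self.caps_n.size, self.caps_m.size
        mean_n = np.zeros(K_A)
        mean_m = np.zeros(K_B)
        for s, p in enumerate(self.probs):
            if p == 0.0:
                continue
            n, m = self.decode(s)
            mean_n += p * n
            mean_m += p * m
        return mean_n, mean_m


def truncated_generator(
    model: MultiGridModel,
    max_counts: tuple[int | np.ndarray, int | np.ndarray],
    initial_state: LatticeState | None = None,
) -> GeneratorStationary:
    """Brute-force stationary law on a truncated state space (test oracle).

    Builds the full master-equation generator — diffusion jumps, localized
    production, overlap-weighted conversion/dimerization, degradation — on
    the box ``0 <= n_j <= caps_n[j]``, ``0 <= m_i <= caps_m[i]``.
    Transitions that would leave the box are dropped (reflecting
    truncation), keeping the generator a proper rate matrix, and the
    stationary distribution is obtained from its null space.
    """
    caps_n = np.broadcast_to(np.asarray(max_counts[0], dtype=np.int64), (model.K_A,)).copy()
    caps_m = np.broadcast_to(np.asarray(max_counts[1], dtype=np.int64), (model.K_B,)).copy()
    radices = np.concatenate([caps_n + 1, caps_m + 1])
    n_states = int(np.prod(radices.astype(object)))
    if n_states > 10**6:
        raise ValueError(
            f"truncated state space has {n_states} states (> 1e6); "
            "the generator oracle is for toy systems only"
        )

    K_A, K_B = model.K_A, model.K_B
    # stride of each digit in the flat mixed-radix index
    strides = np.ones(radices.size, dtype=np.int64)
    for k in range(radices.size - 2, -1, -1):
        strides[k] = strides[k + 1] * radices[k + 1]
    stride_n = strides[:K_A]
    stride_m = strides[K_A:]

    W = overlap_weights(model)
    d_A, d_B = model.d_A, model.d_B
    k1, k2, k3 = model.k1, model.k2, model.k3
    dimer = model.network == DIMERIZATION
    k2_eff = 0.5 * k2 / model.h_A if dimer else k2

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    diag = np.zeros(n_states)

    def add(s_from: int, s_to: int, rate: float) -> None:
        if rate <= 0.0:
            return
        rows.append(s_from)
        cols.append(s_to)
        vals.append(rate)
        diag[s_from] -= rate

    ranges = [range(r) for r in radices]
    for s, digits in enumerate(product(*ranges)):
        n = digits[:K_A]
        m = digits[K_A:]
        # production of A in the first A-compartment
        if n[0] < caps_n[0]:
            add(s, s + stride_n[0], k1)
        # A diffusion
        for j in range(K_A):
            if n[j] == 0:
                continue
            rate = d_A * n[j]
            if j > 0 and n[j - 1] < caps_n[j - 1]:
                add(s, s - stride_n[j] + stride_n[j - 1], rate)
            if j < K_A - 1 and n[j + 1] < caps_n[j + 1]:
                add(s, s - stride_n[j] + stride_n[j + 1], rate)
        # B diffusion
        for i in range(K_B):
            if m[i] == 0:
                continue
            rate = d_B * m[i]
            if i > 0 and m[i - 1] < caps_m[i - 1]:
                add(s, s - stride_m[i] + stride_m[i - 1], rate)
            if i < K_B - 1 and m[i + 1] < caps_m[i + 1]:
                add(s, s - stride_m[i] + stride_m[i + 1], rate)
        # conversion / dimerization, distributed over overlapping targets
        for j in range(K_A):
            if dimer:
                weight = n[j] * (n[j] - 1)
                if n[j] < 2 or weight <= 0:
                    continue
                dn = -2 * stride_n[j]
            else:
                if n[j] == 0:
                    continue
                weight = n[j]
                dn = -stride_n[j]
            for i in np.nonzero(W[:, j])[0]:
                if m[i] < caps_m[i]:
                    add(s, s + dn + stride_m[i], k2_eff * W[i, j] * weight)
        # degradation of B
        for i in range(K_B):
            if m[i] > 0:
                add(s, s - stride_m[i], k3 * m[i])

    if not vals:
        # no transitions at all: the chain never leaves its initial state
        probs = np.zeros(n_states)
        if initial_state is None:
            s0 = 0
        else:
            s0 = int(
                np.dot(stride_n, np.asarray(initial_state.n))
                + np.dot(stride_m, np.asarray(initial_state.m))
            )
        probs[s0] = 1.0
        return GeneratorStationary(probs=probs, caps_n=caps_n, caps_m=caps_m)

    G = sp.coo_matrix(
        (np.concatenate([np.asarray(vals), diag]),
         (np.concatenate([np.asarray(rows, dtype=np.int64), np.arange(n_states)]),
          np.concatenate([np.asarray(cols, dtype=np.int64), np.arange(n_states)]))),
        shape=(n_states, n_states),
    ).tocsr()

    # stationary pi solves pi G = 0, sum(pi) = 1: replace the first equation
    # of G^T pi = 0 with the normalization row
    A = G.T.tolil()
    A[0, :] = 1.0
    b = np.zeros(n_states)
    b[0] = 1.0
    pi = spla.spsolve(A.tocsc(), b)
    pi = np.clip(pi, 0.0, None)
    total = pi.sum()
    if not np.isfinite(total) or total <= 0:
        raise np.linalg.LinAlgError("null-space solve for the truncated generator failed")
    return GeneratorStationary(probs=pi / total, caps_n=caps_n, caps_m=caps_m)
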