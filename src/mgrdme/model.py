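"""Model objects for the dual-grid compartment lattice.

A model couples two species on the 1D domain ``[0, L]``: a fast species A
living on a coarse grid of ``K_A`` compartments and a slow species B on a
fine grid of ``K_B`` compartments.  The grids need not be nested: the
cross-species reaction distributes its product over B-compartments in
proportion to interval overlap, encoded by :func:`overlap_weights`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "MultiGridModel",
    "LatticeState",
    "CompartmentInterval",
    "make_model",
    "overlap_weights",
    "compartments",
]

FIRST_ORDER = "first_order"
DIMERIZATION = "dimerization"

# relative tolerance for floating-point interval intersections; avoids
# spurious zero-width overlaps at endpoints shared by both grids
_OVERLAP_RTOL = 1e-12


class ModelValidationError(ValueError):
    """Raised when a model configuration violates an invariant."""


@dataclass(frozen=True)
class MultiGridModel:
    """Domain, dual grids, network kind, and rate/diffusion parameters.

    Parameters
    ----------
    L : float
        Domain length.
    K_A, K_B : int
        Number of compartments for species A (coarse) and B (fine),
        ``K_B >= K_A``.
    D_A, D_B : float
        Diffusion constants, units [length^2 / time].
    k1 : float
        Production rate of A in the first A-compartment, [1/time].
    k2 : float
        Conversion rate [1/time] (first-order network) or dimerization
        rate constant [length/time] (dimerization network).
    k3 : float
        Degradation rate of B, [1/time].
    network : str
        ``"first_order"`` or ``"dimerization"``.
    doi_lambda, doi_rho : float, optional
        Doi-model reaction rate [1/time] and radius [length]; dimerization
        network only.  When given and ``k2`` is not, ``k2 = 2 * doi_rho *
        doi_lambda`` (the d=1 rate-bridging rule).
    """

    L: float
    K_A: int
    K_B: int
    D_A: float
    D_B: float
    k1: float
    k2: float
    k3: float
    network: str = FIRST_ORDER
    doi_lambda: float | None = None
    doi_rho: float | None = None

    def __post_init__(self) -> None:
        if self.network not in (FIRST_ORDER, DIMERIZATION):
            raise ModelValidationError(
                f"unknown network kind {self.network!r}; expected "
                f"{FIRST_ORDER!r} or {DIMERIZATION!r}"
            )
        if not (self.L > 0):
            raise ModelValidationError(f"domain length L must be > 0, got {self.L}")
        for name in ("K_A", "K_B"):
            k = getattr(self, name)
            if not (isinstance(k, (int, np.integer)) and k >= 1):
                raise ModelValidationError(f"{name} must be an integer >= 1, got {k!r}")
        if self.K_B < self.K_A:
            raise ModelValidationError(
                f"K_B ({self.K_B}) must be >= K_A ({self.K_A}): the B grid is "
                "the fine grid"
            )
        for name in ("D_A", "D_B", "k1", "k2", "k3"):
            v = getattr(self, name)
            if v < 0:
                raise ModelValidationError(f"{name} must be >= 0, got {v}")
        if self.network == DIMERIZATION:
            for name in ("doi_lambda", "doi_rho"):
                v = getattr(self, name)
                if v is not None and v < 0:
                    raise ModelValidationError(f"{name} must be >= 0, got {v}")

    @property
    def h_A(self) -> float:
        """Compartment size of the A grid, ``L / K_A``."""
        return self.L / self.K_A

    @property
    def h_B(self) -> float:
        """Compartment size of the B grid, ``L / K_B``."""
        return self.L / self.K_B

    @property
    def gamma(self) -> float:
        """Grid-size ratio ``K_B / K_A = h_A / h_B`` (need not be integer)."""
        return self.K_B / self.K_A

    @property
    def d_A(self) -> float:
        """Per-molecule diffusive jump rate of A, ``D_A / h_A**2``."""
        return self.D_A / self.h_A**2

    @property
    def d_B(self) -> float:
        """Per-molecule diffusive jump rate of B, ``D_B / h_B**2``."""
        return self.D_B / self.h_B**2

    def to_dict(self) -> dict:
        """Fully resolved parameter mapping (for manifests / provenance)."""
        d = {
            "network": self.network,
            "L": self.L,
            "K_A": self.K_A,
            "K_B": self.K_B,
            "h_A": self.h_A,
            "h_B": self.h_B,
            "gamma": self.gamma,
            "D_A": self.D_A,
            "D_B": self.D_B,
            "k1": self.k1,
            "k2": self.k2,
            "k3": self.k3,
        }
        if self.doi_lambda is not None:
            d["doi_lambda"] = self.doi_lambda
        if self.doi_rho is not None:
            d["doi_rho"] = self.doi_rho
        return d

    def with_grids(self, K_A: int | None = None, K_B: int | None = None) -> "MultiGridModel":
        """Copy of the model with different compartment counts."""
        return MultiGridModel(
            L=self.L,
            K_A=int(K_A if K_A is not None else self.K_A),
            K_B=int(K_B if K_B is not None else self.K_B),
            D_A=self.D_A,
            D_B=self.D_B,
            k1=self.k1,
            k2=self.k2,
            k3=self.k3,
            network=self.network,
            doi_lambda=self.doi_lambda,
            doi_rho=self.doi_rho,
        )


@dataclass
class LatticeState:
    """Copy numbers on the dual lattice: ``n`` (A, length K_A), ``m`` (B,
    length K_B) and the simulation time ``t``."""

    n: np.ndarray
    m: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=np.int64)
        self.m = np.asarray(self.m, dtype=np.int64)
        if self.n.ndim != 1 or self.m.ndim != 1:
            raise ValueError("n and m must be 1D vectors")
        if (self.n < 0).any() or (self.m < 0).any():
            raise ValueError("copy numbers must be non-negative")

    @classmethod
    def empty(cls, model: MultiGridModel, t: float = 0.0) -> "LatticeState":
        return cls(np.zeros(model.K_A, dtype=np.int64), np.zeros(model.K_B, dtype=np.int64), t)

    def validate_against(self, model: MultiGridModel) -> None:
        if len(self.n) != model.K_A or len(self.m) != model.K_B:
            raise ValueError(
                f"state dimensions ({len(self.n)}, {len(self.m)}) do not match "
                f"model grids ({model.K_A}, {model.K_B})"
            )


@dataclass(frozen=True)
class CompartmentInterval:
    """One half-open compartment ``[lo, hi)``, 1-based ``index``."""

    index: int
    lo: float
    hi: float

    @property
    def width(self) -> float:
        return self.hi - self.lo


def compartments(L: float, K: int) -> list[CompartmentInterval]:
    """The K half-open intervals ``[(i-1)h, i h)`` tiling ``[0, L)``."""
    h = L / K
    return [CompartmentInterval(i + 1, i * h, (i + 1) * h) for i in range(K)]


def _flatten_config(config: Mapping) -> dict:
    """Accept both flat and sectioned (domain/rates/diffusion) mappings."""
    flat: dict = {}
    for key, value in config.items():
        if key in ("domain", "rates", "diffusion") and isinstance(value, Mapping):
            flat.update(value)
        else:
            flat[key] = value
    # common aliases
    if "lambda" in flat:
        flat.setdefault("doi_lambda", flat.pop("lambda"))
    if "rho" in flat:
        flat.setdefault("doi_rho", flat.pop("rho"))
    return flat


def make_model(config: Mapping) -> MultiGridModel:
    """Build and validate a :class:`MultiGridModel` from a key-value mapping.

    The mapping may be flat or organised into ``domain`` (L, K_A, K_B),
    ``rates`` (k1, k2, k3 or k1, lambda, rho, k3), ``diffusion`` (D_A, D_B)
    and ``network`` sections.  For the dimerization network, if ``doi_lambda``
    and ``doi_rho`` are supplied and ``k2`` is not, the bimolecular rate
    constant is derived as ``k2 = 2 * doi_rho * doi_lambda``.
    """
    flat = _flatten_config(config)
    network = flat.get("network", FIRST_ORDER)

    if "K" in flat and "K_A" not in flat and "K_B" not in flat:
        flat["K_A"] = flat["K_B"] = flat.pop("K")

    required = ["L", "K_A", "K_B", "D_A", "D_B", "k1", "k3"]
    missing = [k for k in required if k not in flat]
    doi_lambda = flat.get("doi_lambda")
    doi_rho = flat.get("doi_rho")
    k2 = flat.get("k2")
    if k2 is None:
        if network == DIMERIZATION and doi_lambda is not None and doi_rho is not None:
            k2 = 2.0 * float(doi_rho) * float(doi_lambda)
        else:
            missing.append("k2 (or doi_lambda and doi_rho for dimerization)")
    if missing:
        raise ModelValidationError(f"missing required model fields: {', '.join(missing)}")

    return MultiGridModel(
        L=float(flat["L"]),
        K_A=int(flat["K_A"]),
        K_B=int(flat["K_B"]),
        D_A=float(flat["D_A"]),
        D_B=float(flat["D_B"]),
        k1=float(flat["k1"]),
        k2=float(k2),
        k3=float(flat["k3"]),
        network=network,
        doi_lambda=None if doi_lambda is None else float(doi_lambda),
        doi_rho=None if doi_rho is None else float(doi_rho),
    )


def overlap_weights(model: MultiGridModel) -> np.ndarray:
    """Overlap-weight matrix ``W`` of shape ``(K_B, K_A)``.

    ``W[i, j] = |C_i^(B) ∩ C_j^(A)| / |C_j^(A)|`` is the fraction of the
    j-th (coarse) A-compartment covered by the i-th (fine) B-compartment.
    Every column sums to 1, so the cross-species reaction rate carried by an
    A molecule is shared among overlapping B-compartments without loss.  For
    integer ``gamma = K_B / K_A`` the matrix has exactly ``gamma`` nonzero
    entries of value ``1/gamma`` per column, in consecutive rows.
    """
    K_A, K_B = model.K_A, model.K_B
    h_A, h_B = model.h_A, model.h_B
    tol = _OVERLAP_RTOL * model.L
    W = np.zeros((K_B, K_A))
    for j in range(K_A):
        lo_A, hi_A = j * h_A, (j + 1) * h_A
        # only B-compartments that can intersect column j
        i_lo = max(0, int(np.floor(lo_A / h_B)) - 1)
        i_hi = min(K_B, int(np.ceil(hi_A / h_B)) + 1)
        for i in range(i_lo, i_hi):
            lo = max(lo_A, i * h_B)
            hi = min(hi_A, (i + 1) * h_B)
            if hi - lo > tol:
                W[i, j] = (hi - lo) / h_A
    # clean up rounding so columns sum to exactly 1
    W /= W.sum(axis=0, keepdims=True)
    return W


def overlap_weights_csc(model: MultiGridModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-compressed form of :func:`overlap_weights`.

    Returns ``(indptr, rows, vals)`` such that for A-compartment ``j`` the
    overlapping B-compartments are ``rows[indptr[j]:indptr[j+1]]`` with
    weights ``vals[indptr[j]:indptr[j+1]]`` (summing to 1).  Used by the
    simulation kernels.
    """
    W = overlap_weights(model)
    indptr = [0]
    rows: list[int] = []
    vals: list[float] = []
    for j in range(model.K_A):
        nz = np.nonzero(W[:, j])[0]
        rows.extend(nz.tolist())
        vals.extend(W[nz, j].tolist())
        indptr.append(len(rows))
    return (
        np.asarray(indptr, dtype=np.int64),
        np.asarray(rows, dtype=np.int64),
        np.asarray(vals, dtype=np.float64),
    )
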