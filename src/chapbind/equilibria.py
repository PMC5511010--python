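"""Multi-equilibrium speciation for chaperone binding to a marginally stable client.

The client protein exchanges between a native state ``N`` and an unfolded
state ``U`` with folding constant ``K_UN = [N]/[U]``; only ``U`` is binding
competent.  Two binding schemes are supported:

* **linear** — sequential binding, ``U + K <=> UK`` (Kd1) followed by
  ``UK + K <=> UK2`` (Kd2);
* **square** — two independent sites A and B, ``U + K <=> UKA`` (Kd1),
  ``U + K <=> UKB`` (Kd2), either of which binds a second chaperone to give
  the doubly bound ``UKAB`` with the opposite-arm constants equal.

For either scheme mass balance reduces to a cubic in the free chaperone
concentration ``x = [K]``::

    a x^3 + b x^2 + c x + d = 0

with (linear)  a = K1*K2, b = K1 + K1*K2*(2*N_T - K_T),
               c = 1 + K_UN + K1*(N_T - K_T), d = -(1 + K_UN)*K_T
and  (square)  a = K1*K2, b = K1 + K2 + K1*K2*(2*N_T - K_T),
               c = 1 + K_UN + (K1 + K2)*(N_T - K_T), d = -(1 + K_UN)*K_T

where K1 = 1/Kd1 and K2 = 1/Kd2 are association constants and ``N_T``,
``K_T`` are total client and chaperone concentrations (molar throughout).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BindingModel",
    "EquilibriumParams",
    "MixtureTotals",
    "CubicCoefficients",
    "SpeciesConcentrations",
    "cubic_coefficients",
    "solve_free_chaperone",
    "solve_free_chaperone_oracle",
    "species_concentrations",
]

#: relative tolerance on mass balance guaranteed by the solvers
MASS_BALANCE_RTOL = 1e-9


class BindingModel(enum.Enum):
    """Binding scheme: sequential (linear) or two independent sites (square)."""

    LINEAR = "linear"
    SQUARE = "square"


class InvalidParameterError(ValueError):
    """Raised for non-finite or out-of-domain model inputs."""


class InternalConsistencyError(RuntimeError):
    """Raised when no physically admissible root exists (should not happen)."""


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if math.isnan(value) or (math.isinf(value) and value < 0):
        raise InvalidParameterError(f"{name} must be finite (or +inf for a Kd); got {value}")
    return value


@dataclass(frozen=True)
class EquilibriumParams:
    """Folding constant and site dissociation constants.

    Parameters
    ----------
    K_UN : float
        Dimensionless folding equilibrium constant ``[N]/[U]`` of the free
        client.  Must be >= 0.
    Kd1, Kd2 : float
        Molar dissociation constants of the first and second binding steps
        (linear scheme) or of sites A and B (square scheme).  Must be > 0;
        ``math.inf`` disables a step.
    """

    K_UN: float
    Kd1: float
    Kd2: float

    def __post_init__(self) -> None:
        for name in ("K_UN", "Kd1", "Kd2"):
            _require_finite(name, getattr(self, name))
        if self.K_UN < 0:
            raise InvalidParameterError(f"K_UN must be >= 0; got {self.K_UN}")
        if self.Kd1 <= 0 or self.Kd2 <= 0:
            raise InvalidParameterError("Kd1 and Kd2 must be > 0 (use inf to disable)")

    @property
    def K1(self) -> float:
        """Association constant of step/site 1 (1/M); 0 if Kd1 is infinite."""
        return 0.0 if math.isinf(self.Kd1) else 1.0 / self.Kd1

    @property
    def K2(self) -> float:
        """Association constant of step/site 2 (1/M); 0 if Kd2 is infinite."""
        return 0.0 if math.isinf(self.Kd2) else 1.0 / self.Kd2


@dataclass(frozen=True)
class MixtureTotals:
    """Total (all species) molar concentrations of client and chaperone."""

    N_T: float
    K_T: float

    def __post_init__(self) -> None:
        for name in ("N_T", "K_T"):
            v = _require_finite(name, getattr(self, name))
            if math.isinf(v) or v < 0:
                raise InvalidParameterError(f"{name} must be finite and >= 0; got {v}")

    @property
    def ratio(self) -> float:
        """Total-concentration ratio K_T / N_T (inf when N_T == 0)."""
        return math.inf if self.N_T == 0 else self.K_T / self.N_T


@dataclass(frozen=True)
class CubicCoefficients:
    """Coefficients of ``a x^3 + b x^2 + c x + d = 0`` in free chaperone x."""

    a: float
    b: float
    c: float
    d: float

    def __call__(self, x: float) -> float:
        return ((self.a * x + self.b) * x + self.c) * x + self.d


@dataclass(frozen=True)
class SpeciesConcentrations:
    """Equilibrium molar concentrations of every species in the mixture.

    ``UK``/``UK2`` are populated for the linear scheme, ``UKA``/``UKB``/
    ``UKAB`` for the square scheme; the unused set is zero.
    """

    model: BindingModel
    N: float
    U: float
    K: float
    UK: float = 0.0
    UK2: float = 0.0
    UKA: float = 0.0
    UKB: float = 0.0
    UKAB: float = 0.0

    def as_dict(self) -> dict[str, float]:
        """Species name -> concentration, restricted to the active scheme."""
        base = {"N": self.N, "U": self.U, "K": self.K}
        if self.model is BindingModel.LINEAR:
            base.update(UK=self.UK, UK2=self.UK2)
        else:
            base.update(UKA=self.UKA, UKB=self.UKB, UKAB=self.UKAB)
        return base

    @property
    def client_total(self) -> float:
        return self.N + self.U + self.UK + self.UK2 + self.UKA + self.UKB + self.UKAB

    @property
    def chaperone_total(self) -> float:
        return self.K + self.UK + 2 * self.UK2 + self.UKA + self.UKB + 2 * self.UKAB

    @property
    def bound_1to1(self) -> float:
        """Total concentration of singly bound (1:1) complexes."""
        return self.UK + self.UKA + self.UKB

    @property
    def bound_2to1(self) -> float:
        """Concentration of the doubly bound (2:1 chaperone:client) complex."""
        return self.UK2 + self.UKAB


def _binding_polynomial_coeffs(params: EquilibriumParams, model: BindingModel) -> tuple[float, float]:
    """Return (p1, p2) such that the client partition over binding states is
    ``1 + K_UN + p1*x + p2*x**2`` and bound chaperone is ``U*(p1*x + 2*p2*x**2)``."""
    K1, K2 = params.K1, params.K2
    if model is BindingModel.LINEAR:
        return K1, K1 * K2
    return K1 + K2, K1 * K2


def cubic_coefficients(
    params: EquilibriumParams, totals: MixtureTotals, model: BindingModel
) -> CubicCoefficients:
    """Coefficients of the free-chaperone cubic for the requested scheme."""
    p1, p2 = _binding_polynomial_coeffs(params, model)
    N_T, K_T = totals.N_T, totals.K_T
    a = params.K1 * params.K2
    b = p1 + a * (2 * N_T - K_T)
    c = 1 + params.K_UN + p1 * (N_T - K_T)
    d = -(1 + params.K_UN) * K_T
    return CubicCoefficients(a, b, c, d)


def _mass_balance_residual(
    x: float, params: EquilibriumParams, totals: MixtureTotals, model: BindingModel
) -> float:
    """g(x) = x + bound chaperone(x) - K_T; strictly increasing on [0, K_T]."""
    p1, p2 = _binding_polynomial_coeffs(params, model)
    denom = 1 + params.K_UN + p1 * x + p2 * x * x
    U = totals.N_T / denom
    return x + U * (p1 * x + 2 * p2 * x * x) - totals.K_T


def solve_free_chaperone_oracle(
    params: EquilibriumParams, totals: MixtureTotals, model: BindingModel
) -> float:
    """Free chaperone by bracketed root-finding on the mass-balance residual.

    ``g(0) = -K_T <= 0`` and ``g(K_T) >= 0`` always, so a bracket exists for
    every valid input.  Independent of the cubic path; used for verification.
    """
    K_T = totals.K_T
    if K_T == 0:
        return 0.0
    p1, _ = _binding_polynomial_coeffs(params, model)
    if K_T < 1e-30:
        # far below any physical concentration the residual is linear in x
        # to double precision (quadratic terms are O(p1*x) < 1e-18 relative)
        return K_T / (1.0 + totals.N_T * p1 / (1.0 + params.K_UN))
    g0 = _mass_balance_residual(0.0, params, totals, model)
    g1 = _mass_balance_residual(K_T, params, totals, model)
    if g0 > 0 or g1 < 0:
        raise InternalConsistencyError("mass-balance residual not bracketed on [0, K_T]")
    if g1 == 0.0:
        return K_T
    # xtol scales with the bracket so convergence is well defined even for
    # vanishingly small chaperone totals
    return brentq(
        _mass_balance_residual, 0.0, K_T, args=(params, totals, model),
        xtol=max(K_T * 1e-18, 5e-324), rtol=8.9e-16, maxiter=500,
    )


def solve_free_chaperone(
    params: EquilibriumParams, totals: MixtureTotals, model: BindingModel
) -> float:
    """Free chaperone concentration as the physical root of the cubic.

    Real roots are enumerated; the (provably unique) one in ``[0, K_T]`` is
    kept and polished by Newton iteration on the cubic.  Degenerate inputs
    (``K_T = 0``, no binding, ``N_T = 0``) are handled analytically.
    """
    K_T = totals.K_T
    if K_T == 0:
        return 0.0
    if (params.K1 == 0 and params.K2 == 0) or totals.N_T == 0:
        return K_T  # nothing binds: free == total
    coeffs = cubic_coefficients(params, totals, model)
    poly = [coeffs.a, coeffs.b, coeffs.c, coeffs.d]
    # strip leading zeros so np.roots sees the true degree
    while len(poly) > 1 and poly[0] == 0.0:
        poly = poly[1:]
    roots = np.roots(poly) if len(poly) > 1 else np.array([])
    tol = 1e-12 * K_T
    candidates = sorted(
        float(r.real)
        for r in roots
        if abs(r.imag) <= 1e-9 * max(1.0, abs(r.real)) and -tol <= r.real <= K_T + tol
    )
    if not candidates:
        # floating-point noise pushed the root off the admissible interval
        return solve_free_chaperone_oracle(params, totals, model)
    x = min(max(candidates[0], 0.0), K_T)
    # Newton polish on the cubic for full double precision
    a, b, c = coeffs.a, coeffs.b, coeffs.c
    for _ in range(3):
        f = coeffs(x)
        fp = (3 * a * x + 2 * b) * x + c
        if fp == 0:
            break
        step = f / fp
        x_new = x - step
        if not (0.0 <= x_new <= K_T):
            break
        x = x_new
        if abs(step) <= 1e-17 * max(x, 1e-300):
            break
    if x < 0 or x > K_T:
        raise InternalConsistencyError("no cubic root in [0, K_T]")
    return x


def species_concentrations(
    params: EquilibriumParams, totals: MixtureTotals, model: BindingModel
) -> SpeciesConcentrations:
    """All equilibrium species concentrations at the given totals.

    The free chaperone is solved via the cubic, then back-substituted into
    the equilibrium-constant expressions: ``U`` from the client mass balance,
    ``N = K_UN*U``, and the complexes from ``K1``/``K2`` times ``U`` and
    powers of the free chaperone.
    """
    x = solve_free_chaperone(params, totals, model)
    p1, p2 = _binding_polynomial_coeffs(params, model)
    U = totals.N_T / (1 + params.K_UN + p1 * x + p2 * x * x)
    N = params.K_UN * U
    K1, K2 = params.K1, params.K2
    if model is BindingModel.LINEAR:
        return SpeciesConcentrations(
            model=model, N=N, U=U, K=x,
            UK=K1 * U * x, UK2=K1 * K2 * U * x * x,
        )
    return SpeciesConcentrations(
        model=model, N=N, U=U, K=x,
        UKA=K1 * U * x, UKB=K2 * U * x, UKAB=K1 * K2 * U * x * x,
    )
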