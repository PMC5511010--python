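"""Auxiliary spectroscopic computations.

Rotamer populations from methyl carbon shifts, HMQC relaxation-loss
estimates from linewidth differences, pulsed-field-gradient diffusion decay
fitting, symmetric two-site magnetization exchange (and the off-rate bound
its non-observation implies), and two-state folding kinetics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

__all__ = [
    "RotamerReferenceShifts",
    "RotamerFractions",
    "DiffusionSeries",
    "ExchangeParams",
    "KineticTrajectory",
    "rotamer_fractions",
    "relaxation_loss_fraction",
    "fit_diffusion_decay",
    "exchange_crosspeak_ratio",
    "exchange_intensities",
    "koff_upper_bound",
    "simulate_folding",
    "fit_single_exponential",
    "DEFAULT_JCH_HZ",
    "hmqc_transfer_time",
]

#: one-bond 1H-13C scalar coupling of a methyl group, Hz
DEFAULT_JCH_HZ = 125.0


@dataclass(frozen=True)
class RotamerReferenceShifts:
    """Limiting Ile 13C-delta1 shifts of the pure chi2 rotamers (ppm).

    Defaults are the standard limits used for shift-based chi2 rotamer
    estimation: 14.8 ppm for pure trans, 9.3 ppm for pure gauche-.
    """

    delta_trans: float = 14.8
    delta_gauche: float = 9.3

    def __post_init__(self) -> None:
        if self.delta_trans == self.delta_gauche:
            raise ValueError("reference shifts must differ")


@dataclass(frozen=True)
class RotamerFractions:
    p_trans: float
    p_gauche: float


@dataclass(frozen=True)
class DiffusionSeries:
    """Gradient strengths (G/cm) and peak intensities of a PFG experiment."""

    G: np.ndarray
    I: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "G", np.asarray(self.G, dtype=float))
        object.__setattr__(self, "I", np.asarray(self.I, dtype=float))
        if self.G.shape != self.I.shape:
            raise ValueError("G and I must have the same shape")
        if np.any(self.G < 0):
            raise ValueError("gradient strengths must be >= 0")
        if np.unique(self.G).size < 3:
            raise ValueError("need at least 3 distinct gradient strengths")


@dataclass(frozen=True)
class ExchangeParams:
    """Symmetric two-site exchange rate, longitudinal relaxation, mixing time."""

    k_ex: float
    R1: float
    t_mix: float

    def __post_init__(self) -> None:
        if self.k_ex < 0 or self.R1 < 0 or self.t_mix < 0:
            raise ValueError("k_ex, R1 and t_mix must all be >= 0")


@dataclass(frozen=True)
class KineticTrajectory:
    """Time grid (s) and per-state populations (columns sum to 1)."""

    t: np.ndarray
    populations: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        total = sum(np.asarray(p) for p in self.populations.values())
        if np.any(np.abs(total - 1.0) > 1e-9):
            raise ValueError("state populations must sum to 1 at every time point")


def rotamer_fractions(
    delta_obs: float, refs: RotamerReferenceShifts = RotamerReferenceShifts()
) -> RotamerFractions:
    """Trans/gauche- chi2 populations from an observed 13C shift.

    Linear two-state interpolation between the pure-rotamer reference
    shifts, clamped to [0, 1] (observed shifts can fall slightly outside
    the reference window).
    """
    p = (delta_obs - refs.delta_gauche) / (refs.delta_trans - refs.delta_gauche)
    p = min(max(p, 0.0), 1.0)
    return RotamerFractions(p_trans=p, p_gauche=1.0 - p)


def hmqc_transfer_time(J_CH_hz: float = DEFAULT_JCH_HZ) -> float:
    """Total constant-time HMQC transfer duration (s).

    Two INEPT-style transfer periods of 1/(2J) each, so 1/J in total:
    8 ms for a methyl one-bond coupling of 125 Hz.
    """
    return 1.0 / J_CH_hz


def relaxation_loss_fraction(delta_nu_hz: float, T_transfer_s: float) -> float:
    """Relative signal loss from a linewidth difference during HMQC transfers.

    A Lorentzian linewidth difference ``delta_nu`` (Hz) corresponds to a
    transverse-rate difference ``pi*delta_nu``; over the constant-time
    transfer periods (total duration ``T_transfer``) the extra loss is
    ``1 - exp(-pi*delta_nu*T_transfer)``.
    """
    if delta_nu_hz < 0 or T_transfer_s < 0:
        raise ValueError("linewidth difference and transfer time must be >= 0")
    return 1.0 - math.exp(-math.pi * delta_nu_hz * T_transfer_s)


def fit_diffusion_decay(series: DiffusionSeries) -> tuple[float, float]:
    """Fit ``I = I0 * exp(-d * G**2)`` to a gradient series.

    A log-linear least-squares fit of ``ln I`` against ``G**2`` seeds a
    nonlinear refinement of the exponential form.  Returns ``(I0, d)``.
    """
    if np.any(series.I <= 0):
        raise ValueError("all intensities must be > 0")
    G2 = series.G**2
    slope, intercept = np.polyfit(G2, np.log(series.I), 1)
    p0 = (math.exp(intercept), -slope)
    with warnings.catch_warnings():
        # the covariance is singular for degenerate (e.g. constant) data;
        # only the point estimate is used
        warnings.simplefilter("ignore", OptimizeWarning)
        popt, _ = curve_fit(
            lambda g2, I0, d: I0 * np.exp(-d * g2), G2, series.I, p0=p0,
            maxfev=10000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    return float(popt[0]), float(popt[1])


def exchange_crosspeak_ratio(params: ExchangeParams) -> float:
    """Crosspeak share of total longitudinal signal after mixing.

    For symmetric equal-population two-site exchange with uniform R1, the
    magnetization that has hopped site an odd number of times by ``t_mix``
    is ``(1 - exp(-2*k_ex*t_mix))/2``; R1 damps diagonal and crosspeak
    equally and cancels in the ratio.
    """
    return 0.5 * (1.0 - math.exp(-2.0 * params.k_ex * params.t_mix))


def exchange_intensities(params: ExchangeParams) -> tuple[float, float]:
    """Absolute (diagonal, crosspeak) intensities including R1 damping."""
    damp = math.exp(-params.R1 * params.t_mix)
    frac = exchange_crosspeak_ratio(params)
    return damp * (1.0 - frac), damp * frac


def koff_upper_bound(detection_threshold: float, t_mix: float) -> float:
    """Exchange-rate bound implied by the absence of exchange crosspeaks.

    Crosspeaks below ``detection_threshold`` (as a fraction of the total
    longitudinal signal) are invisible, so non-observation at mixing time
    ``t_mix`` bounds the off-rate by the ``k_ex`` at which the crosspeak
    fraction equals the threshold: ``-ln(1 - 2*thr) / (2*t_mix)``.
    """
    if not (0 < detection_threshold < 0.5):
        raise ValueError("threshold must lie in (0, 0.5): the ratio saturates at 1/2")
    if t_mix <= 0:
        raise ValueError("t_mix must be > 0")
    return -math.log(1.0 - 2.0 * detection_threshold) / (2.0 * t_mix)


def simulate_folding(
    k_fold: float, k_unfold: float, U0: float, t: np.ndarray
) -> KineticTrajectory:
    """Two-state folding kinetics ``U <-> N``.

    Solves ``dU/dt = -k_fold*U + k_unfold*N`` with ``N = 1 - U`` exactly:
    ``U(t) = U_inf + (U0 - U_inf) * exp(-(k_fold + k_unfold) * t)`` with
    ``U_inf = k_unfold / (k_fold + k_unfold)`` (``U_inf = 0`` when both
    rates vanish is moot: populations are then constant).
    """
    if k_fold < 0 or k_unfold < 0:
        raise ValueError("rates must be >= 0")
    if not (0 <= U0 <= 1):
        raise ValueError("U0 must be a fraction in [0, 1]")
    t = np.asarray(t, dtype=float)
    lam = k_fold + k_unfold
    if lam == 0:
        U = np.full_like(t, U0)
    else:
        U_inf = k_unfold / lam
        U = U_inf + (U0 - U_inf) * np.exp(-lam * t)
    return KineticTrajectory(t=t, populations={"U": U, "N": 1.0 - U})


def fit_single_exponential(
    trajectory: KineticTrajectory, observable: str = "N"
) -> float:
    """Rate of a saturating single-exponential ``A*(1 - exp(-lam*t)) + C``.

    Fits the named state population and returns the relaxation rate
    ``lam`` (s^-1); exact on noiseless two-state trajectories, where
    ``lam = k_fold + k_unfold``.
    """
    if trajectory.t.size < 5:
        raise ValueError("need at least 5 time points")
    y = np.asarray(trajectory.populations[observable], dtype=float)
    t = trajectory.t
    span = y[-1] - y[0]
    if span == 0:
        raise ValueError("flat trajectory: no rate to fit")
    # crude rate guess from the 63% crossing of the span
    target = y[0] + 0.632 * span
    idx = np.argmin(np.abs(y - target))
    lam0 = 1.0 / max(t[idx], (t[1] - t[0]))
    popt, _ = curve_fit(
        lambda tt, A, lam, C: A * (1.0 - np.exp(-lam * tt)) + C,
        t, y, p0=(span, lam0, y[0]), maxfev=20000,
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    return float(popt[1])
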