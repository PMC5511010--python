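"""Serial volume-replacement titration simulation.

The experimental protocol removes an aliquot of the sample and replaces it
with an equal volume of chaperone stock: the total volume is constant, the
client dilutes geometrically, and the chaperone total relaxes toward the
stock concentration.  One replacement step with volume fraction ``f``
updates the totals as::

    N_T' = N_T * (1 - f)
    K_T' = K_T * (1 - f) + f * K_stock

Species concentrations at each point come from :mod:`chapbind.equilibria`.
A dense-grid mode evaluates the model on the continuous-replacement limit
of the same protocol, giving smooth concentration profiles against the
total-concentration ratio ``K_T/N_T`` so profile maxima can be located to
better than the experimental point spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .equilibria import (
    BindingModel,
    EquilibriumParams,
    InvalidParameterError,
    MixtureTotals,
    SpeciesConcentrations,
    species_concentrations,
)

__all__ = [
    "TitrationProtocol",
    "TitrationPoint",
    "SpeciesProfile",
    "advance_totals",
    "plan_protocol",
    "run_titration",
    "dense_ratio_totals",
    "run_dense_titration",
    "profile_maximum",
    "DEFAULT_TARGET_RATIOS",
]

#: default chaperone:client total-concentration ratios visited by a titration
DEFAULT_TARGET_RATIOS = (0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 2.0, 2.5, 3.0, 4.0)


class UnreachableRatioError(ValueError):
    """A target ratio cannot be reached with a replaced-volume fraction in [0, 1)."""


class InsufficientDataError(ValueError):
    """Too few points for the requested profile analysis."""


@dataclass(frozen=True)
class TitrationProtocol:
    """Initial client total, chaperone stock, and ordered replacement fractions."""

    N_T0: float
    K_stock: float
    steps: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (self.N_T0 > 0 and self.K_stock > 0):
            raise InvalidParameterError("N_T0 and K_stock must be > 0")
        for f in self.steps:
            if not (0 <= f < 1):
                raise InvalidParameterError(f"replaced-volume fraction {f} outside [0, 1)")


@dataclass(frozen=True)
class TitrationPoint:
    index: int
    totals: MixtureTotals

    @property
    def ratio(self) -> float:
        return self.totals.ratio


@dataclass
class SpeciesProfile:
    """Ordered (point, speciation) records along a titration."""

    records: list[tuple[TitrationPoint, SpeciesConcentrations]] = field(default_factory=list)

    @property
    def ratios(self) -> np.ndarray:
        return np.array([pt.ratio for pt, _ in self.records])

    def species_series(self, name: str) -> np.ndarray:
        """Concentration of one species (by name) at every titration point."""
        return np.array([sp.as_dict()[name] for _, sp in self.records])

    def population_series(self, name: str) -> np.ndarray:
        """Fraction of total client held by one species at every point.

        Dividing by the (diluting) client total removes the dilution factor
        of the replacement protocol; the population of a 1:1 complex peaks
        at the stoichiometric ratio K_T/N_T = 1, whereas its raw
        concentration peaks earlier because the client is diluted as
        chaperone is added.
        """
        return np.array(
            [sp.as_dict()[name] / pt.totals.N_T for pt, sp in self.records]
        )

    def bound_1to1_series(self, population: bool = False) -> np.ndarray:
        """Total singly bound (1:1) complex, concentration or client fraction."""
        out = np.array([sp.bound_1to1 for _, sp in self.records])
        if population:
            out = out / np.array([pt.totals.N_T for pt, _ in self.records])
        return out

    def bound_2to1_series(self, population: bool = False) -> np.ndarray:
        """Doubly bound (2:1) complex, concentration or client fraction."""
        out = np.array([sp.bound_2to1 for _, sp in self.records])
        if population:
            out = out / np.array([pt.totals.N_T for pt, _ in self.records])
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: step, ratio, N_T_M, K_T_M, species, conc_M."""
        rows = []
        for pt, sp in self.records:
            for name, conc in sp.as_dict().items():
                rows.append(
                    dict(step=pt.index, ratio=pt.ratio, N_T_M=pt.totals.N_T,
                         K_T_M=pt.totals.K_T, species=name, conc_M=conc)
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")


def advance_totals(totals: MixtureTotals, f: float, K_stock: float) -> MixtureTotals:
    """Totals after one replacement of volume fraction ``f`` with stock."""
    if not (0 <= f < 1):
        raise InvalidParameterError(f"replaced-volume fraction {f} outside [0, 1)")
    return MixtureTotals(
        N_T=totals.N_T * (1 - f),
        K_T=totals.K_T * (1 - f) + f * K_stock,
    )


def plan_protocol(
    target_ratios: Sequence[float], N_T0: float, K_stock: float
) -> TitrationProtocol:
    """Replacement fractions that hit the requested K_T/N_T ratios exactly.

    Solving ``(K_T(1-f) + f*K_stock) / (N_T(1-f)) = rho`` for ``f`` gives
    ``f = (rho*N_T - K_T) / (K_stock - K_T + rho*N_T)``.
    """
    if any(b <= a for a, b in zip(target_ratios, target_ratios[1:])):
        raise InvalidParameterError("target ratios must be strictly increasing")
    totals = MixtureTotals(N_T=N_T0, K_T=0.0)
    steps: list[float] = []
    for rho in target_ratios:
        num = rho * totals.N_T - totals.K_T
        den = K_stock - totals.K_T + rho * totals.N_T
        if num < 0 or den <= 0:
            raise UnreachableRatioError(f"target ratio {rho} below current ratio")
        f = num / den
        if not (0 <= f < 1):
            raise UnreachableRatioError(
                f"target ratio {rho} needs replaced fraction {f:.3g} outside [0, 1)"
            )
        steps.append(f)
        totals = advance_totals(totals, f, K_stock)
    return TitrationProtocol(N_T0=N_T0, K_stock=K_stock, steps=tuple(steps))


def run_titration(
    protocol: TitrationProtocol,
    params: EquilibriumParams,
    model: BindingModel,
    include_start: bool = False,
) -> SpeciesProfile:
    """Speciation at every point of a stepwise replacement titration."""
    profile = SpeciesProfile()
    totals = MixtureTotals(N_T=protocol.N_T0, K_T=0.0)
    if include_start:
        profile.records.append(
            (TitrationPoint(0, totals), species_concentrations(params, totals, model))
        )
    for i, f in enumerate(protocol.steps, start=1):
        totals = advance_totals(totals, f, protocol.K_stock)
        try:
            sp = species_concentrations(params, totals, model)
        except Exception as exc:  # annotate with the failing point
            raise type(exc)(f"titration point {i}: {exc}") from exc
        profile.records.append((TitrationPoint(i, totals), sp))
    return profile


def dense_ratio_totals(
    ratios: Iterable[float], N_T0: float, K_stock: float
) -> list[MixtureTotals]:
    """Totals along the continuous-replacement limit of the protocol.

    Replacing an infinitesimal volume fraction ``ds`` per step gives
    ``dN_T = -N_T ds`` and ``dK_T = (K_stock - K_T) ds``, hence
    ``N_T = N_T0 * exp(-s)`` and ``K_T = K_stock * (1 - exp(-s))``.  A target
    ratio ``rho`` corresponds to ``s = ln(1 + rho*N_T0/K_stock)``.
    """
    out = []
    for rho in ratios:
        if rho < 0:
            raise InvalidParameterError("ratio must be >= 0")
        es = 1.0 + rho * N_T0 / K_stock  # = exp(s)
        out.append(MixtureTotals(N_T=N_T0 / es, K_T=K_stock * (1 - 1 / es)))
    return out


def run_dense_titration(
    params: EquilibriumParams,
    model: BindingModel,
    N_T0: float,
    K_stock: float,
    ratio_max: float = 4.0,
    n_points: int = 401,
) -> SpeciesProfile:
    """Smooth speciation profile over a dense ratio grid (continuum protocol)."""
    ratios = np.linspace(0.0, ratio_max, n_points)
    profile = SpeciesProfile()
    for i, totals in enumerate(dense_ratio_totals(ratios, N_T0, K_stock)):
        profile.records.append(
            (TitrationPoint(i, totals), species_concentrations(params, totals, model))
        )
    return profile


def profile_maximum(
    ratios: Sequence[float], values: Sequence[float]
) -> tuple[float, bool]:
    """Locate the maximum of a profile sampled on an increasing ratio grid.

    Returns ``(ratio_at_max, boundary)``.  An interior maximum is refined by
    quadratic interpolation through the maximal sample and its neighbours;
    a maximum at either end sets the boundary flag and is returned at the
    endpoint.  Ties between equal maxima report the lower ratio.
    """
    r = np.asarray(ratios, dtype=float)
    v = np.asarray(values, dtype=float)
    if r.size < 3:
        raise InsufficientDataError("need at least 3 points to locate a maximum")
    if np.any(np.diff(r) <= 0):
        raise InvalidParameterError("ratios must be strictly increasing")
    i = int(np.argmax(v))  # argmax takes the first of equal maxima
    if i == 0 or i == r.size - 1:
        return float(r[i]), True
    x0, x1, x2 = r[i - 1], r[i], r[i + 1]
    y0, y1, y2 = v[i - 1], v[i], v[i + 1]
    denom = (x1 - x0) * (y1 - y2) - (x1 - x2) * (y1 - y0)
    if denom == 0:  # flat top: keep the sample location
        return float(x1), False
    vertex = x1 - 0.5 * ((x1 - x0) ** 2 * (y1 - y2) - (x1 - x2) ** 2 * (y1 - y0)) / denom
    return float(vertex), False
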