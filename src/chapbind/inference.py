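"""Stoichiometry and relative-affinity inference from titration peak intensities.

In a serial-replacement titration the concentration of a 1:1
chaperone:client complex is maximal at a total-concentration ratio
``K_T/N_T`` of about 1 and that of a 2:1 complex at about 2, so the
location of the intensity maximum of a bound-state resonance calls its
stoichiometry.  At the common maximum, intensities of different 1:1
complexes are proportional to their concentrations, and the concentration
ratio of two 1:1 complexes equals the inverse ratio of their dissociation
constants; intensity ratios therefore yield relative Kd values and, via
``ddG = R*T*ln(kd_rel)``, free-energy differences between binding modes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .titration import profile_maximum

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEFAULT_TEMPERATURE_K",
    "IntensityTable",
    "Stoichiometry",
    "StoichiometryCall",
    "classify_stoichiometry",
    "relative_kd",
    "delta_delta_g",
    "unfolded_fraction",
]

#: gas constant in kcal mol^-1 K^-1
GAS_CONSTANT_KCAL = 1.9872e-3
#: experimental temperature, 35 degrees C
DEFAULT_TEMPERATURE_K = 308.15
#: half-width of the decision window around the candidate ratios {1, 2}
DEFAULT_DECISION_MARGIN = 0.25


class InvalidIntensityError(ValueError):
    pass


class Stoichiometry(Enum):
    ONE_TO_ONE = "one_to_one"
    TWO_TO_ONE = "two_to_one"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class StoichiometryCall:
    conformer: str
    call: Stoichiometry
    ratio_at_max: float
    boundary: bool


class IntensityTable:
    """Per-conformer peak intensity versus total-concentration ratio.

    Thin wrapper over a tidy :class:`pandas.DataFrame` with columns
    ``conformer``, ``ratio``, ``intensity`` and optionally ``sigma``.
    Within each conformer the ratios must be strictly increasing and
    intensities nonnegative.
    """

    REQUIRED = ("conformer", "ratio", "intensity")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise InvalidIntensityError(f"missing columns: {missing}")
        if (frame["intensity"] < 0).any():
            raise InvalidIntensityError("intensities must be >= 0")
        for conf, grp in frame.groupby("conformer"):
            if (grp["ratio"].diff().dropna() <= 0).any():
                raise InvalidIntensityError(f"ratios not strictly increasing for {conf!r}")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "IntensityTable":
        return cls(pd.read_csv(path, comment="#"))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, lineterminator="\n")

    @property
    def conformers(self) -> list[str]:
        return list(dict.fromkeys(self.frame["conformer"]))

    def profile(self, conformer: str) -> pd.DataFrame:
        grp = self.frame[self.frame["conformer"] == conformer]
        if grp.empty:
            raise KeyError(f"unknown conformer {conformer!r}")
        return grp


def classify_stoichiometry(
    table: IntensityTable,
    conformer: str,
    margin: float = DEFAULT_DECISION_MARGIN,
) -> StoichiometryCall:
    """Call 1:1 vs 2:1 binding from the position of the intensity maximum.

    The profile maximum (quadratic-refined) is assigned to the nearer of the
    candidate ratios 1 and 2; a boundary maximum, or one farther than
    ``margin`` from both candidates (or equidistant within it), is ambiguous.
    """
    grp = table.profile(conformer)
    ratio_at_max, boundary = profile_maximum(
        grp["ratio"].to_numpy(), grp["intensity"].to_numpy()
    )
    if boundary:
        call = Stoichiometry.AMBIGUOUS
    else:
        d1, d2 = abs(ratio_at_max - 1.0), abs(ratio_at_max - 2.0)
        if min(d1, d2) > margin or math.isclose(d1, d2, abs_tol=1e-12):
            call = Stoichiometry.AMBIGUOUS
        elif d1 < d2:
            call = Stoichiometry.ONE_TO_ONE
        else:
            call = Stoichiometry.TWO_TO_ONE
    return StoichiometryCall(conformer, call, ratio_at_max, boundary)


def relative_kd(intensity_ref: float, intensity_i: float) -> float:
    """Kd of conformer *i* relative to the reference conformer.

    Both intensities are taken at the common titration-profile maximum of
    1:1 complexes; since ``[UK']/[UK] = Kd1/Kd1'``, the relative Kd is the
    reciprocal of the intensity ratio: ``kd_rel = I_ref / I_i``.
    """
    if intensity_ref <= 0 or intensity_i <= 0:
        raise InvalidIntensityError("intensities must be > 0 for a Kd ratio")
    return intensity_ref / intensity_i


def delta_delta_g(kd_rel: float, T_kelvin: float = DEFAULT_TEMPERATURE_K) -> float:
    """Binding free-energy difference R*T*ln(kd_rel), kcal/mol."""
    if kd_rel <= 0:
        raise ValueError("kd_rel must be > 0")
    if T_kelvin <= 0:
        raise ValueError("temperature must be > 0 K")
    return GAS_CONSTANT_KCAL * T_kelvin * math.log(kd_rel)


def unfolded_fraction(K_UN: float) -> float:
    """Equilibrium unfolded fraction 1/(1 + K_UN) of the free client."""
    if K_UN < 0:
        raise ValueError("K_UN must be >= 0")
    if math.isinf(K_UN):
        return 0.0
    return 1.0 / (1.0 + K_UN)
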