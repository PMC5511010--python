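"""Synthetic data generators with the statistical structure of the experiments.

Peak intensities along a serial-replacement titration are modelled as
species concentration times a per-conformer response factor and relative
attenuation, an optional cumulative per-step sample-loss factor
(aggregation), and multiplicative Gaussian noise.  Diffusion decays and
magnetization-exchange series follow the closed forms used by the fitting
code, with the same noise model.  All generators are pure functions of
their parameters and a mandatory seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .equilibria import BindingModel, EquilibriumParams
from .inference import IntensityTable
from .spectral import ExchangeParams, DiffusionSeries, exchange_intensities
from .titration import SpeciesProfile, TitrationProtocol, run_titration

__all__ = [
    "ResponseModel",
    "generate_titration_intensities",
    "generate_diffusion_series",
    "generate_exchange_series",
]


@dataclass(frozen=True)
class ResponseModel:
    """Observation model mapping species concentrations to peak intensities.

    Parameters
    ----------
    response_factors : dict
        Per-conformer intensity per molar (> 0).
    attenuations : dict
        Per-conformer relative attenuation in (0, 1] (differential
        relaxation losses between bound states); default 1 for all.
    noise_sd : float
        Standard deviation of the multiplicative Gaussian noise, as a
        fraction of the noiseless intensity.
    loss_per_step : float
        Fraction of signal lost per titration step (sample aggregation),
        applied cumulatively.
    seed : int
        Mandatory seed for the noise stream.
    """

    response_factors: dict[str, float]
    seed: int
    attenuations: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    loss_per_step: float = 0.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.response_factors.values()):
            raise ValueError("response factors must be > 0")
        if any(not (0 < v <= 1) for v in self.attenuations.values()):
            raise ValueError("attenuations must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not (0 <= self.loss_per_step < 1):
            raise ValueError("loss per step must lie in [0, 1)")


def generate_titration_intensities(
    params: EquilibriumParams,
    model: BindingModel,
    protocol: TitrationProtocol,
    response: ResponseModel,
    conformer_species: dict[str, str],
) -> IntensityTable:
    """Synthetic per-conformer intensity table for a titration.

    ``conformer_species`` assigns each conformer label to one complex
    species of the binding scheme (e.g. ``{"a": "UK", "c": "UK2"}``).
    Intensity = response factor x attenuation x concentration x
    cumulative loss x (1 + noise); deterministic for a fixed seed.
    """
    unknown = set(conformer_species) - set(response.response_factors)
    if unknown:
        raise KeyError(f"conformers without response factors: {sorted(unknown)}")
    profile: SpeciesProfile = run_titration(protocol, params, model)
    rng = np.random.default_rng(response.seed)
    rows = []
    for conformer, species in conformer_species.items():
        factor = response.response_factors[conformer]
        atten = response.attenuations.get(conformer, 1.0)
        for step_i, (pt, sp) in enumerate(profile.records, start=1):
            try:
                conc = sp.as_dict()[species]
            except KeyError:
                raise KeyError(
                    f"conformer {conformer!r} mapped to species {species!r} "
                    f"absent from the {model.value} scheme"
                ) from None
            clean = factor * atten * conc * (1 - response.loss_per_step) ** step_i
            noisy = clean * (1.0 + rng.normal(0.0, response.noise_sd)) if response.noise_sd else clean
            if noisy < 0:
                warnings.warn("negative generated intensity clipped to 0")
                noisy = 0.0
            rows.append(dict(conformer=conformer, ratio=pt.ratio, intensity=noisy))
    return IntensityTable(pd.DataFrame(rows))


def generate_diffusion_series(
    I0: float, d: float, G: np.ndarray, noise_sd: float, seed: int
) -> DiffusionSeries:
    """Noisy exponential gradient decay ``I = I0*exp(-d*G^2)*(1 + eps)``."""
    if I0 < 0 or d < 0:
        raise ValueError("I0 and d must be >= 0")
    G = np.asarray(G, dtype=float)
    rng = np.random.default_rng(seed)
    I = I0 * np.exp(-d * G**2)
    if noise_sd:
        I = I * (1.0 + rng.normal(0.0, noise_sd, size=I.shape))
    return DiffusionSeries(G=G, I=np.clip(I, 0.0, None))


def generate_exchange_series(
    params: ExchangeParams, t_mix_grid: np.ndarray, noise_sd: float, seed: int
) -> pd.DataFrame:
    """Diagonal and crosspeak intensities over a mixing-time grid.

    Columns ``t_mix``, ``diagonal``, ``crosspeak``; symmetric two-site
    closed form with exp(-R1*t_mix) damping plus multiplicative noise.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for tm in np.asarray(t_mix_grid, dtype=float):
        diag, cross = exchange_intensities(
            ExchangeParams(k_ex=params.k_ex, R1=params.R1, t_mix=tm)
        )
        if noise_sd:
            diag *= 1.0 + rng.normal(0.0, noise_sd)
            cross *= 1.0 + rng.normal(0.0, noise_sd)
        rows.append(dict(t_mix=tm, diagonal=max(diag, 0.0), crosspeak=max(cross, 0.0)))
    return pd.DataFrame(rows)
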