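"""Synthetic GPS-style single-cell data and random parameter sets.

The generator emulates the dual-fluorescent reporter readout after
gating and filtering: per cell, an RFP intensity (protein synthesis,
proportional to mRNA) and a GFP intensity (protein abundance) produced
by the closed-form decoding model, with multiplicative Gaussian noise
whose normalized standard deviation matches the ~0.3 measured in real
cytometry data.  mRNA levels span 1–4000 model units, about a thousand
points per parameter set across several selenium conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import KineticParameters, ModelVariant, predict_gfp

__all__ = [
    "ParameterBounds",
    "DEFAULT_SE_GRID",
    "default_m_grid",
    "sample_parameters",
    "simulate_gps",
    "simulate_western_ratio",
]

#: Selenium conditions (nM sodium selenite) used by default for
#: multi-condition simulation and the recovery benchmark: a zero
#: control plus a titration reaching charged-tRNA saturation.
DEFAULT_SE_GRID: tuple[float, ...] = (0.0, 8.0, 40.0, 200.0, 1000.0)

#: Searched-parameter ranges.  Where the physiological table gives a
#: lower bound of zero (meaningless on a log grid) the floor is 0.01.
_DEFAULT_BOUNDS = {
    "k1": (0.01, 100.0),
    "kF": (0.01, 10000.0),
    "k3": (0.01, 100.0),
    "T_total": (10.0, 1000.0),
    "rho": (0.01, 10000.0),
}

SEARCHED_PARAMETERS = tuple(_DEFAULT_BOUNDS)


@dataclass(frozen=True)
class ParameterBounds:
    """Log-uniform sampling / search box for the five free parameters."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_BOUNDS)
    )

    def __post_init__(self) -> None:
        for name in SEARCHED_PARAMETERS:
            if name not in self.bounds:
                raise ValueError(f"missing bounds for {name}")
            lb, ub = self.bounds[name]
            if not (0 < lb < ub) or not (math.isfinite(lb) and math.isfinite(ub)):
                raise ValueError(f"require 0 < LB < UB for {name}, got ({lb}, {ub})")

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.bounds[name]

    def log10_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([math.log10(self.bounds[p][0]) for p in SEARCHED_PARAMETERS])
        hi = np.array([math.log10(self.bounds[p][1]) for p in SEARCHED_PARAMETERS])
        return lo, hi


def default_m_grid(n: int = 1000, low: float = 1.0, high: float = 4000.0) -> np.ndarray:
    """Linearly spaced total-mRNA levels, 1–4000 model units."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.linspace(low, high, n)


def sample_parameters(
    bounds: ParameterBounds,
    n: int,
    seed: int,
    rho_p: float = 100.0,
    SP_L: float = 7.0,
    SP_S: float = 0.7,
) -> list[KineticParameters]:
    """Draw ``n`` log-uniform parameter sets within the bounds.

    Each searched parameter is drawn as
    ``10^(log10 LB + (log10 UB - log10 LB)·X)`` with ``X ~ U(0, 1)``,
    i.e. uniformly in log10 space, so every decade of the range is
    sampled with equal probability.  ``rho_p`` and the control slopes
    are fixed, not sampled (the fit treats them as known).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = bounds.log10_arrays()
    X = rng.random((n, len(SEARCHED_PARAMETERS)))
    values = 10.0 ** (lo + (hi - lo) * X)
    return [
        KineticParameters(
            k1=row[0], kF=row[1], k3=row[2], T_total=row[3], rho=row[4],
            rho_p=rho_p, SP_L=SP_L, SP_S=SP_S,
        )
        for row in values
    ]


def simulate_gps(
    params: KineticParameters,
    m_grid,
    Se: float,
    noise_sd: float = 0.0,
    seed: int | None = 0,
    variant: ModelVariant | str = ModelVariant.FULL,
    construct: str = "synthetic",
) -> pd.DataFrame:
    """Simulate one selenium condition of GPS data.

    One record per ``m_grid`` entry: ``RFP = rho·rho_p·m_total`` exactly
    and ``GFP = GFP_model·(1 + NorR)`` with ``NorR ~ N(0, noise_sd²)``,
    floored at zero (intensities are non-negative).  Bitwise
    reproducible for a given seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    m = np.asarray(m_grid, dtype=float)
    if m.ndim != 1 or m.size == 0:
        raise ValueError("m_grid must be a non-empty 1-D array")
    rfp = params.rho * params.rho_p * m
    gfp = np.asarray(predict_gfp(params, rfp, float(Se), variant), dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        gfp = gfp * (1.0 + rng.normal(0.0, noise_sd, size=gfp.shape))
        gfp = np.maximum(gfp, 0.0)
    return pd.DataFrame(
        {"rfp": rfp, "gfp": gfp, "selenium": float(Se), "construct": construct}
    )


def simulate_multi_condition(
    params: KineticParameters,
    m_grid,
    se_grid=DEFAULT_SE_GRID,
    noise_sd: float = 0.0,
    seed: int | None = 0,
    variant: ModelVariant | str = ModelVariant.FULL,
    construct: str = "synthetic",
) -> pd.DataFrame:
    """Simulate every selenium condition and concatenate the records."""
    sub_seeds = np.random.SeedSequence(seed).generate_state(len(tuple(se_grid))) % (2**31)
    frames = [
        simulate_gps(params, m_grid, se, noise_sd, int(s), variant, construct)
        for se, s in zip(se_grid, sub_seeds)
    ]
    return pd.concat(frames, ignore_index=True)


def simulate_western_ratio(
    params: KineticParameters,
    m_grid,
    se_grid,
    variant: ModelVariant | str = ModelVariant.FULL,
) -> pd.DataFrame:
    """Sec incorporation efficiency P_L/P_S over an (mRNA, selenium) grid.

    Mirrors a quantified Western blot: long-form table with columns
    ``m_total, selenium, ratio``.  Conditions with ``P_S = 0`` report an
    infinite ratio rather than an error.
    """
    from .model import predict_proteins

    m = np.asarray(m_grid, dtype=float)
    rows = []
    for se in se_grid:
        P_L, P_S = predict_proteins(params, m, float(se), variant)
        P_L, P_S = np.atleast_1d(P_L), np.atleast_1d(P_S)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(P_S > 0, P_L / np.where(P_S > 0, P_S, 1.0), np.inf)
        ratio = np.where((P_S == 0) & (P_L == 0), 0.0, ratio)
        rows.append(pd.DataFrame({"m_total": m, "selenium": float(se), "ratio": ratio}))
    return pd.concat(rows, ignore_index=True)
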