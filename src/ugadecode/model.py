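"""Closed-form steady-state model of alternative UGA codon assignment.

At a selenoprotein UGA codon, charged Sec-tRNA and release factors (RF)
compete: tRNA binding yields the full-length protein P_L, RF binding
yields the truncated protein P_S.  The model couples three mass-action
equilibria to two resource constraints — a finite mRNA pool and a
finite Sec-tRNA pool — and resolves all species in closed
form, so that observable GFP (abundance) can be predicted from RFP
(synthesis) for any selenium concentration.

Species and balances (all concentrations in nM):

* mRNA partition:      ``m_f + m_SeT + m_RF = m_total``
* charged-tRNA pool:   ``SeT_f + m_SeT = SeT_total``
* total tRNA pool:     ``T_uncharged + SeT_total = T_total``
* binding equilibria:  ``m_SeT = k1·m_f·SeT_f``, ``m_RF = kF·m_f``,
  ``SeT_total = k3·Se·T_uncharged``

Free parameters are reduced to ``{k1, kF, k3, T_total, rho, rho_p}``
plus the two control slopes ``SP_L``/``SP_S`` measured from
full-length-only and truncated-only reporter constructs.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "KineticParameters",
    "NMDParameters",
    "DecodingState",
    "HalfLifeMixture",
    "ModelVariant",
    "sec_trna_pool",
    "solve_free_mrna",
    "resolve_state",
    "predict_proteins",
    "predict_gfp",
    "uga_sec_fraction",
    "nmd_alphas",
    "mixture_half_life",
    "rate_ratio_from_slope",
]


class ModelVariant(enum.Enum):
    """Which of the two resource constraints are active.

    FULL applies both the mRNA partition and the finite-tRNA pool.
    MRNA_ONLY keeps the mRNA partition and charged-pool depletion but
    lets the uncharged tRNA supply be unlimited, so the charged pool
    grows linearly with selenium.  TRNA_ONLY keeps the tRNA pool but
    treats every mRNA as free.  NONE removes all resource coupling and
    is exactly linear in mRNA.
    """

    FULL = "full"
    MRNA_ONLY = "mrna_only"
    TRNA_ONLY = "trna_only"
    NONE = "none"

    @classmethod
    def coerce(cls, value: "ModelVariant | str") -> "ModelVariant":
        if isinstance(value, cls):
            return value
        return cls(str(value).lower())

    @property
    def mrna_constrained(self) -> bool:
        return self in (ModelVariant.FULL, ModelVariant.MRNA_ONLY)

    @property
    def trna_pool_finite(self) -> bool:
        return self in (ModelVariant.FULL, ModelVariant.TRNA_ONLY)

    @property
    def charged_pool_depleted(self) -> bool:
        # With no resource limits at all there is nothing to deplete.
        return self is not ModelVariant.NONE


@dataclass(frozen=True)
class KineticParameters:
    """The reduced parameter set of the UGA-decoding model.

    Parameters
    ----------
    k1
        mRNA–Sec-tRNA association constant (1/nM): ``m_SeT = k1·m_f·SeT_f``.
    kF
        Combined release-factor term ``k2·[RF]`` (dimensionless);
        ``m_RF = kF·m_f``.
    k3
        Sec charging association constant (1/nM of selenium):
        ``SeT_total = k3·Se·T_uncharged``.
    T_total
        Total tRNA^Sec pool, charged plus uncharged (nM).
    rho
        Ratio of RFP to GFP intensity constants (dimensionless);
        ``RFP = rho·rho_p·m_total``.
    rho_p
        GFP intensity per protein concentration (a.u./nM);
        ``GFP = rho_p·P_total``.
    SP_L, SP_S
        GFP-vs-RFP slopes of the full-length-only and truncated-only
        control constructs.  They encode the synthesis/degradation
        ratios via ``gamma/lambda = rho·SP·(1+kF)/kF``.
    """

    k1: float
    kF: float
    k3: float
    T_total: float
    rho: float
    rho_p: float = 100.0
    SP_L: float = 7.0
    SP_S: float = 0.7

    def __post_init__(self) -> None:
        for name in ("k1", "kF", "k3", "T_total", "rho", "rho_p", "SP_L", "SP_S"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be finite and strictly positive, got {value!r}")
        if self.SP_L <= self.SP_S:
            warnings.warn(
                "SP_L <= SP_S: the full-length protein is expected to be "
                "more stable than the truncated one",
                stacklevel=2,
            )

    def with_(self, **kwargs) -> "KineticParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class NMDParameters:
    """Nonsense-mediated-decay correction (off by default).

    ``e0`` is the background mRNA decay probability, ``N`` the average
    number of proteins translated per mRNA lifetime.  The escape
    probabilities ``alpha_L = 1 - e0`` and ``alpha_S`` (a function of
    the Sec-commitment probability eta) multiply the complex
    concentrations before translation.  Reporter constructs built from
    intron-less cDNA are immune to NMD, hence the default
    ``enabled=False`` which fixes ``alpha_L = alpha_S = 1``.
    """

    enabled: bool = False
    e0: float = 0.0
    N: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.e0 < 1.0:
            raise ValueError(f"e0 must lie in [0, 1), got {self.e0!r}")
        if self.enabled and self.N <= 1.0:
            raise ValueError("N must exceed 1 when NMD is enabled")


@dataclass(frozen=True)
class DecodingState:
    """All species concentrations at one resolved steady state (nM)."""

    m_total: float
    Se: float
    m_f: float
    m_SeT: float
    m_RF: float
    SeT_total: float
    SeT_f: float
    T_uncharged: float
    P_L: float
    P_S: float


@dataclass(frozen=True)
class HalfLifeMixture:
    """Degradation-rate mixture of full-length and truncated protein.

    ``x`` is the proportion of UGA events decoded as Sec; the observed
    population rate ``lambda_T`` is the harmonic mixture of the two
    species' rates (half-lives add linearly).
    """

    x: float
    lambda_L: float
    lambda_S: float

    @property
    def lambda_T(self) -> float:
        return mixture_half_life(self.x, self.lambda_L, self.lambda_S)


def _validate_nonneg(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr


def sec_trna_pool(params: KineticParameters, Se) -> np.ndarray | float:
    """Total charged Sec-tRNA pool at a given selenium concentration.

    Combining the charging equilibrium ``SeT_total = k3·Se·T_uncharged``
    with the pool constraint ``T_uncharged + SeT_total = T_total`` gives

        ``SeT_total = k3·Se·T_total / (1 + k3·Se)``

    which rises from 0 at zero selenium and saturates at ``T_total``.
    """
    se = _validate_nonneg("Se", Se)
    x = params.k3 * se
    out = x * params.T_total / (1.0 + x)
    return float(out) if np.isscalar(Se) or np.ndim(Se) == 0 else out


def _charged_pool(k3, T_total, Se, finite_pool):
    """Charged-tRNA supply term S; saturating iff the pool is finite."""
    x = k3 * Se
    return x * T_total / (1.0 + x) if finite_pool else x * T_total


def _free_mrna_from_supply(k1, kF, S, m_total):
    """Positive root of k1(1+kF)·m_f² + [(1+kF)+k1(S−m_total)]·m_f − m_total = 0.

    Uses the conjugate form m_f = 2·m_total / (b + sqrt(b² + 4a·m_total)),
    which is exact for m_total = 0, stable for large positive b, and
    degenerates smoothly to m_total/(1+kF) as k1 → 0.
    """
    a = k1 * (1.0 + kF)
    b = (1.0 + kF) + k1 * (S - m_total)
    disc = b * b + 4.0 * a * m_total
    # Floating-point cancellation cannot make disc negative here
    # (4·a·m_total >= 0), but guard anyway.
    disc = np.maximum(disc, 0.0)
    denom = b + np.sqrt(disc)
    with np.errstate(divide="ignore", invalid="ignore"):
        m_f = np.where(denom > 0, 2.0 * m_total / np.where(denom > 0, denom, 1.0), 0.0)
    return np.minimum(m_f, m_total)


def solve_free_mrna(
    params: KineticParameters,
    m_total,
    Se,
    variant: ModelVariant | str = ModelVariant.FULL,
    strict_eq16: bool = False,
) -> np.ndarray | float:
    """Free (unbound) mRNA concentration at steady state.

    For mRNA-constrained variants this is the positive root of the
    quadratic obtained by substituting both binding equilibria and the
    charged-pool balance into the mRNA partition; otherwise every mRNA
    is free and ``m_f = m_total``.

    ``strict_eq16`` replaces the saturating charged-pool term
    ``k3·Se·T_total/(1+k3·Se)`` with the bare product ``Se·T_total``
    inside the quadratic only.  This mirrors a printed form of the
    closed-form solution that is inconsistent with the charging
    equilibrium; it exists for comparison and is never the default.
    """
    variant = ModelVariant.coerce(variant)
    m_arr = _validate_nonneg("m_total", m_total)
    se_arr = _validate_nonneg("Se", Se)
    if not variant.mrna_constrained:
        out = np.broadcast_arrays(m_arr, se_arr)[0].copy()
    else:
        if strict_eq16:
            S = se_arr * params.T_total
        else:
            S = _charged_pool(params.k3, params.T_total, se_arr, variant.trna_pool_finite)
        out = _free_mrna_from_supply(params.k1, params.kF, S, m_arr)
    scalar = np.ndim(m_total) == 0 and np.ndim(Se) == 0
    return float(out) if scalar else out


def _resolve_arrays(params, m_total, Se, variant, strict_eq16=False, alpha_L=1.0, alpha_S=1.0):
    """Vectorized resolution of all species; the single internal solver.

    With NMD enabled the post-degradation complexes are
    ``alpha_L·k1·m_f·SeT_f`` and ``alpha_S·kF·m_f``; the conservation
    balances are written on the post-degradation species, so the alphas
    enter as effective multipliers on k1 and kF.
    """
    variant = ModelVariant.coerce(variant)
    k1e = alpha_L * params.k1
    kFe = alpha_S * params.kF
    S = _charged_pool(params.k3, params.T_total, Se, variant.trna_pool_finite)
    if variant.mrna_constrained:
        S_solver = Se * params.T_total if strict_eq16 else S
        m_f = _free_mrna_from_supply(k1e, kFe, S_solver, m_total)
    else:
        m_f = np.broadcast_arrays(np.asarray(m_total, dtype=float), np.asarray(Se, dtype=float))[0] + 0.0
    if variant.charged_pool_depleted:
        SeT_f = S / (1.0 + k1e * m_f)
    else:
        SeT_f = np.broadcast_arrays(np.asarray(S, dtype=float), np.asarray(m_f))[0] + 0.0
    m_SeT = k1e * m_f * SeT_f
    m_RF = kFe * m_f
    rr_L = rate_ratio_from_slope(params.SP_L, params.rho, params.kF)
    rr_S = rate_ratio_from_slope(params.SP_S, params.rho, params.kF)
    P_L = rr_L * m_SeT
    P_S = rr_S * m_RF
    return m_f, SeT_f, m_SeT, m_RF, S, P_L, P_S


def resolve_state(
    params: KineticParameters,
    m_total: float,
    Se: float,
    variant: ModelVariant | str = ModelVariant.FULL,
    nmd: NMDParameters | None = None,
    strict_eq16: bool = False,
) -> DecodingState:
    """Resolve every species concentration for one (m_total, Se) condition.

    When NMD is enabled, the commitment probability eta depends on the
    resolved free charged-tRNA level, which itself depends on alpha_S;
    the pair is iterated to a fixed point.
    """
    _validate_nonneg("m_total", m_total)
    _validate_nonneg("Se", Se)
    variant = ModelVariant.coerce(variant)
    alpha_L, alpha_S = 1.0, 1.0
    if nmd is not None and nmd.enabled:
        alpha_L = 1.0 - nmd.e0
        for _ in range(200):
            _, SeT_f, *_ = _resolve_arrays(
                params, float(m_total), float(Se), variant, strict_eq16, alpha_L, alpha_S
            )
            eta = params.k1 * SeT_f / (params.k1 * SeT_f + params.kF)
            if eta <= 0:
                new_alpha_S = 0.0
            else:
                _, new_alpha_S = nmd_alphas(NMDParameters(True, nmd.e0, nmd.N), float(eta))
            if abs(new_alpha_S - alpha_S) < 1e-12:
                alpha_S = new_alpha_S
                break
            alpha_S = new_alpha_S
    m_f, SeT_f, m_SeT, m_RF, S, P_L, P_S = _resolve_arrays(
        params, float(m_total), float(Se), variant, strict_eq16, alpha_L, alpha_S
    )
    SeT_total = float(S)
    return DecodingState(
        m_total=float(m_total),
        Se=float(Se),
        m_f=float(m_f),
        m_SeT=float(m_SeT),
        m_RF=float(m_RF),
        SeT_total=SeT_total,
        SeT_f=float(SeT_f),
        T_uncharged=max(params.T_total - SeT_total, 0.0),
        P_L=float(P_L),
        P_S=float(P_S),
    )


def predict_proteins(
    params: KineticParameters,
    m_total,
    Se,
    variant: ModelVariant | str = ModelVariant.FULL,
    strict_eq16: bool = False,
):
    """Full-length and truncated protein concentrations (P_L, P_S).

    ``P_L = (gamma_L/lambda_L)·k1·m_f·SeT_f`` and
    ``P_S = (gamma_S/lambda_S)·kF·m_f``, with the rate ratios taken from
    the control slopes.  Accepts scalars or arrays (broadcast).
    """
    m_arr = _validate_nonneg("m_total", m_total)
    se_arr = _validate_nonneg("Se", Se)
    *_, P_L, P_S = _resolve_arrays(params, m_arr, se_arr, variant, strict_eq16)
    if np.ndim(m_total) == 0 and np.ndim(Se) == 0:
        return float(P_L), float(P_S)
    return P_L, P_S


def predict_gfp(
    params: KineticParameters,
    rfp,
    Se,
    variant: ModelVariant | str = ModelVariant.FULL,
    strict_eq16: bool = False,
):
    """Predicted GFP intensity for observed RFP intensity.

    RFP is converted to mRNA via ``m_total = RFP/(rho·rho_p)``, the
    model is evaluated, and total protein is converted back via
    ``GFP = rho_p·(P_L + P_S)``.
    """
    rfp_arr = _validate_nonneg("rfp", rfp)
    m_total = rfp_arr / (params.rho * params.rho_p)
    P_L, P_S = predict_proteins(params, m_total, Se, variant, strict_eq16)
    out = params.rho_p * (np.asarray(P_L) + np.asarray(P_S))
    if np.ndim(rfp) == 0 and np.ndim(Se) == 0:
        return float(out)
    return out


def uga_sec_fraction(
    params: KineticParameters,
    m_total,
    Se,
    variant: ModelVariant | str = ModelVariant.FULL,
) -> np.ndarray | float:
    """Probability eta that a UGA event is decoded as Sec.

    ``eta = k1·SeT_f / (k1·SeT_f + kF)`` evaluated at the resolved
    steady state: the relative rate at which charged tRNA outcompetes
    the release factor.  Rises with selenium, falls with mRNA load as
    the charged pool is depleted.
    """
    m_arr = _validate_nonneg("m_total", m_total)
    se_arr = _validate_nonneg("Se", Se)
    _, SeT_f, *_ = _resolve_arrays(params, m_arr, se_arr, variant)
    num = params.k1 * np.asarray(SeT_f, dtype=float)
    eta = num / (num + params.kF)
    if np.ndim(m_total) == 0 and np.ndim(Se) == 0:
        return float(eta)
    return eta


def nmd_alphas(nmd: NMDParameters, eta: float) -> tuple[float, float]:
    """Escape-from-decay probabilities (alpha_L, alpha_S).

    ``alpha_L = 1 - e0``.  For the truncated branch,

        ``alpha_S = 1 - 1/[(N-1)·eta] - e0·(N-1)·eta / [(N-1)·eta + 1]``

    clamped to [0, 1].  Undefined when ``(N-1)·eta = 0``.  When NMD is
    disabled both probabilities are exactly 1 and the formula is never
    evaluated.
    """
    if not nmd.enabled:
        return 1.0, 1.0
    if nmd.N <= 1.0:
        raise ValueError("alpha_S is singular for N <= 1")
    if not 0.0 < eta <= 1.0:
        raise ValueError(f"eta must lie in (0, 1], got {eta!r}")
    alpha_L = 1.0 - nmd.e0
    z = (nmd.N - 1.0) * eta
    alpha_S = 1.0 - 1.0 / z - nmd.e0 * z / (z + 1.0)
    return alpha_L, float(min(max(alpha_S, 0.0), 1.0))


def mixture_half_life(x: float, lambda_L: float, lambda_S: float) -> float:
    """Observed degradation rate of a P_L/P_S mixture.

    A fraction ``x`` of UGA events yield the long-lived species, so the
    observed half-life is the x-weighted sum of the component
    half-lives:  ``x/lambda_L + (1-x)/lambda_S = 1/lambda_T``.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"x must lie in [0, 1], got {x!r}")
    if lambda_L <= 0 or lambda_S <= 0:
        raise ValueError("degradation rates must be positive")
    return 1.0 / (x / lambda_L + (1.0 - x) / lambda_S)


def rate_ratio_from_slope(slope: float, rho: float, kF: float):
    """Synthesis/degradation ratio gamma/lambda implied by a control slope.

    ``gamma/lambda = rho·SP·(1+kF)/kF``; identical form for the
    full-length (SP_L) and truncated (SP_S) controls.
    """
    if np.any(np.asarray(slope) <= 0) or np.any(np.asarray(rho) <= 0):
        raise ValueError("slope and rho must be positive")
    if np.any(np.asarray(kF) <= 0):
        raise ValueError("kF must be positive")
    return rho * slope * (1.0 + kF) / kF
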