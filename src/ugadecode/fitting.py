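"""Loss function and recursive grid-search estimation of decoding parameters.

The loss surface of the UGA-decoding model is multimodal in the five
free parameters {k1, kF, k3, T_total, rho}, which defeats gradient
descent.  The estimator therefore works on a logarithmic grid: evaluate
the squared-error loss on a coarse grid spanning the physiological
ranges, keep the best-scoring cells, bisect them, and recurse until the
cells are narrower than the requested resolution.  rho_p is excluded
from the search — it only rescales expression levels — and is fixed by
configuration; the control slopes SP_L/SP_S are measured once from the
full-length-only and truncated-only constructs.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import model as _model
from .gps_io import validate_gps
from .model import KineticParameters, ModelVariant
from .simulate import SEARCHED_PARAMETERS, ParameterBounds

__all__ = [
    "FitConfig",
    "FitResult",
    "total_loss",
    "fit_control_slopes",
    "grid_search",
    "goodness_of_fit",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitConfig:
    """Settings for the recursive grid search.

    ``blocks`` grid divisions per parameter at the coarse level (the
    original search used 4–12); ``top_k`` cells retained per level;
    ``report_k`` solutions reported.  Recursion stops when every cell is
    narrower than ``resolution`` decades per parameter, or after
    ``max_levels`` refinements.
    """

    bounds: ParameterBounds = field(default_factory=ParameterBounds)
    blocks: int = 8
    top_k: int = 30
    report_k: int = 15
    max_levels: int = 30
    resolution: float = 0.01
    rho_p: float = 100.0
    SP_L: float = 7.0
    SP_S: float = 0.7
    variant: ModelVariant | str = ModelVariant.FULL
    chunk: int = 2048

    def __post_init__(self) -> None:
        if self.blocks < 2:
            raise ValueError("blocks must be >= 2")
        if self.top_k < 1 or self.report_k < 1:
            raise ValueError("top_k and report_k must be >= 1")
        if self.rho_p <= 0 or self.SP_L <= 0 or self.SP_S <= 0:
            raise ValueError("rho_p and control slopes must be positive")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive (decades)")


@dataclass(frozen=True)
class FitResult:
    """Ranked parameter sets with their loss values.

    ``table`` has one row per reported solution, ascending loss, with
    columns k1, kF, k3, T_total, rho, rho_p, Q2.  ``history`` records
    per-level progress (configurations evaluated, best loss so far).
    """

    table: pd.DataFrame
    config: FitConfig
    history: list[dict]

    @property
    def best(self) -> KineticParameters:
        row = self.table.iloc[0]
        return KineticParameters(
            k1=row["k1"], kF=row["kF"], k3=row["k3"], T_total=row["T_total"],
            rho=row["rho"], rho_p=row["rho_p"],
            SP_L=self.config.SP_L, SP_S=self.config.SP_S,
        )

    def params_at(self, rank: int) -> KineticParameters:
        row = self.table.iloc[rank]
        return KineticParameters(
            k1=row["k1"], kF=row["kF"], k3=row["k3"], T_total=row["T_total"],
            rho=row["rho"], rho_p=row["rho_p"],
            SP_L=self.config.SP_L, SP_S=self.config.SP_S,
        )

    def predict_gfp(self, rfp, Se) -> np.ndarray:
        """Predicted GFP curve of the rank-1 solution."""
        return _model.predict_gfp(self.best, rfp, Se, ModelVariant.coerce(self.config.variant))

    def with_rho_p(self, rho_p: float) -> "FitResult":
        """Re-express the solutions at a different fluorescence scale.

        rho_p only sets the protein/mRNA scale: replacing it by a new
        value while rescaling rho keeps rho·rho_p (hence the inferred
        mRNA level) and every predicted GFP value unchanged; the loss
        rescales by the squared ratio of protein scales.
        """
        if rho_p <= 0:
            raise ValueError("rho_p must be positive")
        d = rho_p / self.table["rho_p"]
        table = self.table.copy()
        table["rho"] = table["rho"] / d
        table["rho_p"] = rho_p
        table["Q2"] = table["Q2"] / d**2
        config = FitConfig(
            bounds=self.config.bounds, blocks=self.config.blocks,
            top_k=self.config.top_k, report_k=self.config.report_k,
            max_levels=self.config.max_levels, resolution=self.config.resolution,
            rho_p=rho_p, SP_L=self.config.SP_L, SP_S=self.config.SP_S,
            variant=self.config.variant, chunk=self.config.chunk,
        )
        return FitResult(table=table, config=config, history=self.history)


def _loss_batch(theta, rfp, gfp, se, rho_p, SP_L, SP_S, variant):
    """Total squared loss for a batch of parameter configurations.

    ``theta`` is (C, 5) in linear space ordered (k1, kF, k3, T_total,
    rho); data arrays are length n.  Returns (C,) losses.  The model
    algebra reuses the same primitives as the scalar API so the two
    paths cannot drift apart.
    """
    variant = ModelVariant.coerce(variant)
    k1 = theta[:, 0:1]
    kF = theta[:, 1:2]
    k3 = theta[:, 2:3]
    Tt = theta[:, 3:4]
    rho = theta[:, 4:5]
    se = se[None, :]
    m_total = rfp[None, :] / (rho * rho_p)
    S = _model._charged_pool(k3, Tt, se, variant.trna_pool_finite)
    if variant.mrna_constrained:
        m_f = _model._free_mrna_from_supply(k1, kF, S, m_total)
    else:
        m_f = np.broadcast_to(m_total, np.broadcast_shapes(m_total.shape, S.shape))
    if variant.charged_pool_depleted:
        SeT_f = S / (1.0 + k1 * m_f)
    else:
        SeT_f = np.broadcast_to(S, np.broadcast_shapes(m_f.shape, np.shape(S)))
    pred = rho * SP_L * (1.0 + kF) / kF * k1 * m_f * SeT_f + rho * SP_S * (1.0 + kF) * m_f
    resid = gfp[None, :] / rho_p - pred
    return np.einsum("ij,ij->i", resid, resid)


def _loss_many(theta, rfp, gfp, se, config: FitConfig) -> np.ndarray:
    out = np.empty(len(theta))
    for start in range(0, len(theta), config.chunk):
        stop = min(start + config.chunk, len(theta))
        out[start:stop] = _loss_batch(
            theta[start:stop], rfp, gfp, se,
            config.rho_p, config.SP_L, config.SP_S, config.variant,
        )
    return out


def _data_arrays(data: pd.DataFrame):
    validate_gps(data)
    if "selenium" not in data.columns:
        raise ValueError("GPS data must carry a `selenium` condition column")
    rfp = data["rfp"].to_numpy(dtype=float)
    gfp = data["gfp"].to_numpy(dtype=float)
    se = data["selenium"].to_numpy(dtype=float)
    if np.any(~np.isfinite(se)):
        raise ValueError("selenium labels must be finite numbers")
    return rfp, gfp, se


def total_loss(params: KineticParameters, data: pd.DataFrame,
               variant: ModelVariant | str = ModelVariant.FULL) -> float:
    """Summed squared residual on the protein scale.

    ``TQ² = Σ_i (P_total,i − P_L,i − P_S,i)²`` with
    ``P_total,i = GFP_i / rho_p`` and predictions evaluated at each
    point's selenium condition.  Zero iff the model reproduces every
    point exactly.
    """
    rfp, gfp, se = _data_arrays(data)
    theta = np.array([[params.k1, params.kF, params.k3, params.T_total, params.rho]])
    return float(
        _loss_batch(theta, rfp, gfp, se, params.rho_p, params.SP_L, params.SP_S, variant)[0]
    )


def fit_control_slopes(
    control_L: pd.DataFrame,
    control_S: pd.DataFrame,
    robust: bool = False,
) -> tuple[float, float]:
    """Slopes of GFP vs RFP for the two single-species control constructs.

    Least squares through the origin by default
    (``slope = Σ rfp·gfp / Σ rfp²``); ``robust=True`` uses the median of
    per-cell GFP/RFP ratios instead.  The full-length control is
    expected to be steeper (more stable protein); a violation warns but
    does not fail.
    """

    def one(dataset: pd.DataFrame) -> float:
        validate_gps(dataset)
        if dataset.empty:
            raise ValueError("control dataset is empty")
        rfp = dataset["rfp"].to_numpy(dtype=float)
        gfp = dataset["gfp"].to_numpy(dtype=float)
        if robust:
            ok = rfp > 0
            if not ok.any():
                raise ValueError("control dataset has no positive rfp values")
            return float(np.median(gfp[ok] / rfp[ok]))
        denom = float(np.dot(rfp, rfp))
        if denom == 0:
            raise ValueError("control dataset has zero rfp variance")
        return float(np.dot(rfp, gfp) / denom)

    SP_L, SP_S = one(control_L), one(control_S)
    if SP_L <= 0 or SP_S <= 0:
        raise ValueError("control slopes must be positive")
    if SP_L <= SP_S:
        warnings.warn(
            "fitted SP_L <= SP_S: full-length control is not steeper than "
            "the truncated control",
            stacklevel=2,
        )
    return SP_L, SP_S


def _rank_order(losses: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Ascending by loss, ties broken by lexicographic parameter order."""
    keys = tuple(centers[:, j] for j in reversed(range(centers.shape[1]))) + (losses,)
    return np.lexsort(keys)


def grid_search(data: pd.DataFrame, config: FitConfig | None = None) -> FitResult:
    """Recursive divide-and-conquer grid search over the five parameters.

    Level 0 evaluates the loss at the log-space midpoints of
    ``blocks``\\ :sup:`5` cells covering the search box.  The ``top_k``
    best cells are then recursively bisected per dimension (each parent
    also survives with halved width, so the best retained loss can only
    improve) until the requested resolution is reached.  Deterministic:
    identical (data, config) give an identical result.
    """
    if config is None:
        config = FitConfig()
    rfp, gfp, se = _data_arrays(data)
    if len(rfp) == 0:
        raise ValueError("no data points to fit")

    lo, hi = config.bounds.log10_arrays()
    ndim = len(SEARCHED_PARAMETERS)
    width0 = (hi - lo) / config.blocks

    # Level 0: all midpoint combinations of the coarse grid.
    axes = [lo[j] + (np.arange(config.blocks) + 0.5) * width0[j] for j in range(ndim)]
    mesh = np.meshgrid(*axes, indexing="ij")
    centers = np.stack([m.ravel() for m in mesh], axis=1)
    losses = _loss_many(10.0 ** centers, rfp, gfp, se, config)

    order = _rank_order(losses, centers)[: config.top_k]
    retained_c = centers[order]
    retained_l = losses[order]
    widths = np.tile(width0, (len(retained_c), 1))
    history = [
        {"level": 0, "evaluated": len(centers), "best_loss": float(retained_l[0])}
    ]
    logger.info("level 0: %d configurations, best loss %.6g", len(centers), retained_l[0])

    offsets = np.array(list(itertools.product((-0.25, 0.25), repeat=ndim)))
    level = 0
    while level < config.max_levels and np.max(widths) > config.resolution:
        level += 1
        # Children: 2^ndim bisections of every retained cell; the parent
        # center is carried over with halved width (loss already known).
        child_c = (retained_c[:, None, :] + offsets[None, :, :] * widths[:, None, :]).reshape(
            -1, ndim
        )
        child_l = _loss_many(10.0 ** child_c, rfp, gfp, se, config)
        pool_c = np.vstack([retained_c, child_c])
        pool_l = np.concatenate([retained_l, child_l])
        pool_w = np.vstack(
            [widths / 2.0, np.repeat(widths / 2.0, len(offsets), axis=0)]
        )
        order = _rank_order(pool_l, pool_c)[: config.top_k]
        retained_c, retained_l, widths = pool_c[order], pool_l[order], pool_w[order]
        history.append(
            {"level": level, "evaluated": len(child_c), "best_loss": float(retained_l[0])}
        )
        logger.info(
            "level %d: %d configurations, best loss %.6g",
            level, len(child_c), retained_l[0],
        )

    # The algorithm's answers are the retained configurations at the
    # final resolution (not the union of every coarse survey cell),
    # deduplicated by cell identity.
    keys = np.round(retained_c, 12)
    _, unique_idx = np.unique(keys, axis=0, return_index=True)
    final_c = retained_c[np.sort(unique_idx)]
    final_l = retained_l[np.sort(unique_idx)]
    order = _rank_order(final_l, final_c)[: config.report_k]
    values = 10.0 ** final_c[order]
    table = pd.DataFrame(values, columns=list(SEARCHED_PARAMETERS))
    table["rho_p"] = config.rho_p
    table["Q2"] = final_l[order]
    return FitResult(table=table, config=config, history=history)


def goodness_of_fit(
    result: FitResult,
    data: pd.DataFrame,
    rfp_bins: int = 50,
) -> pd.DataFrame:
    """Per-condition r² and RMSE of the rank-1 solution.

    Both scores are computed on the mean-GFP-per-RFP-bin summary curve
    (single cells are far too noisy for a meaningful pointwise r²).
    Conditions with fewer than two occupied bins report ``r2 = NaN``.
    """
    from .gps_io import summarize_mean_gfp

    rows = []
    for se_value, group in data.groupby("selenium", sort=True):
        summary = summarize_mean_gfp(group, rfp_bins)
        pred = np.asarray(
            result.predict_gfp(summary["rfp"].to_numpy(), float(se_value)), dtype=float
        )
        obs = summary["mean_gfp"].to_numpy()
        resid = obs - pred
        rmse = float(np.sqrt(np.mean(resid**2)))
        if len(obs) < 2:
            r2 = float("nan")
        else:
            ss_tot = float(np.sum((obs - obs.mean()) ** 2))
            r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
        rows.append({"selenium": float(se_value), "r2": r2, "rmse": rmse, "n_bins": len(obs)})
    return pd.DataFrame(rows)
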