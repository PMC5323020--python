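"""Reading, writing and filtering of GPS single-cell fluorescence tables.

The interchange format is a delimited text table (comma or tab) with
columns ``rfp, gfp[, selenium, construct]``.  Raw cytometry exports of
~10^6 cells per sample are reduced by a two-stage protocol: a 2-D
occupancy filter that discards sparse histogram bins (outlier cells),
then an even-stride subsample of 0.4% of the RFP-sorted points, leaving
roughly 3000 cells per selenium condition for fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FilterConfig",
    "read_gps",
    "write_gps",
    "validate_gps",
    "filter_gps",
    "summarize_mean_gfp",
]

REQUIRED_COLUMNS = ("rfp", "gfp")
OPTIONAL_COLUMNS = ("selenium", "construct")


@dataclass(frozen=True)
class FilterConfig:
    """Two-stage filter settings.

    ``grid_count`` bins per axis for the occupancy filter;
    ``min_bin_occupancy`` is the minimum number of cells a bin must hold
    for its points to survive; ``keep_fraction`` is the fraction kept in
    the RFP-sorted subsample.  ``subsample`` selects the deterministic
    even stride (default, preserves the RFP distribution shape) or a
    seeded uniform random draw for comparison.
    """

    grid_count: int = 2000
    min_bin_occupancy: int = 30
    keep_fraction: float = 0.004
    subsample: str = "stride"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_count < 2:
            raise ValueError("grid_count must be >= 2")
        if self.min_bin_occupancy < 1:
            raise ValueError("min_bin_occupancy must be >= 1")
        if not 0 < self.keep_fraction <= 1:
            raise ValueError("keep_fraction must lie in (0, 1]")
        if self.subsample not in ("stride", "random"):
            raise ValueError("subsample must be 'stride' or 'random'")


def validate_gps(data: pd.DataFrame) -> pd.DataFrame:
    """Check required columns, finiteness and non-negative RFP."""
    for col in REQUIRED_COLUMNS:
        if col not in data.columns:
            raise ValueError(f"GPS table must contain a `{col}` column")
    arr = data[list(REQUIRED_COLUMNS)].to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("GPS table contains non-finite rfp/gfp values")
    if np.any(data["rfp"].to_numpy(dtype=float) < 0):
        raise ValueError("rfp intensities must be non-negative")
    return data


def read_gps(
    path,
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a delimited GPS table (comma or tab, sniffed automatically).

    Non-numeric rows in the rfp/gfp columns are dropped with a warning.
    ``column_map`` renames source columns onto the canonical names, e.g.
    ``{"RFP-A": "rfp", "GFP-A": "gfp"}`` for raw cytometry exports.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") >= first.count(",") else ","
    data = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if column_map:
        data = data.rename(columns=column_map)
    data.columns = [str(c).strip().lower() for c in data.columns]
    if not set(REQUIRED_COLUMNS) <= set(data.columns):
        if data.shape[1] >= 2 and not set(REQUIRED_COLUMNS) & set(data.columns):
            # Positional fallback: first two columns are rfp, gfp.
            rename = {data.columns[0]: "rfp", data.columns[1]: "gfp"}
            data = data.rename(columns=rename)
        else:
            raise ValueError(
                f"{path}: expected columns {REQUIRED_COLUMNS}, found {tuple(data.columns)}"
            )
    n_raw = len(data)
    for col in REQUIRED_COLUMNS:
        data[col] = pd.to_numeric(data[col], errors="coerce")
    data = data.dropna(subset=list(REQUIRED_COLUMNS)).reset_index(drop=True)
    dropped = n_raw - len(data)
    if dropped:
        warnings.warn(f"{path}: dropped {dropped} non-numeric row(s)", stacklevel=2)
    if data.empty:
        raise ValueError(f"{path}: no numeric rfp/gfp rows")
    keep = [c for c in (*REQUIRED_COLUMNS, *OPTIONAL_COLUMNS) if c in data.columns]
    return validate_gps(data[keep])


def write_gps(data: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a GPS table; round-trips float values losslessly."""
    validate_gps(data)
    pd.DataFrame(data).to_csv(path, sep=sep, index=False, float_format="%.17g")


def _filter_one_condition(data: pd.DataFrame, config: FilterConfig) -> pd.DataFrame:
    rfp = data["rfp"].to_numpy(dtype=float)
    gfp = data["gfp"].to_numpy(dtype=float)
    # Stage 1: occupancy filter on a grid_count x grid_count histogram
    # spanning the observed min-max range of each axis.
    if rfp.min() == rfp.max() or gfp.min() == gfp.max():
        warnings.warn(
            "degenerate intensity range; occupancy filter reduced to a single bin",
            stacklevel=3,
        )
        survivors = np.ones(len(data), dtype=bool) if len(data) >= config.min_bin_occupancy else np.zeros(len(data), dtype=bool)
    else:
        edges_r = np.linspace(rfp.min(), rfp.max(), config.grid_count + 1)
        edges_g = np.linspace(gfp.min(), gfp.max(), config.grid_count + 1)
        ir = np.clip(np.searchsorted(edges_r, rfp, side="right") - 1, 0, config.grid_count - 1)
        ig = np.clip(np.searchsorted(edges_g, gfp, side="right") - 1, 0, config.grid_count - 1)
        flat = ir * config.grid_count + ig
        counts = np.bincount(flat, minlength=config.grid_count**2)
        survivors = counts[flat] >= config.min_bin_occupancy
    stage1 = data.loc[survivors]
    if stage1.empty:
        return stage1.reset_index(drop=True)
    # Stage 2: sort by RFP, keep an even-stride subsample so the RFP
    # distribution shape is preserved.
    stage1 = stage1.sort_values("rfp", kind="stable")
    n = len(stage1)
    k = max(1, round(config.keep_fraction * n))
    if k >= n:
        return stage1.reset_index(drop=True)
    if config.subsample == "random":
        rng = np.random.default_rng(config.seed)
        idx = np.sort(rng.choice(n, size=k, replace=False))
    else:
        idx = np.unique(np.round(np.linspace(0, n - 1, k)).astype(int))
    return stage1.iloc[idx].reset_index(drop=True)


def filter_gps(data: pd.DataFrame, config: FilterConfig | None = None) -> pd.DataFrame:
    """Apply the two-stage filter, per selenium condition.

    Output rows are a subset of input rows (no point is ever invented),
    condition labels are preserved, and the procedure is deterministic.
    """
    if config is None:
        config = FilterConfig()
    validate_gps(data)
    if data.empty:
        raise ValueError("cannot filter an empty dataset")
    if "selenium" in data.columns and data["selenium"].nunique() > 1:
        parts = [
            _filter_one_condition(group, config)
            for _, group in data.groupby("selenium", sort=True)
        ]
        return pd.concat(parts, ignore_index=True)
    return _filter_one_condition(data, config)


def summarize_mean_gfp(data: pd.DataFrame, rfp_bins: int | np.ndarray = 50) -> pd.DataFrame:
    """Mean GFP per RFP bin — the summary curve used for fit assessment.

    ``rfp_bins`` is either a bin count over the observed RFP range or an
    explicit edge array.  Empty bins are omitted.  Returns a table with
    columns ``rfp`` (mean RFP of the bin's points — less biased than the
    bin center when the curve bends within a bin), ``mean_gfp`` and ``n``.
    """
    validate_gps(data)
    if data.empty:
        raise ValueError("cannot summarize an empty dataset")
    rfp = data["rfp"].to_numpy(dtype=float)
    gfp = data["gfp"].to_numpy(dtype=float)
    if np.ndim(rfp_bins) == 0:
        if rfp.min() == rfp.max():
            return pd.DataFrame(
                {"rfp": [float(rfp[0])], "mean_gfp": [float(gfp.mean())], "n": [len(gfp)]}
            )
        edges = np.linspace(rfp.min(), rfp.max(), int(rfp_bins) + 1)
    else:
        edges = np.asarray(rfp_bins, dtype=float)
    idx = np.clip(np.searchsorted(edges, rfp, side="right") - 1, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    sums = np.bincount(idx, weights=gfp, minlength=len(edges) - 1)
    rfp_sums = np.bincount(idx, weights=rfp, minlength=len(edges) - 1)
    occupied = counts > 0
    return pd.DataFrame(
        {
            "rfp": rfp_sums[occupied] / counts[occupied],
            "mean_gfp": sums[occupied] / counts[occupied],
            "n": counts[occupied],
        }
    )
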