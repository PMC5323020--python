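"""Published reference values for the SEPHS2 reporter system.

These numbers are literature inputs (published estimates from the
original SEPHS2 GPS study), not outputs of this package: the top ten
parameter sets recovered from the experimental SEPHS2 data, grouped
into two degenerate solution classes, and the SECIS-element comparison
with SECIS-SBP2 dissociation constants.  They are shipped so that users
can compare their own fits against the published optimum.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["sephs2_top10", "secis_comparison"]

_SEPHS2_TOP10 = [
    # (k1, kF, k3, T_total, rho, rho_p, Q2)
    (17.03, 9803.03, 0.02, 63.44, 10.40, 0.95, 1.48e8),
    (17.65, 9704.55, 0.02, 60.63, 10.87, 0.95, 1.48e8),
    (17.96, 10000.00, 0.02, 61.39, 10.75, 0.95, 1.48e8),
    (17.03, 9556.83, 0.02, 61.90, 10.64, 0.95, 1.48e8),
    (17.34, 9852.28, 0.02, 62.67, 10.52, 0.95, 1.48e8),
    (13.13, 8621.24, 0.02, 72.39, 13.32, 0.65, 3.17e8),
    (12.82, 8473.52, 0.02, 72.90, 13.20, 0.65, 3.17e8),
    (13.13, 9768.97, 0.02, 73.66, 13.09, 0.65, 3.17e8),
    (13.13, 8867.45, 0.02, 74.43, 12.97, 0.65, 3.17e8),
    (12.82, 8621.24, 0.02, 74.18, 12.97, 0.65, 3.17e8),
]

_SECIS = [
    # (element, Kd_nM, k1, kF)
    ("SEPHS2", 7.5, 17.0, 9803.0),
    ("GPX1", 6.3, 12.2, 8521.3),
    ("SEPX1", 9.7, 5.7, 9803.0),
    ("SELK", 3.6, 5.7, 8522.8),
]


def sephs2_top10() -> pd.DataFrame:
    """Top ten published SEPHS2 parameter estimates with their losses."""
    return pd.DataFrame(
        _SEPHS2_TOP10,
        columns=["k1", "kF", "k3", "T_total", "rho", "rho_p", "Q2"],
    )


def secis_comparison() -> pd.DataFrame:
    """Published Sec-incorporation strength of four SECIS elements."""
    table = pd.DataFrame(_SECIS, columns=["secis", "Kd_nM", "k1", "kF"])
    table["k1_over_kF"] = table["k1"] / table["kF"]
    return table
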