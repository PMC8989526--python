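"""Bundled reference tables: in-vitro melting/titration data and the
length/deletion profile for d(TCCC)n repeats.

Values are stored verbatim as published.  ``TABLE_PH65`` holds first-
derivative melting (Tm) and annealing (Ta) temperatures with hysteresis and
CD-derived transitional pH at pH 6.5 / 100 mM KCl; ``TABLE_PH53`` holds the
same melting quantities at pH 5.3 (the bisulfite reaction pH).  The profile
table links each assayed genomic locus to its repeat copy number, in-vitro
stability, and the fraction of cloned isolates carrying a 5'-oriented
deletion; quantities never printed as numbers carry provenance "figure" (an
estimate read from a plot) or are stored as counts, and NaN where no
defensible value exists.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .deletion_model import LengthProfile

__all__ = [
    "TABLE_PH65",
    "TABLE_PH53",
    "published_length_profile",
    "hysteresis_consistency",
]

_PH65_ROWS = [
    # n, tm, tm_sd, ta, ta_sd, hysteresis, hysteresis_sd, ph_t, ph_t_se
    (4, 15.6, 1.0, 13.8, 1.2, 1.8, 2.1, 6.6, 0.01),
    (5, 28.3, 0.6, 26.0, 0.6, 2.4, 1.0, 6.7, 0.04),
    (6, 31.4, 0.6, 29.2, 0.0, 2.2, 0.6, 6.8, 0.02),
    (7, 32.8, 1.0, 29.1, 0.0, 3.7, 1.0, 6.8, 0.03),
    (8, 40.7, 0.6, 30.7, 0.6, 10.0, 0.0, 6.9, 0.01),
    (9, 40.7, 0.6, 30.3, 0.6, 10.4, 0.6, 7.1, 0.04),
    (12, 40.2, 0.6, 30.5, 0.0, 9.8, 0.6, 7.2, 0.08),
    (14, 42.0, 4.0, 30.4, 0.0, 11.6, 4.0, 7.1, 0.07),
    (15, 40.2, 4.0, 23.2, 2.0, 16.0, 2.0, 7.1, 0.08),
]

_PH53_ROWS = [
    (5, 50.2, 3.5, 45.8, 3.5, 4.3, 0.5, np.nan, np.nan),
    (9, 66.7, 2.0, 62.0, 2.0, 4.6, 0.5, np.nan, np.nan),
]

_COLUMNS = ["n", "tm", "tm_sd", "ta", "ta_sd", "hysteresis",
            "hysteresis_sd", "ph_t", "ph_t_se"]

TABLE_PH65 = pd.DataFrame(_PH65_ROWS, columns=_COLUMNS)
TABLE_PH53 = pd.DataFrame(_PH53_ROWS, columns=_COLUMNS)


def published_length_profile() -> LengthProfile:
    """The genomic loci assayed for deletions, with in-vitro stability.

    deletion_fraction: TAFA5 and RACK7 are printed values (0% and 100%);
    ABL1 and PLA2G2A showed a deletion in every cloned representative
    (fraction 1.0); BCR yielded a single recovered deletion with no printed
    denominator, so only deletion_count is stored (fraction NaN, dropped by
    association analysis).  ph_t: values for n = 5, 7, 9, 15 are printed;
    n = 11 (ABL1) is the plateau value read from the length-dependence
    figure, provenance "figure".
    """
    table = pd.DataFrame({
        "n": [5, 7, 9, 11, 15],
        "gene": ["TAFA5", "BCR", "RACK7", "ABL1", "PLA2G2A"],
        "ph_t": [6.7, 6.8, 7.1, 7.1, 7.1],
        "tm": [28.3, 32.8, 40.7, np.nan, 40.2],
        "deletion_fraction": [0.0, np.nan, 1.0, 1.0, 1.0],
        "deletion_count": [0, 1, np.nan, np.nan, np.nan],
        "provenance_ph_t": ["table", "table", "table", "figure", "table"],
        "provenance_fraction": ["text", "count", "text", "figure", "figure"],
    })
    return LengthProfile(table=table)


def hysteresis_consistency(table: pd.DataFrame = TABLE_PH65,
                           tol: float = 0.15) -> pd.DataFrame:
    """Check printed hysteresis against Tm - Ta, row by row.

    Returns the table with ``tm_minus_ta``, ``discrepancy`` and a
    ``flagged`` column marking rows whose printed hysteresis differs from
    the recomputed difference by more than ``tol`` degC (rounding noise is
    expected at the printed precision; larger discrepancies indicate a
    different pairing of replicate values).
    """
    out = table.copy()
    out["tm_minus_ta"] = out["tm"] - out["ta"]
    out["discrepancy"] = (out["hysteresis"] - out["tm_minus_ta"]).abs()
    out["flagged"] = out["discrepancy"] > tol + 1e-12
    return out
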