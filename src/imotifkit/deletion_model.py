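"""Suppression-failure probability and the length/stability/deletion profile.

If an i-motif at a genomic repeat escapes suppression (resolution by repair
or replication machinery) with per-replication-cycle probability p, the
probability that it impairs replication at least once over c cycles is
1 - (1 - p)^c.  With p = 0.05 over 25 cycles this is 0.72, enough for the
stochastic accumulation of deletions in a long-cultured, repair-compromised
cell line.

The length profile relates repeat copy number n to in-vitro i-motif
stability (transitional pH and Tm) and to the fraction of cloned isolates
carrying a 5'-oriented deletion; a monotone association is summarised by a
Spearman rank correlation, and the threshold claim — every element whose
transitional pH exceeds a cutoff shows deletions in all clones — is checked
directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "SuppressionModel",
    "LengthProfile",
    "ProfileAssociation",
    "impairment_probability",
    "profile_association",
]

_PROFILE_COLUMNS = ["n", "gene", "ph_t", "tm", "deletion_fraction"]


@dataclass(frozen=True)
class SuppressionModel:
    """Per-cycle escape probability and number of replication cycles."""

    p_unsuppressed: float
    cycles: int

    def __post_init__(self):
        if not 0.0 <= self.p_unsuppressed <= 1.0:
            raise ValueError("p_unsuppressed must be a probability")
        if self.cycles < 1:
            raise ValueError("cycles must be a positive integer")


def impairment_probability(model: SuppressionModel) -> float:
    """P(impaired at least once in c cycles) = 1 - (1 - p)^c.

    Evaluated in log space for numerical stability at small p.
    """
    p, c = model.p_unsuppressed, model.cycles
    if p >= 1.0:
        return 1.0
    return -math.expm1(c * math.log1p(-p))


@dataclass
class LengthProfile:
    """Rows of (n, gene, ph_t, tm, deletion_fraction), n strictly increasing.

    Missing values (NaN) are allowed where a quantity was never printed;
    association analysis drops incomplete rows.
    """

    table: pd.DataFrame

    def __post_init__(self):
        missing = set(_PROFILE_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"profile missing columns {sorted(missing)}")
        n = self.table["n"].to_numpy()
        if np.any(np.diff(n) <= 0):
            raise ValueError("n must be strictly increasing")
        frac = self.table["deletion_fraction"].dropna()
        if ((frac < 0) | (frac > 1)).any():
            raise ValueError("deletion fractions must lie in [0, 1]")


@dataclass(frozen=True)
class ProfileAssociation:
    """Spearman rho (None when undefined) and the pH-threshold check."""

    rho: float | None
    threshold_consistency: bool
    n_used: int


def profile_association(profile: LengthProfile,
                        ph_threshold: float = 7.0) -> ProfileAssociation:
    """Rank correlation of ph_t vs deletion fraction, plus threshold check.

    Rows with a missing ph_t or deletion_fraction are dropped; at least 4
    complete rows are required.  ``rho`` is the Spearman rank correlation
    (ties mid-ranked); it is returned as ``None`` — an explicit sentinel,
    never silently 0 — when either column is constant.
    ``threshold_consistency`` is True iff every row with ph_t above the
    threshold has deletion_fraction exactly 1.0.
    """
    rows = profile.table.dropna(subset=["ph_t", "deletion_fraction"])
    if len(rows) < 4:
        raise ValueError("need at least 4 complete profile rows")
    ph = rows["ph_t"].to_numpy(dtype=float)
    frac = rows["deletion_fraction"].to_numpy(dtype=float)
    if np.all(ph == ph[0]) or np.all(frac == frac[0]):
        rho = None
    else:
        rho = float(spearmanr(ph, frac).statistic)
    above = frac[ph > ph_threshold]
    consistent = bool(np.all(above == 1.0))
    return ProfileAssociation(rho=rho, threshold_consistency=consistent,
                              n_used=len(rows))
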