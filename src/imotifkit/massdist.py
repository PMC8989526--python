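"""Oligonucleotide masses and dU-count assignment for deconvoluted spectra.

Bisulfite deaminates cytosine to uracil; on an intact oligonucleotide each
dC->dU conversion raises the neutral mass by ~1 Da (0.984 Da on the average
mass scale).  Given a deconvoluted neutral-mass peak list, each peak is
assigned a conversion count k by its offset from the unconverted reference
mass on the Delta-m ladder, and the abundance-weighted distribution of k
summarises how many cytosines reacted per molecule.  Peaks below the
reference mass are strand-breakage fragments and feed the complement of the
intact fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RESIDUE_AVERAGE_MASS",
    "DELTA_M_DU",
    "PeakList",
    "SpeciesTable",
    "DistributionStats",
    "oligo_mass",
    "assign_du_counts",
    "distribution_stats",
]

# Average residue masses (Da) of the nucleoside-5'-monophosphate residues
# within a DNA chain; the 5'-OH terminus removes one HPO3 + adds H2O (61.96).
RESIDUE_AVERAGE_MASS = {
    "A": 313.21,
    "C": 289.18,
    "G": 329.21,
    "T": 304.20,
    "U": 290.17,
}
_TERMINUS_5OH = -61.96
_PHOSPHATE = 79.98

# dU - dC mass difference (Da): -NH2 +OH on the base, 0.984 on the average
# mass scale.  The 2-dp residue table above rounds this to 0.99.
DELTA_M_DU = 0.984


def oligo_mass(sequence: str, terminus: str = "5'-OH") -> float:
    """Average neutral mass (Da) of an oligodeoxynucleotide.

    ``terminus`` is "5'-OH" (synthetic oligo convention) or "5'-phosphate"
    (adds 79.98 Da).
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    try:
        total = sum(RESIDUE_AVERAGE_MASS[b] for b in seq)
    except KeyError as exc:
        raise ValueError(f"unknown base {exc.args[0]!r}") from None
    total += _TERMINUS_5OH
    if terminus == "5'-phosphate":
        total += _PHOSPHATE
    elif terminus != "5'-OH":
        raise ValueError("terminus must be \"5'-OH\" or \"5'-phosphate\"")
    return round(total, 6)


@dataclass
class PeakList:
    """Deconvoluted neutral-mass peaks with abundances."""

    masses: np.ndarray
    abundances: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.masses.shape != self.abundances.shape:
            raise ValueError("masses and abundances must match in length")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        if not np.all(np.isfinite(self.abundances)) or np.any(self.abundances < 0):
            raise ValueError("abundances must be finite and nonnegative")


@dataclass(frozen=True)
class SpeciesTable:
    """Abundance-weighted dU-count distribution derived from a peak list.

    ``frequencies`` maps k (dU count) to its share of the assigned
    abundance; frequencies sum to 1.  ``intact_fraction`` is the share of
    total abundance at masses at or above the reference (full-length
    molecules, converted or not).
    """

    frequencies: dict[int, float]
    unassigned_fraction: float
    intact_fraction: float
    n_cytosines: int
    total_abundance: float


@dataclass(frozen=True)
class DistributionStats:
    mode_k: int
    mean_k: float
    intact_fraction: float


def assign_du_counts(peaks: PeakList, ref_mass: float, n_cytosines: int,
                     delta_m: float = DELTA_M_DU, tol: float = 0.35) -> SpeciesTable:
    """Assign each peak a dU count on the ref_mass + k*delta_m ladder.

    A peak is assigned k = round((mass - ref_mass) / delta_m) when
    0 <= k <= n_cytosines and the residual from the ladder rung is within
    ``tol``; otherwise it contributes to the unassigned fraction.
    ``tol`` must stay below delta_m/2 so assignments are unambiguous.
    """
    if delta_m <= 0:
        raise ValueError("delta_m must be positive")
    if not 0 < tol < delta_m / 2:
        raise ValueError("tol must lie in (0, delta_m/2)")
    if peaks.masses.size == 0:
        raise ValueError("empty peak list")
    total = float(peaks.abundances.sum())
    if total <= 0:
        raise ValueError("peak list has zero total abundance")

    freqs: dict[int, float] = {}
    assigned = 0.0
    for mass, ab in zip(peaks.masses, peaks.abundances):
        k = int(round((mass - ref_mass) / delta_m))
        if 0 <= k <= n_cytosines and abs(mass - (ref_mass + k * delta_m)) <= tol:
            freqs[k] = freqs.get(k, 0.0) + ab
            assigned += ab
    if assigned > 0:
        freqs = {k: v / assigned for k, v in sorted(freqs.items())}
    intact = float(peaks.abundances[peaks.masses >= ref_mass - tol].sum()) / total
    return SpeciesTable(frequencies=freqs,
                        unassigned_fraction=1.0 - assigned / total,
                        intact_fraction=intact,
                        n_cytosines=n_cytosines,
                        total_abundance=total)


def distribution_stats(table: SpeciesTable) -> DistributionStats:
    """Mode (tie -> smallest k) and abundance-weighted mean of the dU counts."""
    if not table.frequencies:
        raise ValueError("no assigned species in table")
    best = max(table.frequencies.values())
    mode_k = min(k for k, f in table.frequencies.items() if f == best)
    mean_k = sum(k * f for k, f in table.frequencies.items())
    return DistributionStats(mode_k=mode_k, mean_k=mean_k,
                             intact_fraction=table.intact_fraction)
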