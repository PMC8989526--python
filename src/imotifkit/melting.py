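"""UV melting analysis: first-derivative Tm/Ta, hysteresis, and TDS.

A melting experiment records absorbance at 295 nm while ramping temperature
up (melt) and back down (anneal).  i-Motif unfolding is hypochromic at
295 nm, so the melt transition appears as a drop in absorbance; folding is
slow, so the annealing midpoint Ta lags the melting midpoint Tm and the
difference (hysteresis) reports on folding kinetics.  Midpoints are taken by
the first-derivative method: the temperature at which |dA/dT| is maximal,
after local-quadratic smoothing, refined below grid resolution by parabolic
interpolation.

A thermal difference spectrum (TDS) is the unfolded-minus-folded absorbance
spectrum (95 C minus 4 C) normalised so its maximum equals +1; its shape is
a structural fingerprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MeltCurve",
    "MeltResult",
    "Spectrum",
    "TDSpectrum",
    "first_derivative_midpoint",
    "melt_stats",
    "compute_tds",
]


@dataclass
class MeltCurve:
    """One temperature ramp of A295 readings.

    ``direction`` is "melt" (heating) or "anneal" (cooling).  The grid must
    be monotone once duplicate-temperature hold points are dropped, and must
    carry at least 10 points.
    """

    temperatures: np.ndarray
    signal: np.ndarray
    direction: str = "melt"
    replicate_id: int = 0
    label: str = ""
    buffer: tuple[float, float] | None = None  # (pH, KCl mM)

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.direction not in ("melt", "anneal"):
            raise ValueError("direction must be 'melt' or 'anneal'")
        if self.temperatures.shape != self.signal.shape:
            raise ValueError("temperatures and signal must match in length")
        if self.temperatures.size < 10:
            raise ValueError("a melt curve needs at least 10 points")
        d = np.diff(self.temperatures)
        if not (np.all(d >= 0) or np.all(d <= 0)):
            raise ValueError("temperature grid must be monotone")


@dataclass(frozen=True)
class MeltResult:
    """Replicate-averaged melting statistics (deg C)."""

    tm_mean: float
    tm_sd: float
    ta_mean: float
    ta_sd: float
    hysteresis: float
    n_melt: int
    n_anneal: int


@dataclass
class Spectrum:
    """A wavelength scan (nm, absorbance or ellipticity)."""

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape:
            raise ValueError("wavelengths and values must match in length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")


@dataclass(frozen=True)
class TDSpectrum:
    """Normalised thermal difference spectrum (max delta = +1)."""

    wavelengths: np.ndarray
    delta: np.ndarray


def _dedup_sorted(t: np.ndarray, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # ascending order, then drop duplicate temperatures (instrument holds)
    order = np.argsort(t, kind="mergesort")
    t, a = t[order], a[order]
    keep = np.concatenate([[True], np.diff(t) > 0])
    return t[keep], a[keep]


def _local_quadratic_smooth(t: np.ndarray, a: np.ndarray, window: int) -> np.ndarray:
    """Moving-window least-squares quadratic smoothing on a possibly uneven grid."""
    n = t.size
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        if hi - lo < 3:
            out[i] = a[i]
            continue
        x = t[lo:hi] - t[i]
        coef = np.polynomial.polynomial.polyfit(x, a[lo:hi], 2)
        out[i] = coef[0]
    return out


def first_derivative_midpoint(curve: MeltCurve, window: int = 5) -> float | None:
    """Transition midpoint by the first-derivative method, or None.

    Returns the temperature of the global extremum of |dA/dT| after
    local-quadratic smoothing, refined by parabolic interpolation through the
    extremum and its two neighbours.  Returns ``None`` when no extremum rises
    above the derivative noise floor (flat or featureless curve).
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if window > curve.temperatures.size:
        raise ValueError("window exceeds curve length")
    if not np.all(np.isfinite(curve.signal)):
        raise ValueError("signal contains non-finite values")

    t, a = _dedup_sorted(curve.temperatures, curve.signal)
    if t.size < 3:
        return None
    smooth = _local_quadratic_smooth(t, a, window)

    # no-transition guard: the smoothed signal must swing well beyond the
    # residual noise left by smoothing
    resid = a - smooth
    sigma = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    amplitude = float(smooth.max() - smooth.min())
    if amplitude <= max(8.0 * sigma, 1e-12):
        return None

    deriv = np.abs(np.gradient(smooth, t))
    i = int(np.argmax(deriv))

    if 0 < i < t.size - 1:
        # parabola through the three samples around the extremum
        x0, x1, x2 = t[i - 1], t[i], t[i + 1]
        y0, y1, y2 = deriv[i - 1], deriv[i], deriv[i + 1]
        denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
        A = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
        B = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
        if A < 0:
            vertex = -B / (2 * A)
            return float(np.clip(vertex, x0, x2))
    return float(t[i])


def melt_stats(curves: list[MeltCurve], window: int = 5,
               hysteresis_mode: str = "mean_of_means") -> MeltResult:
    """Aggregate replicate melt/anneal curves into Tm, Ta and hysteresis.

    Midpoints are estimated per replicate and then averaged per direction;
    the sample standard deviation (ddof=1) is reported, 0 for singletons.
    ``hysteresis_mode`` "mean_of_means" reports tm_mean - ta_mean;
    "per_replicate" averages the per-replicate-pair differences (the two
    agree for balanced designs but differ for unpaired replicates).
    """
    if hysteresis_mode not in ("mean_of_means", "per_replicate"):
        raise ValueError("unknown hysteresis_mode")
    labels = {(c.label, c.buffer) for c in curves}
    if len(labels) > 1:
        raise ValueError(f"curves mix labels/buffers: {sorted(map(str, labels))}")
    mids = {"melt": [], "anneal": []}
    for c in curves:
        m = first_derivative_midpoint(c, window=window)
        if m is None:
            raise ValueError(f"no transition in {c.direction} replicate "
                             f"{c.replicate_id}")
        mids[c.direction].append(m)
    if not mids["melt"] or not mids["anneal"]:
        raise ValueError("need at least one melt and one anneal replicate")

    def _mean_sd(xs):
        xs = np.asarray(xs)
        return float(xs.mean()), float(xs.std(ddof=1)) if xs.size > 1 else 0.0

    tm_mean, tm_sd = _mean_sd(mids["melt"])
    ta_mean, ta_sd = _mean_sd(mids["anneal"])
    if hysteresis_mode == "per_replicate" and len(mids["melt"]) == len(mids["anneal"]):
        hyst = float(np.mean(np.asarray(mids["melt"]) - np.asarray(mids["anneal"])))
    else:
        hyst = tm_mean - ta_mean
    return MeltResult(tm_mean, tm_sd, ta_mean, ta_sd, hyst,
                      len(mids["melt"]), len(mids["anneal"]))


def compute_tds(folded: Spectrum, unfolded: Spectrum,
                lo: float = 220.0, hi: float = 320.0) -> TDSpectrum:
    """Thermal difference spectrum: unfolded (95 C) minus folded (4 C), max=+1.

    Spectra are restricted to [lo, hi] intersected with the common wavelength
    range; the unfolded spectrum is interpolated onto the folded grid when
    the grids differ.  Raises if the difference has no positive maximum
    (normalisation undefined).
    """
    w_lo = max(lo, folded.wavelengths[0], unfolded.wavelengths[0])
    w_hi = min(hi, folded.wavelengths[-1], unfolded.wavelengths[-1])
    if w_hi <= w_lo:
        raise ValueError("spectra have no common wavelength range")
    mask = (folded.wavelengths >= w_lo) & (folded.wavelengths <= w_hi)
    wl = folded.wavelengths[mask]
    if wl.size < 2:
        raise ValueError("insufficient wavelength coverage")
    a4 = folded.values[mask]
    a95 = np.interp(wl, unfolded.wavelengths, unfolded.values)
    delta = a95 - a4
    mx = delta.max()
    if mx <= 0:
        raise ValueError("degenerate TDS: difference has no positive maximum")
    return TDSpectrum(wavelengths=wl, delta=delta / mx)
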