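"""CD pH-titration fitting (transitional pH) and CD signature classification.

i-Motif folding is proton-coupled: lowering the pH protonates cytosine N3
and drives C:C+ pairing.  Following the ellipticity at 288 nm (the positive
i-motif CD band) across a pH series traces a sigmoid whose inflection is the
transitional pH, pH_T — the pH at which half the molecules are folded.  The
series is fitted to a four-parameter Hill sigmoid

    theta(pH) = theta_u + (theta_f - theta_u) / (1 + 10^(n_H (pH - pH_T)))

by nonlinear least squares; theta_f is the folded (low-pH) baseline.  The
folded fraction at any pH follows from the same fit.  CD wavelength scans
are classified by their band signature: a positive band near 288 nm with a
negative band near 265 nm is the i-motif signature, while a positive band
near 264 nm with a negative band near 240 nm marks a parallel G-quadruplex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, savgol_filter

from .melting import Spectrum

__all__ = [
    "TitrationSeries",
    "TitrationFit",
    "CDSpectrum",
    "fit_titration",
    "fraction_folded",
    "classify_spectrum",
]

HILL_BOUNDS = (0.2, 10.0)

CDSpectrum = Spectrum  # wavelength (nm) vs ellipticity (mdeg)


@dataclass
class TitrationSeries:
    """Ellipticity at 288 nm versus pH for one replicate."""

    ph: np.ndarray
    ellipticity: np.ndarray
    replicate_id: int = 0
    label: str = ""

    def __post_init__(self):
        self.ph = np.asarray(self.ph, dtype=float)
        self.ellipticity = np.asarray(self.ellipticity, dtype=float)
        if self.ph.shape != self.ellipticity.shape:
            raise ValueError("ph and ellipticity must match in length")
        distinct = np.unique(self.ph)
        if distinct.size < 6:
            raise ValueError("need at least 6 distinct pH points")
        if distinct.max() - distinct.min() < 1.5:
            raise ValueError("pH series must span at least 1.5 units")


@dataclass(frozen=True)
class TitrationFit:
    """Fitted Hill sigmoid: pH_T with SE, slope n_H, and baselines (mdeg)."""

    ph_t: float
    ph_t_se: float
    hill: float
    theta_folded: float
    theta_unfolded: float
    rss: float
    extrapolated: bool = False


def _model(ph, ph_t, hill, theta_f, theta_u):
    return theta_u + (theta_f - theta_u) / (1.0 + 10.0 ** (hill * (ph - ph_t)))


def fit_titration(series: TitrationSeries | list[TitrationSeries]) -> TitrationFit:
    """Fit pH_T (inflection point) by nonlinear least squares.

    Accepts one series or a list of replicates, pooled into a single fit.
    Initialisation: the folded/unfolded baselines from the 10% extreme-pH
    quantiles, pH_T from linear interpolation of the half-amplitude
    crossing, n_H = 1.  The Hill slope is bounded to (0.2, 10] to exclude
    degenerate step fits.  pH_T_SE comes from the parameter covariance.
    """
    if isinstance(series, TitrationSeries):
        series = [series]
    ph = np.concatenate([s.ph for s in series])
    theta = np.concatenate([s.ellipticity for s in series])
    order = np.argsort(ph, kind="mergesort")
    ph, theta = ph[order], theta[order]

    k = max(1, int(round(0.1 * ph.size)))
    theta_f0 = float(theta[:k].mean())   # low pH: folded
    theta_u0 = float(theta[-k:].mean())  # high pH: unfolded
    if theta_f0 == theta_u0:
        raise ValueError("degenerate series: no amplitude between baselines")
    half = 0.5 * (theta_f0 + theta_u0)
    # first crossing of the half-amplitude level
    sgn = np.sign(theta - half)
    idx = np.nonzero(np.diff(sgn) != 0)[0]
    if idx.size:
        i = idx[0]
        x0, x1 = ph[i], ph[i + 1]
        y0, y1 = theta[i], theta[i + 1]
        ph_t0 = x0 if y1 == y0 else x0 + (half - y0) * (x1 - x0) / (y1 - y0)
    else:
        ph_t0 = float(ph.mean())

    amp = abs(theta_f0 - theta_u0)
    lo = [ph.min() - 1.0, HILL_BOUNDS[0], -np.inf, -np.inf]
    hi = [ph.max() + 1.0, HILL_BOUNDS[1], np.inf, np.inf]
    p0 = [float(np.clip(ph_t0, lo[0], hi[0])), 1.0, theta_f0, theta_u0]
    popt, pcov = curve_fit(_model, ph, theta, p0=p0, bounds=(lo, hi),
                           maxfev=20000)
    resid = theta - _model(ph, *popt)
    rss = float(resid @ resid)
    dof = max(1, ph.size - 4)
    noise = np.sqrt(rss / dof)
    if noise > 0 and abs(popt[2] - popt[3]) <= 3.0 * noise:
        raise ValueError("signal amplitude does not exceed 3x noise estimate")
    ph_t_se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.nan
    extrapolated = not (ph.min() <= popt[0] <= ph.max())
    return TitrationFit(ph_t=float(popt[0]), ph_t_se=ph_t_se,
                        hill=float(popt[1]), theta_folded=float(popt[2]),
                        theta_unfolded=float(popt[3]), rss=rss,
                        extrapolated=extrapolated)


def fraction_folded(fit: TitrationFit, ph):
    """Folded fraction 1 / (1 + 10^(n_H (pH - pH_T))); 0.5 at pH_T."""
    ph = np.asarray(ph, dtype=float)
    f = 1.0 / (1.0 + 10.0 ** (fit.hill * (ph - fit.ph_t)))
    return float(f) if f.ndim == 0 else f


# CD band windows (nm): (positive band, negative band)
_I_MOTIF_BANDS = ((285.0, 292.0), (255.0, 270.0))
_PARALLEL_G4_BANDS = ((260.0, 268.0), (235.0, 245.0))


def _band_peaks(wl, y, prominence):
    pos, _ = find_peaks(y, height=0.0, prominence=prominence)
    neg, _ = find_peaks(-y, height=0.0, prominence=prominence)
    return wl[pos], wl[neg]


def classify_spectrum(spectrum: CDSpectrum) -> str:
    """Classify a CD scan as i_motif, parallel_g4 or unfolded_or_other."""
    wl, y = spectrum.wavelengths, spectrum.values
    if wl[0] > 230.0 or wl[-1] < 310.0:
        raise ValueError("spectrum must cover 230-310 nm")
    if wl.size >= 7:
        win = min(11, wl.size if wl.size % 2 else wl.size - 1)
        y = savgol_filter(y, window_length=win, polyorder=3)
    span = float(y.max() - y.min())
    if span <= 0:
        return "unfolded_or_other"
    pos_wl, neg_wl = _band_peaks(wl, y, prominence=0.05 * span)

    def in_band(values, band):
        return any(band[0] <= v <= band[1] for v in values)

    for label, (pos_band, neg_band) in (("i_motif", _I_MOTIF_BANDS),
                                        ("parallel_g4", _PARALLEL_G4_BANDS)):
        if in_band(pos_wl, pos_band) and in_band(neg_wl, neg_band):
            return label
    return "unfolded_or_other"
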