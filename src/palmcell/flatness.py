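"""Cell tilt/flatness QC from multi-plane membrane images, and
surface-immobilization movement QC.

A dividing cell imaged across z shows two pole peaks in its axial membrane
profile at the plane of the open septum center (z = 0) and a third,
midcell peak away from it.  Writing d_R and d_L for the distances from the
central peak to the right and left pole peaks: on a flat cell the profile
stays symmetric, so d_R and d_L decrease together or stay unchanged across
z; on a tilted cell the pole peaks shift laterally with z, so d_R grows
while d_L shrinks on one side of focus and the reverse on the other.  The
verdict therefore tests for opposite-signed, significant slopes of d_R(z)
and d_L(z).

Movement QC tracks cell-edge positions over time via Gaussian edge fits
and evaluates the pairwise center displacement statistic
``psi(t) = |(X_j,t - X_k,t)/2 - (X_j,0 - X_k,0)/2|``, which is invariant
under common drift of the whole field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks
from scipy.stats import linregress

from .cells import IntensityProfile
from .errors import ParameterError


# ---------------------------------------------------------------------------
# multi-Gaussian peak fitting
# ---------------------------------------------------------------------------

@dataclass
class PeakFit:
    positions_nm: np.ndarray
    position_ses_nm: np.ndarray
    n_peaks: int
    converged: bool


def _multi_gauss(x, baseline, *params):
    y = np.full_like(x, baseline, dtype=float)
    for i in range(0, len(params), 3):
        a, mu, sigma = params[i : i + 3]
        y = y + a * np.exp(-((x - mu) ** 2) / (2 * sigma**2))
    return y


def _fit_k_gaussians(x, y, k):
    """Fit baseline + k Gaussians; returns (positions, ses, sse) or None.

    Initial peak positions come from prominence-ranked local maxima with a
    minimum mutual distance; bounds keep components inside the sampled
    range and stop them from collapsing onto one another.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    span = x[-1] - x[0]
    step = span / max(len(x) - 1, 1)
    amp = float(y.max() - y.min())
    prom = max(amp * 0.05, 1e-12)
    min_dist = max(int(span / (6 * step) / max(k, 1)), 1)
    peaks, props = find_peaks(y, prominence=prom, distance=min_dist)
    order = np.argsort(props["prominences"])[::-1]
    guesses = list(x[peaks[order][:k]])
    while len(guesses) < k:
        guesses.append(x[0] + span * (len(guesses) + 0.5) / k)
    guesses.sort()
    p0 = [float(y.min())]
    lo = [float(y.min()) - amp]
    hi = [float(y.max())]
    sigma0 = max(span / 30, step)
    for mu in guesses:
        p0 += [amp, float(mu), sigma0]
        lo += [0.0, float(x[0]), step / 2]
        hi += [2 * amp + 1e-9, float(x[-1]), span / 4]
    try:
        popt, pcov = curve_fit(
            _multi_gauss, x, y, p0=p0, bounds=(lo, hi), maxfev=20000, method="trf"
        )
    except (RuntimeError, ValueError):
        return None
    resid = y - _multi_gauss(x, *popt)
    sse = float(np.sum(resid**2))
    mus = popt[2::3]
    ses = np.sqrt(np.clip(np.diag(pcov)[2::3], 0, None))
    srt = np.argsort(mus)
    mus, ses = np.asarray(mus)[srt], np.asarray(ses)[srt]
    # reject degenerate fits: overlapping components cannot be read as
    # distinct structural peaks
    if k > 1 and np.min(np.diff(mus)) < 3 * step:
        return None
    return mus, ses, sse


def fit_three_peaks(profile: IntensityProfile) -> PeakFit:
    """Fit a 2- or 3-component Gaussian mixture to an axial profile.

    The model order is chosen by BIC on the residuals; a flat or unfittable
    profile yields ``converged=False``.
    """
    x, y = profile.positions_nm, profile.intensities
    if len(x) < 8 or y.std() < 1e-9:
        return PeakFit(np.array([]), np.array([]), 0, False)
    fits = {}
    for k in (2, 3):
        res = _fit_k_gaussians(x, y, k)
        if res is not None:
            mus, ses, sse = res
            n = len(x)
            n_par = 1 + 3 * k
            bic = n * math.log(max(sse / n, 1e-300)) + n_par * math.log(n)
            fits[k] = (mus, ses, bic)
    if not fits:
        return PeakFit(np.array([]), np.array([]), 0, False)
    k_best = min(fits, key=lambda k: fits[k][2])
    mus, ses, _ = fits[k_best]
    return PeakFit(mus, ses, k_best, True)


def fit_cell_edges(profile: IntensityProfile) -> tuple[float, float] | None:
    """Left/right edge positions from a 2-Gaussian + baseline fit, or None."""
    res = _fit_k_gaussians(profile.positions_nm, profile.intensities, 2)
    if res is None:
        return None
    mus, _, _ = res
    return float(mus[0]), float(mus[1])


# ---------------------------------------------------------------------------
# tilt assessment
# ---------------------------------------------------------------------------

@dataclass
class TiltAssessment:
    """Per-plane peak geometry and the flat/inclined verdict."""

    z_positions_nm: np.ndarray
    d_r_nm: np.ndarray  # NaN where a plane had no 3-peak fit
    d_l_nm: np.ndarray
    verdict: str | None = None  # "flat" | "inclined"
    tilt_deg: float | None = None
    peak_fits: list = field(default_factory=list)


def classify_tilt(assessment: TiltAssessment) -> str:
    """Flat/inclined verdict from the trends of d_R(z) and d_L(z).

    Inclined iff the two slopes have opposite signs and each exceeds its
    standard error; symmetric shrinking (defocus) or constancy is flat.
    Requires >= 3 planes with a valid 3-peak fit.
    """
    ok = np.isfinite(assessment.d_r_nm) & np.isfinite(assessment.d_l_nm)
    if ok.sum() < 3:
        raise ParameterError("tilt verdict needs >= 3 z-planes with fitted d_R and d_L")
    z = assessment.z_positions_nm[ok]
    fit_r = linregress(z, assessment.d_r_nm[ok])
    fit_l = linregress(z, assessment.d_l_nm[ok])
    opposite = fit_r.slope * fit_l.slope < 0
    significant = abs(fit_r.slope) > fit_r.stderr and abs(fit_l.slope) > fit_l.stderr
    assessment.verdict = "inclined" if (opposite and significant) else "flat"
    if assessment.verdict == "inclined":
        # mean absolute lateral peak shift per unit z ~ tan(tilt)
        shift_per_z = (abs(fit_r.slope) + abs(fit_l.slope)) / 2
        assessment.tilt_deg = math.degrees(math.atan(shift_per_z))
    return assessment.verdict


def assess_tilt(
    profiles: list[IntensityProfile],
    z_positions_nm: np.ndarray,
) -> TiltAssessment:
    """Fit peaks on each plane's axial profile and classify the tilt."""
    d_r, d_l, fits = [], [], []
    for prof in profiles:
        fit = fit_three_peaks(prof)
        fits.append(fit)
        if fit.converged and fit.n_peaks == 3:
            left, center, right = fit.positions_nm
            d_r.append(right - center)
            d_l.append(center - left)
        else:
            d_r.append(np.nan)
            d_l.append(np.nan)
    assessment = TiltAssessment(
        z_positions_nm=np.asarray(z_positions_nm, dtype=float),
        d_r_nm=np.asarray(d_r),
        d_l_nm=np.asarray(d_l),
        peak_fits=fits,
    )
    classify_tilt(assessment)
    return assessment


def stack_axial_profiles(
    planes: np.ndarray, pixel_size_nm: float, band_px: int = 1
) -> list[IntensityProfile]:
    """Axial line profiles per z-plane for a single-cell stack.

    The line passes through the cell poles and the septum center: a narrow
    band (``2*band_px + 1`` rows) around the cell's central row, averaged.
    A narrow band is essential — averaging across the full cell width
    washes out the pole peaks that the tilt diagnostic reads.
    """
    mid = planes[len(planes) // 2]
    row_sum = mid.sum(axis=1) - mid.sum(axis=1).min()
    weights = row_sum / row_sum.sum()
    center_row = int(round(float(np.arange(len(row_sum)) @ weights)))
    lo = max(center_row - band_px, 0)
    hi = min(center_row + band_px + 1, planes.shape[1])
    profiles = []
    for plane in planes:
        y = plane[lo:hi].mean(axis=0)
        x = (np.arange(plane.shape[1]) + 0.5) * pixel_size_nm
        profiles.append(IntensityProfile(positions_nm=x, intensities=y))
    return profiles


def min_detectable_tilt(precision_nm: float, z_step_nm: float) -> float:
    """Minimal detectable tilt angle, in degrees: arctan(precision/z_step).

    The geometric convention of this package: a tilt is resolvable once the
    lateral peak shift between adjacent z-planes exceeds the localization
    precision of the peak position.
    """
    if precision_nm < 0 or z_step_nm <= 0:
        raise ParameterError("precision must be >= 0 and z_step > 0")
    return math.degrees(math.atan(precision_nm / z_step_nm))


# ---------------------------------------------------------------------------
# movement QC
# ---------------------------------------------------------------------------

@dataclass
class MovementSeries:
    """Per-time left/right edge positions for several cells (nm).

    Arrays are (n_cells, n_times); NaN marks a missing edge fit.
    """

    x_left: np.ndarray
    x_right: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        self.x_left = np.asarray(self.x_left, dtype=float)
        self.x_right = np.asarray(self.x_right, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.x_left.shape != self.x_right.shape:
            raise ParameterError("x_left and x_right must have the same shape")
        if self.x_left.shape[1] != len(self.times):
            raise ParameterError("time axis mismatch")

    @property
    def centers(self) -> np.ndarray:
        return (self.x_left + self.x_right) / 2


def movement_displacement(series: MovementSeries) -> dict:
    """Pairwise center displacement psi(t) for consecutive cell pairs.

    psi_jk(t) = |(X_j,t - X_k,t)/2 - (X_j,0 - X_k,0)/2| with X the edge-pair
    midpoint; psi(0) = 0 by construction and a common translation of all
    cells cancels exactly.  Pairs with a missing edge fit at a time point
    are skipped (NaN) there.  Returns per-pair psi plus mean +/- sd over
    pairs.
    """
    X = series.centers
    n_cells, n_times = X.shape
    if n_cells < 2 or n_times < 2:
        raise ParameterError("need >= 2 cells and >= 2 time points")
    pairs = [(j, j + 1) for j in range(n_cells - 1)]
    psi = np.full((len(pairs), n_times), np.nan)
    for p, (j, k) in enumerate(pairs):
        half_sep = (X[j] - X[k]) / 2
        psi[p] = np.abs(half_sep - half_sep[0])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(psi, axis=0)
        sd = np.nanstd(psi, axis=0)
    return {"psi_nm": psi, "pairs": pairs, "mean_nm": mean, "sd_nm": sd, "times": series.times}
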