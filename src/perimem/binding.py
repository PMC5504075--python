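"""Binding isotherms, association kinetics and lamellar stack geometry.

Three small analyses accompany the reflectometry pipeline:

* SPR saturation titrations are fitted with the four-parameter logistic
  dose-response model

      R(c) = R_hi - (R_hi - R_lo) / (1 + (c / A1)^A2),

  whose midpoint A1 acts as an apparent dissociation constant.
* SPR association phases are fitted with a one-phase exponential
  association, R(t) = plateau * (1 - exp(-k_obs t)); regression of k_obs
  against analyte concentration gives k_on (slope) and k_off (intercept)
  under a pseudo-first-order 1:1 scheme.  The fit quality is reported
  honestly — for complex binding events the one-phase model is expected to
  describe the data poorly.
* The first-order Bragg peak of a lamellar proteolipid multilayer gives
  the mean repeat distance d = 2 pi / s, and the membrane-stack geometry
  (two bilayers sandwiching a protein phase) is simple arithmetic on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal, stats


class NonIdentifiableError(ValueError):
    """Raised when the data cannot constrain the dose-response model."""


class InsufficientDataError(ValueError):
    pass


def dose_response(conc, R_hi: float, R_lo: float, A1: float, A2: float):
    """Four-parameter logistic response at concentration ``conc`` (nM)."""
    if A1 <= 0:
        raise ValueError(f"A1 must be > 0, got {A1}")
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    with np.errstate(divide="ignore"):
        ratio = np.where(conc > 0, (conc / A1) ** A2, 0.0)
    out = R_hi - (R_hi - R_lo) / (1.0 + ratio)
    return out if out.ndim else float(out)


@dataclass
class BindingIsotherm:
    """A titration with its fitted dose-response parameters."""

    concentrations: np.ndarray
    responses: np.ndarray
    R_hi: float
    R_lo: float
    A1: float
    A2: float
    r_squared: float
    stderr: dict = field(default_factory=dict)

    @property
    def apparent_kd(self) -> float:
        """The saturation midpoint A1, read as an apparent K_d (nM)."""
        return self.A1

    def predict(self, conc):
        return dose_response(conc, self.R_hi, self.R_lo, self.A1, self.A2)


def fit_dose_response(concs, responses, weights=None) -> BindingIsotherm:
    """Least-squares fit of the four-parameter dose-response model.

    Unweighted by default; pass per-point standard deviations as
    ``weights`` for a sigma-weighted fit.  Requires at least five distinct
    concentrations and a non-constant response.
    """
    concs = np.asarray(concs, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if np.unique(concs).size < 5:
        raise InsufficientDataError(
            "need at least 5 distinct concentrations"
        )
    if np.ptp(responses) == 0:
        raise NonIdentifiableError("constant response: model not identifiable")
    if np.any(concs <= 0):
        raise ValueError("concentrations must be > 0")

    r_lo0 = float(np.min(responses))
    r_hi0 = float(np.max(responses))
    mid = 0.5 * (r_lo0 + r_hi0)
    a1_0 = float(concs[np.argmin(np.abs(responses - mid))])
    p0 = [r_hi0, r_lo0, a1_0, 1.0]

    def model(c, r_hi, r_lo, a1, a2):
        return dose_response(c, r_hi, r_lo, a1, a2)

    popt, pcov = optimize.curve_fit(
        model,
        concs,
        responses,
        p0=p0,
        sigma=weights,
        absolute_sigma=weights is not None,
        bounds=([-np.inf, -np.inf, 1e-12, 1e-6], np.inf),
        maxfev=20000,
        xtol=1e-14,
        ftol=1e-14,
    )
    pred = model(concs, *popt)
    ss_res = float(np.sum((responses - pred) ** 2))
    ss_tot = float(np.sum((responses - responses.mean()) ** 2))
    perr = np.sqrt(np.diag(pcov))
    return BindingIsotherm(
        concentrations=concs,
        responses=responses,
        R_hi=float(popt[0]),
        R_lo=float(popt[1]),
        A1=float(popt[2]),
        A2=float(popt[3]),
        r_squared=1.0 - ss_res / ss_tot,
        stderr=dict(zip(("R_hi", "R_lo", "A1", "A2"), perr)),
    )


@dataclass
class Sensorgram:
    """A single-concentration association trace (time in s, response in RU)."""

    time: np.ndarray
    response: np.ndarray
    concentration: float
    k_obs: float | None = None
    plateau: float | None = None
    r_squared: float | None = None
    poor_fit: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")


def fit_association(
    trace: Sensorgram,
    window: float = 180.0,
    min_saturation: float = 0.2,
) -> Sensorgram:
    """Fit a one-phase exponential association over ``[0, window]`` s.

    The fit is flagged ``poor_fit`` (never raised) when the exponential
    curvature is not resolved within the window (k_obs * window below
    ``min_saturation``, as happens for a linear ramp) or the residual
    variance is large.  Returns the trace with fitted fields set.
    """
    mask = (trace.time >= 0) & (trace.time <= window)
    t = trace.time[mask]
    y = trace.response[mask]
    if t.size < 5:
        raise InsufficientDataError("fewer than 5 points inside the window")

    plateau0 = float(np.max(y)) if np.max(y) > 0 else 1.0
    # crude k from the e-folding point
    above = np.nonzero(y >= 0.632 * plateau0)[0]
    k0 = 1.0 / t[above[0]] if above.size and t[above[0]] > 0 else 1.0 / t[-1]

    def model(tt, plateau, k):
        return plateau * (1.0 - np.exp(-k * tt))

    try:
        popt, _ = optimize.curve_fit(
            model,
            t,
            y,
            p0=[plateau0, k0],
            bounds=([0.0, 1e-12], np.inf),
            maxfev=20000,
            xtol=1e-14,
            ftol=1e-14,
        )
        plateau, k_obs = float(popt[0]), float(popt[1])
        pred = model(t, *popt)
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        poor = (k_obs * window < min_saturation) or r2 < 0.9
    except RuntimeError:
        plateau, k_obs, r2, poor = np.nan, np.nan, np.nan, True

    trace.k_obs = k_obs
    trace.plateau = plateau
    trace.r_squared = r2
    trace.poor_fit = bool(poor)
    return trace


def kinetic_regression(
    concentrations,
    k_obs_values,
    fitting_set: str = "all",
    threshold: float = 500.0,
) -> tuple[float, float]:
    """Linear regression of k_obs on concentration: (k_on, k_off).

    ``fitting_set='all'`` uses every point; ``'geq500'`` (the second
    fitting set) omits concentrations below ``threshold`` nM, where surface
    saturation effects bias k_obs under pseudo-first-order assumptions.
    Units follow the inputs: with nM and s⁻¹, k_on is nM⁻¹ s⁻¹.
    """
    conc = np.asarray(concentrations, dtype=float)
    kobs = np.asarray(k_obs_values, dtype=float)
    if fitting_set == "geq500":
        keep = conc >= threshold
        conc, kobs = conc[keep], kobs[keep]
    elif fitting_set != "all":
        raise ValueError("fitting_set must be 'all' or 'geq500'")
    ok = np.isfinite(kobs)
    conc, kobs = conc[ok], kobs[ok]
    if conc.size < 3:
        raise InsufficientDataError(
            "need at least 3 usable (concentration, k_obs) points"
        )
    fit = stats.linregress(conc, kobs)
    return float(fit.slope), float(fit.intercept)


# -- lamellar diffraction ----------------------------------------------------


@dataclass(frozen=True)
class LamellarPeak:
    """A first-order lamellar diffraction peak."""

    s_position: float  # Å⁻¹
    width: float  # FWHM, Å⁻¹

    def __post_init__(self) -> None:
        if self.s_position <= 0:
            raise ValueError("s_position must be > 0")

    @property
    def d_spacing(self) -> float:
        return bragg_spacing(self.s_position)


def bragg_spacing(s_position: float) -> float:
    """Mean lamellar repeat distance d = 2 pi / s, Å."""
    if s_position <= 0:
        raise ValueError(f"s must be > 0, got {s_position}")
    return 2.0 * np.pi / s_position


def _power_law_bg(s, amp, p, const):
    return amp * s ** (-p) + const


def detect_peak(
    s,
    intensity,
    snr_threshold: float = 3.0,
    mask_halfwidth: float = 0.15,
) -> LamellarPeak | None:
    """Locate the first-order Bragg peak on a power-law background.

    A power-law + constant background is fitted outside a window around the
    smoothed-curve apex; the apex of the background-subtracted curve is
    refined by quadratic interpolation and its FWHM measured by half-height
    crossings.  Returns ``None`` when no excursion exceeds
    ``snr_threshold`` times the background residual noise (the
    protein-free-control verdict).  With several diffraction orders the
    lowest-s peak is returned as the primary.
    """
    s = np.asarray(s, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if s.size < 50:
        raise InsufficientDataError("need at least 50 points")

    win = max(5, 2 * (s.size // 40) + 1)
    smooth = signal.savgol_filter(intensity, win, 2)

    def bg_fit(mask):
        popt, _ = optimize.curve_fit(
            _power_law_bg,
            s[mask],
            intensity[mask],
            p0=[intensity[0] * s[0] ** 2, 2.0, float(np.min(intensity))],
            maxfev=20000,
        )
        return popt

    # first pass: fit background everywhere, locate candidate apex
    popt = bg_fit(np.ones_like(s, dtype=bool))
    excess = smooth - _power_law_bg(s, *popt)
    apex = int(np.argmax(excess))
    s0 = s[apex]

    # second pass: refit background with the candidate peak masked out
    mask = np.abs(s - s0) > mask_halfwidth * s0
    if mask.sum() >= 10:
        popt = bg_fit(mask)
    bg = _power_law_bg(s, *popt)
    sub = intensity - bg
    sub_smooth = smooth - bg
    noise = float(np.std(sub[mask])) if mask.sum() >= 10 else float(np.std(sub))

    # find prominent maxima of the subtracted, smoothed curve; require both
    # the noise threshold and a fraction of the tallest excursion, so that
    # structured background-fit residuals at low s are not mistaken for a
    # diffraction order; the lowest-s qualifying maximum is the first order
    height = max(snr_threshold * noise, 0.25 * float(np.max(sub_smooth)))
    peaks, _ = signal.find_peaks(sub_smooth, height=height)
    peaks = peaks[(peaks > 0) & (peaks < s.size - 1)]
    if peaks.size == 0 or float(np.max(sub_smooth)) < snr_threshold * noise:
        return None
    apex = int(peaks[0])

    # quadratic interpolation around the apex of the raw subtracted curve
    ya, yb, yc = sub_smooth[apex - 1], sub_smooth[apex], sub_smooth[apex + 1]
    denom = ya - 2 * yb + yc
    shift = 0.5 * (ya - yc) / denom if denom != 0 else 0.0
    shift = float(np.clip(shift, -1.0, 1.0))
    ds = 0.5 * (s[apex + 1] - s[apex - 1])
    s_refined = float(s[apex] + shift * ds)

    # FWHM from half-height crossings of the smoothed subtracted curve
    half = 0.5 * sub_smooth[apex]
    left = apex
    while left > 0 and sub_smooth[left] > half:
        left -= 1
    right = apex
    while right < s.size - 1 and sub_smooth[right] > half:
        right += 1
    width = float(s[right] - s[left])

    return LamellarPeak(s_position=s_refined, width=width)


@dataclass(frozen=True)
class StackGeometry:
    """Two-bilayer membrane stack with a protein phase between (nm)."""

    bilayer_thickness: float
    protein_gap: float

    def __post_init__(self) -> None:
        if self.bilayer_thickness < 0 or self.protein_gap < 0:
            raise ValueError("thicknesses must be >= 0")

    @property
    def total_thickness(self) -> float:
        return stack_total(self)


def stack_total(geometry: StackGeometry) -> float:
    """Total stack thickness: two bilayers plus the protein gap, nm."""
    return 2.0 * geometry.bilayer_thickness + geometry.protein_gap
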