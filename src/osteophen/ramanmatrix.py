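"""Bone-matrix composition metrics from Raman spectra.

Polynomial baseline subtraction (optionally preceded by PMMA embedding-medium
reference subtraction), band-area integration over configurable windows, the
standard bone composition ratios — mineral:matrix as v2 phosphate : amide III
and v1 phosphate : proline, carbonate:phosphate as v1 carbonate : v1
phosphate — and crystallinity as the inverse full-width at half-maximum of
the v1 phosphate band.

Band windows are configurable; the defaults follow standard bone-Raman
assignments (cm^-1): v1 phosphate 930-980, v2 phosphate 410-460, amide III
1215-1300, proline/hydroxyproline 840-898, v1 carbonate 1050-1100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import BoundsError, FitError, ValidationError

__all__ = [
    "BandWindow",
    "DEFAULT_WINDOWS",
    "RamanResult",
    "as_spectrum",
    "read_spectrum",
    "subtract_baseline",
    "band_area",
    "fit_v1_fwhm",
    "compute_ratios",
    "aggregate_spots",
]

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class BandWindow:
    name: str
    lo: float  # cm^-1
    hi: float  # cm^-1

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValidationError(f"{self.name}: window lo must be < hi")


DEFAULT_WINDOWS: dict[str, BandWindow] = {
    "v1_phosphate": BandWindow("v1_phosphate", 930.0, 980.0),
    "v2_phosphate": BandWindow("v2_phosphate", 410.0, 460.0),
    "amideIII": BandWindow("amideIII", 1215.0, 1300.0),
    "proline": BandWindow("proline", 840.0, 898.0),
    "v1_carbonate": BandWindow("v1_carbonate", 1050.0, 1100.0),
}


@dataclass(frozen=True)
class RamanResult:
    mineral_matrix_v2_amideIII: float  # v2 phosphate : amide III area ratio
    mineral_matrix_v1_proline: float  # v1 phosphate : proline area ratio
    carbonate_phosphate: float  # v1 carbonate : v1 phosphate area ratio
    crystallinity: float  # 1 / FWHM(v1 phosphate), 1/cm
    fwhm_v1: float  # cm^-1
    areas: dict[str, float] = field(default_factory=dict)
    flags: tuple[str, ...] = ()


def as_spectrum(wavenumber, intensity, **meta) -> pd.DataFrame:
    w = np.asarray(wavenumber, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if w.shape != y.shape or w.ndim != 1:
        raise ValidationError("wavenumber and intensity must be 1-D arrays of equal length")
    if not np.all(np.diff(w) > 0):
        raise ValidationError("wavenumber must be strictly increasing")
    spec = pd.DataFrame({"wavenumber_cm1": w, "intensity": y})
    spec.attrs.update(meta)
    return spec


def read_spectrum(path, **meta) -> pd.DataFrame:
    """Read a two-column CSV (wavenumber_cm1, intensity); '#' lines skipped."""
    df = pd.read_csv(path, comment="#")
    cols = list(df.columns[:2])
    return as_spectrum(df[cols[0]].to_numpy(), df[cols[1]].to_numpy(), **meta)


def _band_mask(w: np.ndarray, windows) -> np.ndarray:
    m = np.zeros(w.size, dtype=bool)
    for win in windows.values():
        m |= (w >= win.lo) & (w <= win.hi)
    return m


def subtract_baseline(
    spectrum: pd.DataFrame,
    order: int = 11,
    reference: pd.DataFrame | None = None,
    windows: dict[str, BandWindow] | None = None,
    max_iter: int = 20,
) -> pd.DataFrame:
    """Iterative polynomial baseline subtraction.

    If a background ``reference`` spectrum (e.g. the PMMA embedding medium)
    is given, it is first least-squares scaled over the non-band region and
    subtracted.  The baseline polynomial of the given order (default 11) is
    then fit iteratively: points sitting above the current fit are excluded
    and the fit repeated, up to ``max_iter`` passes, so peaks do not drag the
    baseline up.  Residual negative intensities are clipped to zero (the
    clipped fraction is recorded in ``attrs['clipped_frac']``).
    """
    if order < 0:
        raise ValidationError("order must be >= 0")
    w = spectrum["wavenumber_cm1"].to_numpy()
    y = spectrum["intensity"].to_numpy(dtype=float).copy()
    if order >= w.size:
        raise FitError(f"polynomial order {order} >= number of samples {w.size}")
    windows = DEFAULT_WINDOWS if windows is None else windows

    if reference is not None:
        ref = np.interp(w, reference["wavenumber_cm1"], reference["intensity"])
        m = ~_band_mask(w, windows)
        denom = float(ref[m] @ ref[m])
        if denom > 0:
            y = y - (float(y[m] @ ref[m]) / denom) * ref

    keep = np.ones(w.size, dtype=bool)
    base = np.zeros_like(y)
    for _ in range(max_iter):
        poly = np.polynomial.Polynomial.fit(w[keep], y[keep], order)
        base = poly(w)
        # exclude peak points but tolerate noise; the noise scale is estimated
        # from the negative residuals only (peaks never contribute there), so
        # the baseline tracks the noise mean instead of its lower envelope
        resid = y - base
        neg = resid[resid < 0]
        sigma = float(np.sqrt(np.mean(neg**2))) if neg.size else 0.0
        new_keep = resid <= 2.0 * sigma + 1e-12 * max(1.0, np.abs(y).max())
        # always keep enough points to constrain the polynomial
        if new_keep.sum() <= order + 1:
            break
        if np.array_equal(new_keep, keep):
            break
        keep = new_keep
    corrected = y - base
    clipped = float(np.mean(corrected < 0))
    out = as_spectrum(w, np.clip(corrected, 0.0, None), **spectrum.attrs)
    out.attrs["clipped_frac"] = clipped
    out.attrs["baseline_order"] = order
    return out


def band_area(spectrum: pd.DataFrame, window: BandWindow) -> float:
    """Trapezoidal band area over [lo, hi]; negative intensities clip to 0."""
    w = spectrum["wavenumber_cm1"].to_numpy()
    y = spectrum["intensity"].to_numpy(dtype=float)
    if window.lo < w[0] or window.hi > w[-1]:
        raise BoundsError(
            f"{window.name}: window [{window.lo}, {window.hi}] outside spectral "
            f"range [{w[0]}, {w[-1]}]"
        )
    m = (w >= window.lo) & (w <= window.hi)
    return float(np.trapezoid(np.clip(y[m], 0.0, None), w[m]))


def _gaussian(x, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def fit_v1_fwhm(
    spectrum: pd.DataFrame,
    window: BandWindow | None = None,
    method: str = "fit",
) -> float:
    """FWHM (cm^-1) of the v1 phosphate band.

    ``method="fit"`` (default) fits a single Gaussian by least squares,
    which is robust to noise; ``method="direct"`` interpolates the half-max
    crossings for cross-checking.
    """
    window = window or DEFAULT_WINDOWS["v1_phosphate"]
    w = spectrum["wavenumber_cm1"].to_numpy()
    y = spectrum["intensity"].to_numpy(dtype=float)
    m = (w >= window.lo) & (w <= window.hi)
    ww, yy = w[m], y[m]
    if ww.size < 5 or yy.max() <= 0:
        raise FitError("v1 phosphate window empty or non-positive")
    if method == "direct":
        half = yy.max() / 2.0
        above = yy >= half
        idx = np.flatnonzero(above)
        if idx.size < 2:
            raise FitError("v1 band narrower than sampling grid")
        i0, i1 = idx[0], idx[-1]
        lo = ww[i0] if i0 == 0 else np.interp(half, [yy[i0 - 1], yy[i0]], [ww[i0 - 1], ww[i0]])
        hi = ww[i1] if i1 == ww.size - 1 else np.interp(
            half, [yy[i1 + 1], yy[i1]], [ww[i1 + 1], ww[i1]]
        )
        return float(hi - lo)
    amp0 = float(yy.max())
    mu0 = float(ww[np.argmax(yy)])
    sigma0 = max(float(np.trapezoid(yy, ww)) / (amp0 * np.sqrt(2 * np.pi)), 1.0)
    try:
        popt, _ = curve_fit(
            _gaussian, ww, yy, p0=(amp0, mu0, sigma0),
            bounds=((0, window.lo, 0.1), (np.inf, window.hi, window.hi - window.lo)),
            maxfev=10_000,
        )
    except RuntimeError as exc:
        raise FitError(f"v1 Gaussian fit did not converge: {exc}") from exc
    return float(_FWHM_PER_SIGMA * popt[2])


def compute_ratios(
    spectrum: pd.DataFrame,
    windows: dict[str, BandWindow] | None = None,
    crystallinity_method: str = "fit",
) -> RamanResult:
    """Composition metrics from a baseline-subtracted spectrum.

    Area ratios v2 phosphate : amide III, v1 phosphate : proline and v1
    carbonate : v1 phosphate, plus crystallinity = 1/FWHM of the v1 phosphate
    band.  A zero denominator area flags the affected ratio unavailable
    (NaN); a failed v1 fit flags crystallinity unavailable.
    """
    windows = DEFAULT_WINDOWS if windows is None else windows
    areas = {name: band_area(spectrum, win) for name, win in windows.items()}
    flags: list[str] = []

    tiny = 1e-9 * max(max(areas.values()), 1e-300)

    def _ratio(num: str, den: str, label: str) -> float:
        if areas[den] <= tiny:
            flags.append(f"{label}_unavailable")
            return float("nan")
        return areas[num] / areas[den]

    mm_v2 = _ratio("v2_phosphate", "amideIII", "v2_amideIII")
    mm_v1 = _ratio("v1_phosphate", "proline", "v1_proline")
    cp = _ratio("v1_carbonate", "v1_phosphate", "carb_phos")
    try:
        fwhm = fit_v1_fwhm(spectrum, windows.get("v1_phosphate"), crystallinity_method)
        crystallinity = 1.0 / fwhm if fwhm > 0 else float("nan")
        if not fwhm > 0:
            flags.append("crystallinity_unavailable")
    except FitError:
        fwhm, crystallinity = float("nan"), float("nan")
        flags.append("crystallinity_unavailable")
    return RamanResult(mm_v2, mm_v1, cp, crystallinity, fwhm, areas, tuple(flags))


def aggregate_spots(results: list[RamanResult], stat: str = "median") -> RamanResult:
    """Aggregate spot-level metrics to one per-sample result.

    Raman maps are acquired as a grid of spots per bone; the per-animal value
    of each metric is the median (configurable: ``"median"`` or ``"mean"``)
    over spots, ignoring unavailable spot values.
    """
    if not results:
        raise ValidationError("no spot results to aggregate")
    if stat not in ("median", "mean"):
        raise ValidationError(f"unknown aggregation statistic {stat!r}")
    agg = np.nanmedian if stat == "median" else np.nanmean
    fields = (
        "mineral_matrix_v2_amideIII",
        "mineral_matrix_v1_proline",
        "carbonate_phosphate",
        "crystallinity",
        "fwhm_v1",
    )
    import warnings

    vals = {}
    for f in fields:
        col = np.asarray([getattr(r, f) for r in results], dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            vals[f] = float(agg(col))
    flags = tuple(sorted({fl for r in results for fl in r.flags}))
    return RamanResult(
        vals["mineral_matrix_v2_amideIII"],
        vals["mineral_matrix_v1_proline"],
        vals["carbonate_phosphate"],
        vals["crystallinity"],
        vals["fwhm_v1"],
        {},
        flags,
    )
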