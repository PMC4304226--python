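"""Multi-Gaussian decomposition of photolysis difference spectra.

Band centers, full widths at half maximum and signed integrated areas are
refined by nonlinear least squares (lmfit/Levenberg-Marquardt).  Heme-bound
(A) bands and photoproduct bands are fitted in separate spectral windows;
within one class all bands share the amplitude sign, and occupancies are
reported as fractional areas summing to 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .spectra import (
    GAUSS_AREA_FACTOR,
    BandRegion,
    DifferenceSpectrum,
    gaussian_profile,
)

__all__ = [
    "GaussianBand",
    "BandSet",
    "FitResult",
    "DEFAULT_FWHM",
    "pick_initial_bands",
    "fit_bands",
    "fit_n_bands",
    "fractional_areas",
    "render_bands",
]

#: Decision-default initial widths (cm^-1) by (ligand, band class).
DEFAULT_FWHM = {
    ("CO", "bound"): 10.0,
    ("CO", "photoproduct"): 6.0,
    ("NO", "bound"): 14.0,
    ("NO", "photoproduct"): 8.0,
}

FWHM_MIN, FWHM_MAX = 2.0, 200.0


@dataclass
class GaussianBand:
    center: float
    fwhm: float
    area: float  # signed, AU * cm^-1

    def __post_init__(self):
        if not np.isfinite(self.center):
            raise ValueError("band center must be finite")
        if self.fwhm <= 0:
            raise ValueError("band fwhm must be positive")

    @property
    def amplitude(self) -> float:
        return self.area / (self.fwhm * GAUSS_AREA_FACTOR)


@dataclass
class BandSet:
    """A set of Gaussian components of one spectral class."""

    bands: list
    class_tag: str = "bound"  # "bound" (heme-bound A) or "photoproduct"

    def __len__(self):
        return len(self.bands)

    @property
    def fractional_areas(self):
        return fractional_areas(self)

    def sorted_by_center(self) -> "BandSet":
        return BandSet(sorted(self.bands, key=lambda b: b.center), self.class_tag)

    def sorted_by_fraction(self) -> "BandSet":
        order = np.argsort([-abs(b.area) for b in self.bands])
        return BandSet([self.bands[i] for i in order], self.class_tag)


@dataclass
class FitResult:
    band_set: BandSet
    residual_rms: float
    converged: bool
    stderr: list = field(default_factory=list)  # (center, fwhm, area) 1-sigma per band

    @property
    def bands(self):
        return self.band_set.bands


def fractional_areas(bands) -> list:
    """Order-preserving fractional areas, 100 * |a_i| / sum |a|.

    Bands of one class must share the amplitude sign.
    """
    blist = bands.bands if isinstance(bands, BandSet) else list(bands)
    if not blist:
        raise ValueError("fractional_areas requires at least one band")
    signs = {np.sign(b.area) for b in blist if b.area != 0}
    if len(signs) > 1:
        raise ValueError("mixed amplitude signs within one band class")
    total = sum(abs(b.area) for b in blist)
    if total == 0:
        raise ValueError("all band areas are zero")
    return [100.0 * abs(b.area) / total for b in blist]


def render_bands(grid, bands) -> np.ndarray:
    """Sum of Gaussian profiles on a grid."""
    blist = bands.bands if isinstance(bands, BandSet) else list(bands)
    y = np.zeros(len(grid))
    for b in blist:
        y += gaussian_profile(grid, b.center, b.fwhm, b.area)
    return y


def _class_sign(class_tag: str) -> float:
    # A bands are depleted (negative) in difference spectra; photoproduct
    # bands gain (positive).
    return -1.0 if class_tag == "bound" else 1.0


def pick_initial_bands(
    spec: DifferenceSpectrum,
    class_tag: str = "bound",
    max_bands: int = 5,
    window: BandRegion | None = None,
    init_fwhm: float = 10.0,
) -> BandSet:
    """Initial band guesses from local extrema of the smoothed spectrum.

    Extrema with the sign expected for ``class_tag`` are returned strongest
    first, up to ``max_bands``.  An all-flat spectrum yields an empty set.
    """
    sgn = _class_sign(class_tag)
    m = window.mask(spec.grid) if window is not None else np.ones(len(spec.grid), bool)
    x = spec.grid.values[m]
    y = sgn * spec.delta_absorbance[m]
    if x.size < 7:
        raise ValueError("window too narrow for peak picking")
    smooth = savgol_filter(y, window_length=7, polyorder=3)
    scale = np.max(np.abs(smooth))
    if scale == 0:
        return BandSet([], class_tag)
    idx, props = find_peaks(smooth, height=0.05 * scale, prominence=0.02 * scale)
    if idx.size == 0:
        return BandSet([], class_tag)
    order = np.argsort(-props["peak_heights"])[:max_bands]
    bands = []
    for i in idx[order]:
        amp = sgn * smooth[i]
        bands.append(GaussianBand(x[i], init_fwhm, amp * init_fwhm * GAUSS_AREA_FACTOR))
    return BandSet(bands, class_tag)


def _dedupe(bands, tol=1e-9):
    out = []
    for b in bands:
        if any(abs(b.center - o.center) < tol and abs(b.fwhm - o.fwhm) < tol for o in out):
            continue
        out.append(b)
    return out


def _merge_close(bands, tol=1.0):
    """Merge components whose centers converged to within ``tol`` cm^-1."""
    merged = []
    changed = False
    for b in sorted(bands, key=lambda b: b.center):
        if merged and abs(b.center - merged[-1].center) < tol:
            prev = merged[-1]
            tot = prev.area + b.area
            if tot == 0:
                center = 0.5 * (prev.center + b.center)
            else:
                center = (prev.center * prev.area + b.center * b.area) / tot
            merged[-1] = GaussianBand(center, max(prev.fwhm, b.fwhm), tot)
            changed = True
        else:
            merged.append(b)
    return merged, changed


def _do_fit(x, y, bands, window, max_nfev, vary_fwhm=True):
    params = lmfit.Parameters()
    for i, b in enumerate(bands):
        params.add(f"c{i}", value=b.center, min=window.lo, max=window.hi)
        params.add(f"w{i}", value=np.clip(b.fwhm, FWHM_MIN, FWHM_MAX),
                   min=FWHM_MIN, max=FWHM_MAX, vary=vary_fwhm)
        params.add(f"a{i}", value=b.area)

    n = len(bands)

    def residual(p):
        model = np.zeros_like(x)
        for i in range(n):
            amp = p[f"a{i}"] / (p[f"w{i}"] * GAUSS_AREA_FACTOR)
            model += amp * np.exp(
                -4.0 * np.log(2.0) * (x - p[f"c{i}"]) ** 2 / p[f"w{i}"] ** 2
            )
        return model - y

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = lmfit.minimize(residual, params, method="leastsq", max_nfev=max_nfev)
    out = [
        GaussianBand(
            float(res.params[f"c{i}"].value),
            float(res.params[f"w{i}"].value),
            float(res.params[f"a{i}"].value),
        )
        for i in range(n)
    ]
    errs = [
        tuple(res.params[f"{k}{i}"].stderr for k in ("c", "w", "a")) for i in range(n)
    ]
    rms = float(np.sqrt(np.mean(residual(res.params) ** 2)))
    return out, errs, rms, bool(res.success)


def fit_bands(
    spec: DifferenceSpectrum,
    init: BandSet,
    window: BandRegion,
    max_nfev: int = 2000,
    vary_fwhm: bool = True,
) -> FitResult:
    """Refine centers, widths and signed areas by least squares.

    Centers are constrained to the fit window and widths to
    [2, 200] cm^-1.  Components that converge to within 1 cm^-1 of each
    other are merged (areas added) and the reduced model refitted once.
    ``vary_fwhm=False`` holds widths at their initial values — the usual
    regularization when components overlap by more than about half a width
    and free-width decomposition becomes statistically unidentifiable.
    """
    if len(init) == 0:
        raise ValueError("fit_bands requires a non-empty initial band set")
    m = window.mask(spec.grid)
    if m.sum() < 4:
        raise ValueError("fit window too narrow on this grid")
    x = spec.grid.values[m]
    y = spec.delta_absorbance[m]

    bands = _dedupe(init.bands)
    fitted, errs, rms, ok = _do_fit(x, y, bands, window, max_nfev, vary_fwhm)
    merged, changed = _merge_close(fitted, tol=1.0)
    if changed and len(merged) >= 1:
        fitted, errs, rms, ok = _do_fit(x, y, merged, window, max_nfev, vary_fwhm)
    result = FitResult(
        BandSet(fitted, init.class_tag), rms, ok, errs if ok else []
    )
    return result


def fit_n_bands(
    spec: DifferenceSpectrum,
    n_bands: int,
    window: BandRegion,
    class_tag: str = "bound",
    init_fwhm: float = 10.0,
    vary_fwhm: bool = True,
) -> FitResult:
    """Fit exactly ``n_bands`` Gaussians, growing the model greedily.

    Starts from peak-picked extrema; while fewer components than requested
    are present, adds one at the largest residual extremum of the expected
    sign and refits.  This recovers shoulders that peak picking misses.
    """
    init = pick_initial_bands(spec, class_tag, n_bands, window, init_fwhm)
    sgn = _class_sign(class_tag)
    if len(init) == 0:
        # fall back to the strongest point of the window
        m = window.mask(spec.grid)
        x = spec.grid.values[m]
        y = sgn * spec.delta_absorbance[m]
        i = int(np.argmax(y))
        init = BandSet(
            [GaussianBand(x[i], init_fwhm, sgn * y[i] * init_fwhm * GAUSS_AREA_FACTOR)],
            class_tag,
        )
    result = fit_bands(spec, init, window, vary_fwhm=vary_fwhm)
    while len(result.bands) < n_bands:
        m = window.mask(spec.grid)
        x = spec.grid.values[m]
        resid = sgn * (spec.delta_absorbance[m] - render_bands(spec.grid, result.band_set)[m])
        i = int(np.argmax(resid))
        if resid[i] <= 0:
            break
        extra = GaussianBand(
            x[i], init_fwhm, sgn * resid[i] * init_fwhm * GAUSS_AREA_FACTOR
        )
        if not vary_fwhm:
            extra = GaussianBand(extra.center, init_fwhm, extra.area)
        new_init = BandSet(result.bands + [extra], class_tag)
        new_result = fit_bands(spec, new_init, window, vary_fwhm=vary_fwhm)
        if len(new_result.bands) <= len(result.bands):
            break  # merged straight back; no further structure to recover
        result = new_result
    return result
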