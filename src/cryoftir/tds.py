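"""Temperature derivative spectroscopy (TDS) maps and barrier inversion.

A TDS experiment records one spectrum per 1-K step while a photolyzed sample
is warmed linearly in the dark.  Differences between successive spectra are
proportional to the population rebinding in that temperature interval; they
are assembled into a temperature-by-wavenumber map whose contours are drawn
on logarithmically spaced levels.  For first-order kinetics under a linear
ramp, the temperature of maximal rebinding rate relates the ramp rate and
Arrhenius parameters to the activation enthalpy (Kissinger-type condition)

    H / (R * T_p**2) = (prefactor / ramp_rate) * exp(-H / (R * T_p)),

which is monotone in H and inverted numerically here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.signal import find_peaks

from .spectra import BandRegion, SpectrumSeries, WavenumberGrid, integrate_band

__all__ = [
    "R_GAS",
    "TDSMap",
    "PopulationTrace",
    "RebindingPeak",
    "ContourSpec",
    "build_tds_map",
    "population_trace",
    "extract_peaks",
    "contour_levels",
    "invert_peak_enthalpy",
    "peak_temperature",
]

R_GAS = 8.314  # J mol^-1 K^-1


@dataclass
class TDSMap:
    """Successive-spectrum differences: row t = A(T_{t+1}) - A(T_t).

    ``temperatures`` holds the midpoints of each pair; ``step_starts`` the
    lower temperature of each pair (used for row labels on export).
    """

    temperatures: np.ndarray
    grid: WavenumberGrid
    delta: np.ndarray
    step_starts: np.ndarray = None

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, float)
        self.delta = np.asarray(self.delta, float)
        if self.delta.shape != (self.temperatures.size, len(self.grid)):
            raise ValueError("TDS map shape does not match temperatures x grid")
        if not np.all(np.isfinite(self.delta)):
            raise ValueError("TDS map entries must be finite")
        if self.step_starts is None:
            self.step_starts = self.temperatures.copy()
        else:
            self.step_starts = np.asarray(self.step_starts, float)


@dataclass
class PopulationTrace:
    """Integrated band absorbance (proportional to population) vs temperature."""

    temperatures: np.ndarray
    N: np.ndarray

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, float)
        self.N = np.asarray(self.N, float)
        if self.N.shape != self.temperatures.shape:
            raise ValueError("trace temperatures and N must have equal length")


@dataclass
class RebindingPeak:
    T_peak: float
    nu_peak: float
    sign: str  # "gain" | "loss"
    amplitude: float


@dataclass
class ContourSpec:
    n_levels: int
    levels: np.ndarray = field(default=None)

    def __post_init__(self):
        self.levels = np.asarray(self.levels, float)


def build_tds_map(series: SpectrumSeries) -> TDSMap:
    """Assemble the map of consecutive absorbance differences."""
    if len(series) < 2:
        raise ValueError("a TDS map needs at least two spectra")
    if series.mode != "absorbance":
        raise ValueError("TDS maps are built from absorbance series")
    steps = np.diff(series.temperatures)
    if np.any(steps > 1.5):
        warnings.warn(
            f"temperature steps up to {steps.max():.2f} K exceed the nominal "
            "1-K TDS increment; proceeding",
            stacklevel=2,
        )
    delta = np.diff(series.values, axis=0)
    mids = 0.5 * (series.temperatures[:-1] + series.temperatures[1:])
    return TDSMap(mids, series.grid, delta, step_starts=series.temperatures[:-1])


def population_trace(series: SpectrumSeries, region: BandRegion, sign: str = "abs") -> PopulationTrace:
    """Integrated band absorbance of every spectrum in the series."""
    N = np.array([integrate_band(s, region, sign) for s in series])
    return PopulationTrace(series.temperatures.copy(), N)


def _parabolic_refine(x, y, i):
    """3-point parabola through (x[i-1..i+1], y) -> refined extremum location."""
    if i == 0 or i == len(x) - 1:
        return float(x[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(x[i]), float(y[i])
    d = 0.5 * (y0 - y2) / denom
    d = float(np.clip(d, -1, 1))
    h = x[i + 1] - x[i]
    return float(x[i] + d * h), float(y1 - 0.25 * (y0 - y2) * d)


def extract_peaks(
    tds_map: TDSMap,
    min_amplitude: float = 0.0,
    regions=None,
) -> list:
    """Rebinding peaks from band-integrated step traces.

    For each region (default: the full grid as one region) the per-step map
    rows are integrated over wavenumber; local extrema of the |trace| above
    ``min_amplitude`` are returned with a parabolic refinement of the peak
    temperature.  Sign is "gain" for increasing absorbance.
    """
    if regions is None:
        regions = [BandRegion(tds_map.grid.values[0], tds_map.grid.values[-1])]
    x = tds_map.grid.values
    peaks = []
    for region in regions:
        m = region.mask(tds_map.grid)
        if m.sum() < 2:
            raise ValueError("peak region empty on grid")
        trace = np.trapezoid(tds_map.delta[:, m], x[m], axis=1)
        a = np.abs(trace)
        idx, _ = find_peaks(a)
        # endpoints can hold the maximum (e.g. rebinding maximal at the ramp start)
        for edge in (0, len(a) - 1):
            if a[edge] >= a.max() * 0.999 and edge not in idx:
                idx = np.append(idx, edge)
        for i in sorted(idx):
            if a[i] < min_amplitude or a[i] == 0:
                continue
            T_ref, amp = _parabolic_refine(tds_map.temperatures, a, i)
            row = tds_map.delta[i, m]
            nu = float(x[m][np.argmax(np.abs(row))])
            sign = "gain" if trace[i] > 0 else "loss"
            peaks.append(RebindingPeak(T_ref, nu, sign, float(amp)))
    return peaks


def contour_levels(tds_map: TDSMap, n_levels: int, ratio: float = 2.0) -> ContourSpec:
    """Logarithmically spaced, sign-symmetric contour levels.

    Positive levels form a geometric sequence from max|delta| / ratio**(n-1)
    up to max|delta|; negatives mirror them.
    """
    if n_levels < 2:
        raise ValueError("need at least two contour levels")
    top = float(np.max(np.abs(tds_map.delta)))
    if top == 0:
        raise ValueError("all-zero TDS map has no contours")
    pos = top / ratio ** np.arange(n_levels - 1, -1, -1, dtype=float)
    return ContourSpec(n_levels, np.concatenate([-pos[::-1], pos]))


def _kissinger_residual(H, T_p, ramp_rate, prefactor):
    # H in J/mol; monotone increasing in H
    return H / (R_GAS * T_p**2) - (prefactor / ramp_rate) * np.exp(-H / (R_GAS * T_p))


def invert_peak_enthalpy(T_peak: float, ramp_rate: float, prefactor: float = 10**8.5) -> float:
    """Enthalpy barrier (kJ/mol) from a TDS peak temperature.

    Solves the first-order linear-ramp peak condition for H; ``ramp_rate``
    in K/s, ``prefactor`` in 1/s.  Raises if no root lies in
    [0.1, 200] kJ/mol.
    """
    if T_peak <= 0 or ramp_rate <= 0 or prefactor <= 0:
        raise ValueError("T_peak, ramp_rate and prefactor must be positive")
    lo, hi = 100.0, 200_000.0  # J/mol
    f_lo = _kissinger_residual(lo, T_peak, ramp_rate, prefactor)
    f_hi = _kissinger_residual(hi, T_peak, ramp_rate, prefactor)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"no enthalpy root in [0.1, 200] kJ/mol for T_peak={T_peak} K"
        )
    H = brentq(_kissinger_residual, lo, hi, args=(T_peak, ramp_rate, prefactor), xtol=1e-6)
    return H / 1000.0


def peak_temperature(H_kJ: float, ramp_rate: float, prefactor: float = 10**8.5) -> float:
    """Forward Kissinger condition: peak temperature (K) for a barrier H."""
    if H_kJ <= 0:
        raise ValueError("H must be positive")
    H = H_kJ * 1000.0

    def g(T):
        return _kissinger_residual(H, T, ramp_rate, prefactor)

    lo, hi = 1.0, 1000.0
    if g(lo) * g(hi) > 0:
        raise ValueError("no peak temperature in [1, 1000] K")
    return float(brentq(g, lo, hi, xtol=1e-9))
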