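"""Core data model for cryogenic FTIR spectra and elementary operations.

Spectra live on a uniform, ascending wavenumber grid (cm^-1).  Transmission
spectra hold raw detector intensities; absorbance is the base-10 logarithm of
an intensity ratio.  Photolysis difference spectra follow the convention that
depletion of heme-bound ligand bands (A bands) appears with negative amplitude
and photoproduct bands with positive amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridMismatchError",
    "StructuralError",
    "WavenumberGrid",
    "Spectrum",
    "DifferenceSpectrum",
    "SpectrumSeries",
    "BandRegion",
    "transmission_to_absorbance",
    "absorbance_to_transmission",
    "difference_absorbance",
    "integrate_band",
    "gaussian_profile",
    "GAUSS_AREA_FACTOR",
]

#: area = amplitude * fwhm * GAUSS_AREA_FACTOR for a Gaussian band,
#: i.e. sqrt(pi / ln 16).
GAUSS_AREA_FACTOR = float(np.sqrt(np.pi / np.log(16.0)))


class StructuralError(ValueError):
    """Inputs are structurally incompatible (shapes, grids, ordering)."""


class GridMismatchError(StructuralError):
    """Two spectra do not share the same wavenumber grid."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform, strictly increasing wavenumber axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise StructuralError("grid needs at least two wavenumber points")
        steps = np.diff(values)
        if np.any(steps <= 0):
            raise StructuralError("wavenumbers must be strictly increasing")
        if np.max(np.abs(steps - steps[0])) > 1e-9 * abs(steps[0]):
            raise StructuralError("wavenumber spacing must be uniform")
        object.__setattr__(self, "values", values)

    @property
    def spacing(self) -> float:
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, WavenumberGrid)
            and len(self) == len(other)
            and bool(np.allclose(self.values, other.values, rtol=0, atol=1e-9))
        )

    @classmethod
    def default(cls, lo: float = 1700.0, hi: float = 2300.0, step: float = 2.0):
        """InSb detector window, 1700-2300 cm^-1 at 2 cm^-1."""
        n = int(round((hi - lo) / step)) + 1
        return cls(lo + step * np.arange(n))

    @classmethod
    def extended(cls, step: float = 2.0):
        """MCT detector window, 1100-2300 cm^-1."""
        return cls.default(1100.0, 2300.0, step)


@dataclass
class Spectrum:
    """One IR spectrum at one temperature.

    ``mode`` is ``"absorbance"`` (dimensionless AU) or ``"transmission"``
    (arbitrary positive counts).
    """

    grid: WavenumberGrid
    values: np.ndarray
    mode: str = "absorbance"
    temperature: float = 4.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.grid),):
            raise StructuralError("spectrum length does not match grid length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum values must be finite")
        if self.mode not in ("absorbance", "transmission"):
            raise ValueError(f"unknown spectrum mode {self.mode!r}")
        if self.mode == "transmission" and np.any(self.values <= 0):
            raise ValueError("transmission intensities must be positive")


@dataclass
class DifferenceSpectrum:
    """Photolysis difference spectrum: delta-absorbance vs wavenumber."""

    grid: WavenumberGrid
    delta_absorbance: np.ndarray
    temperature: float = 4.0

    def __post_init__(self):
        self.delta_absorbance = np.asarray(self.delta_absorbance, dtype=float)
        if self.delta_absorbance.shape != (len(self.grid),):
            raise StructuralError("difference spectrum length does not match grid")
        if not np.all(np.isfinite(self.delta_absorbance)):
            raise ValueError("difference spectrum values must be finite")

    def __neg__(self) -> "DifferenceSpectrum":
        return DifferenceSpectrum(self.grid, -self.delta_absorbance, self.temperature)


@dataclass
class SpectrumSeries:
    """Temperature-indexed collection of spectra on a common grid.

    ``values`` has shape (n_temperatures, n_wavenumbers); temperatures are
    strictly increasing (1-K steps for a TDS ramp).
    """

    grid: WavenumberGrid
    temperatures: np.ndarray
    values: np.ndarray
    mode: str = "absorbance"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.temperatures.size, len(self.grid)):
            raise StructuralError(
                "series values must have shape (n_temperatures, n_wavenumbers)"
            )
        if self.temperatures.size > 1 and np.any(np.diff(self.temperatures) <= 0):
            raise StructuralError("series temperatures must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series values must be finite")

    def __len__(self) -> int:
        return self.temperatures.size

    def __getitem__(self, i: int) -> Spectrum:
        return Spectrum(self.grid, self.values[i], self.mode, float(self.temperatures[i]))

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]


@dataclass(frozen=True)
class BandRegion:
    """Half-open spectral integration window [lo, hi] in cm^-1."""

    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"band region requires lo < hi, got [{self.lo}, {self.hi}]")

    def mask(self, grid: WavenumberGrid) -> np.ndarray:
        return (grid.values >= self.lo) & (grid.values <= self.hi)


def _check_same_grid(a, b):
    if a.grid != b.grid:
        raise GridMismatchError("spectra are not on the same wavenumber grid")


def transmission_to_absorbance(sample: Spectrum, reference: Spectrum) -> Spectrum:
    """Absorbance A(nu) = log10(I_reference / I_sample)."""
    _check_same_grid(sample, reference)
    if sample.mode != "transmission" or reference.mode != "transmission":
        raise ValueError("both spectra must be in transmission mode")
    return Spectrum(
        sample.grid,
        np.log10(reference.values / sample.values),
        "absorbance",
        sample.temperature,
    )


def absorbance_to_transmission(spec: Spectrum, reference: Spectrum) -> Spectrum:
    """Inverse of :func:`transmission_to_absorbance`: I = I_ref * 10**(-A)."""
    if spec.mode != "absorbance":
        raise ValueError("spectrum must be in absorbance mode")
    if reference.mode != "transmission":
        raise ValueError("reference must be in transmission mode")
    _check_same_grid(spec, reference)
    return Spectrum(
        spec.grid,
        reference.values * 10.0 ** (-spec.values),
        "transmission",
        spec.temperature,
    )


def difference_absorbance(dark: Spectrum, light: Spectrum) -> DifferenceSpectrum:
    """Photolysis difference dA(nu) = log10(I_dark / I_light).

    With ``light`` the post-photolysis spectrum, depleted A bands come out
    negative and photoproduct bands positive.
    """
    _check_same_grid(dark, light)
    if dark.mode != "transmission" or light.mode != "transmission":
        raise ValueError("difference_absorbance expects transmission spectra")
    if abs(dark.temperature - light.temperature) > 1e-9:
        raise ValueError(
            f"dark ({dark.temperature} K) and light ({light.temperature} K) "
            "temperatures differ"
        )
    return DifferenceSpectrum(
        dark.grid, np.log10(dark.values / light.values), dark.temperature
    )


def integrate_band(spec, region: BandRegion, sign: str = "abs") -> float:
    """Trapezoidal band integral over ``region`` in AU * cm^-1.

    ``sign`` selects the positive part (``"+"``), the negative part as a
    positive magnitude (``"-"``), the absolute value (``"abs"``), or the raw
    signed values (``"raw"``).
    """
    if isinstance(spec, DifferenceSpectrum):
        y = spec.delta_absorbance
    else:
        y = spec.values
    m = region.mask(spec.grid)
    if m.sum() < 2:
        raise ValueError(f"band region [{region.lo}, {region.hi}] is empty on this grid")
    x = spec.grid.values[m]
    y = y[m]
    if sign == "+":
        y = np.clip(y, 0.0, None)
    elif sign == "-":
        y = -np.clip(y, None, 0.0)
    elif sign == "abs":
        y = np.abs(y)
    elif sign != "raw":
        raise ValueError(f"unknown sign selector {sign!r}")
    return float(np.trapezoid(y, x))


def gaussian_profile(grid: WavenumberGrid, center: float, fwhm: float, area: float) -> np.ndarray:
    """Gaussian band with the given integrated (signed) area."""
    amp = area / (fwhm * GAUSS_AREA_FACTOR)
    x = grid.values
    return amp * np.exp(-4.0 * np.log(2.0) * (x - center) ** 2 / fwhm**2)
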