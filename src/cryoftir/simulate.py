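"""Forward simulator of ligand photolysis and rebinding at cryogenic temperatures.

The kinetic model is first-order with static (frozen) conformational
heterogeneity: each protein molecule carries a fixed rebinding enthalpy
barrier H drawn from a Gaussian distribution g(H) truncated at H >= 0, and
rebinds with an Arrhenius rate k(T) = prefactor * exp(-H / (R*T)).
Photolysis is a light-driven first-order process with rate proportional to
laser power.  Temperature/illumination protocols (10-s flash at 4 K,
slow-cool under light, constant illumination, dark TDS ramp) drive the
populations; spectra are rendered as sums of Gaussian bands scaled by state
populations, with the unbound-ligand bands carrying 1/ratio of the bound
integrated extinction (ratio ~20).

Multi-species NO photochemistry is modeled as a small network:
6C-ferric-NO <-> unbound NO photoproduct (broad band), plus a photo-driven
6C-ferrous -> 5C-ferric conversion (thiolate bond rupture), thermal
5C -> 6C-ferrous recovery, and a much slower photo-driven 5C -> 4C step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bandfit import GaussianBand
from .spectra import DifferenceSpectrum, SpectrumSeries, WavenumberGrid, gaussian_profile
from .tds import R_GAS

__all__ = [
    "BarrierDistribution",
    "Schedule",
    "Protocol",
    "Substate",
    "Exchange",
    "SubstateModel",
    "SpeciesNetwork",
    "ProtocolResult",
    "DEFAULT_PREFACTOR",
    "survival_fraction",
    "survival_curve",
    "monte_carlo_survival",
    "run_protocol",
    "render_series",
    "render_difference",
    "photolysis_difference",
    "render_class_difference",
]

DEFAULT_PREFACTOR = 10**8.5  # s^-1, typical geminate heme-ligand rebinding
DEFAULT_RAMP_RATE = 1.0 / 180.0  # K/s: 1 K per 180 s TDS ramp


@dataclass(frozen=True)
class BarrierDistribution:
    """Gaussian enthalpy-barrier distribution, kJ/mol, truncated at H >= 0."""

    mean_H: float
    sigma_H: float = 0.0

    def __post_init__(self):
        if self.mean_H <= 0:
            raise ValueError("mean_H must be positive")
        if self.sigma_H < 0:
            raise ValueError("sigma_H must be non-negative")

    def nodes(self, n: int = 200):
        """Quadrature nodes H (J/mol) and renormalized weights."""
        if self.sigma_H == 0:
            return np.array([self.mean_H * 1e3]), np.array([1.0])
        lo = max(0.0, self.mean_H - 6 * self.sigma_H)
        hi = self.mean_H + 6 * self.sigma_H
        H = np.linspace(lo, hi, n)
        w = np.exp(-0.5 * ((H - self.mean_H) / self.sigma_H) ** 2)
        return H * 1e3, w / w.sum()

    def sample(self, n: int, rng: np.random.Generator):
        """Draw n barriers (J/mol) by rejection below H = 0."""
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.normal(self.mean_H, self.sigma_H, n - filled)
            keep = draw[draw >= 0]
            out[filled : filled + keep.size] = keep
            filled += keep.size
        return out * 1e3


@dataclass
class Schedule:
    """Piecewise-linear temperature (and laser power) path vs time."""

    times: np.ndarray
    temperatures: np.ndarray
    power: float = 0.0  # mW, constant over the schedule

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.temperatures = np.asarray(self.temperatures, float)
        if self.times.shape != self.temperatures.shape or self.times.size < 2:
            raise ValueError("schedule needs matching times/temperatures, length >= 2")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("schedule times must be strictly increasing")

    @classmethod
    def constant(cls, T: float, duration: float, power: float = 0.0):
        return cls(np.array([0.0, duration]), np.array([T, T]), power)

    @classmethod
    def ramp(cls, T_start: float, T_end: float, rate: float, power: float = 0.0):
        """Linear ramp at |rate| K/s (sign inferred from endpoints)."""
        duration = abs(T_end - T_start) / abs(rate)
        return cls(np.array([0.0, duration]), np.array([T_start, T_end]), power)

    def fine(self, max_dt: float = 1.0):
        """Resampled (times, temperatures) with steps <= max_dt."""
        n = max(2, int(math.ceil((self.times[-1] - self.times[0]) / max_dt)) + 1)
        t = np.linspace(self.times[0], self.times[-1], n)
        return t, np.interp(t, self.times, self.temperatures)


@dataclass
class Protocol:
    """Illumination/temperature protocol of one experiment stage."""

    kind: str  # flash_4K | slow_cool | constant_illumination | tds_ramp
    duration: float = None  # s
    power: float = 0.0  # mW
    T_start: float = 4.0
    T_end: float = 4.0
    rate: float = 0.0  # K/s

    @classmethod
    def flash_4K(cls, duration: float = 10.0, power: float = 300.0, T: float = 4.0):
        return cls("flash_4K", duration, power, T, T, 0.0)

    @classmethod
    def slow_cool(cls, power: float = 300.0, T_start: float = 160.0, T_end: float = 4.0,
                  rate: float = 0.3 / 60.0):
        return cls("slow_cool", abs(T_end - T_start) / rate, power, T_start, T_end, rate)

    @classmethod
    def constant_illumination(cls, power: float, duration: float = 15000.0, T: float = 4.0):
        return cls("constant_illumination", duration, power, T, T, 0.0)

    @classmethod
    def tds_ramp(cls, T_start: float = 4.0, T_end: float = 160.0,
                 rate: float = DEFAULT_RAMP_RATE):
        return cls("tds_ramp", abs(T_end - T_start) / rate, 0.0, T_start, T_end, rate)

    def schedule(self) -> Schedule:
        if self.kind in ("flash_4K", "constant_illumination"):
            if not self.duration or self.duration < 0:
                if self.duration == 0:
                    return Schedule.constant(self.T_start, 1e-12, self.power)
                raise ValueError(f"protocol {self.kind} needs a duration")
            return Schedule.constant(self.T_start, self.duration, self.power)
        if self.kind in ("slow_cool", "tds_ramp"):
            return Schedule.ramp(self.T_start, self.T_end, self.rate, self.power)
        raise ValueError(f"unknown protocol kind {self.kind!r}")

    def to_dict(self):
        return {
            "kind": self.kind, "duration": self.duration, "power": self.power,
            "T_start": self.T_start, "T_end": self.T_end, "rate": self.rate,
        }


# ---------------------------------------------------------------------------
# survival over a barrier distribution


def _arrhenius(H, T, prefactor):
    """k(H, T), safe at T <= 0 (frozen limit: rate 0)."""
    H = np.asarray(H, float)
    if T <= 0:
        return np.zeros_like(H)
    return prefactor * np.exp(-H / (R_GAS * T))


def survival_curve(
    barriers: BarrierDistribution,
    schedule: Schedule,
    prefactor: float = DEFAULT_PREFACTOR,
    n_nodes: int = 200,
    max_dt: float = 1.0,
):
    """Unbound-fraction curve N(t)/N0 = int g(H) exp(-int k dt') dH.

    Quadrature over >= ``n_nodes`` barrier nodes; the time integral uses the
    trapezoid rule on a grid with steps <= ``max_dt`` seconds.
    Returns (times, survival).
    """
    H, w = barriers.nodes(n_nodes)
    t, T = schedule.fine(max_dt)
    safeT = np.clip(T, 1e-12, None)
    k = prefactor * np.exp(-H[:, None] / (R_GAS * safeT[None, :]))
    k[:, T <= 0] = 0.0
    dt = np.diff(t)
    lam = np.zeros_like(k)
    lam[:, 1:] = np.cumsum(0.5 * (k[:, 1:] + k[:, :-1]) * dt[None, :], axis=1)
    N = w @ np.exp(-lam)
    return t, N


def survival_fraction(
    barriers: BarrierDistribution,
    schedule: Schedule,
    prefactor: float = DEFAULT_PREFACTOR,
    n_nodes: int = 200,
    max_dt: float = 1.0,
) -> float:
    """Fraction still unbound at the end of the schedule."""
    _, N = survival_curve(barriers, schedule, prefactor, n_nodes, max_dt)
    return float(N[-1])


def monte_carlo_survival(
    barriers: BarrierDistribution,
    schedule: Schedule,
    prefactor: float = DEFAULT_PREFACTOR,
    n_molecules: int = 100_000,
    seed: int = 0,
    max_dt: float = 1.0,
) -> float:
    """Per-molecule Monte Carlo estimate of the survival fraction.

    Each molecule draws its own barrier from g(H); survival is a Bernoulli
    trial with probability exp(-Lambda(H)) where Lambda is the accumulated
    rate integral along the schedule.
    """
    rng = np.random.default_rng(seed)
    if barriers.sigma_H == 0:
        H_mol = np.full(n_molecules, barriers.mean_H * 1e3)
    else:
        H_mol = barriers.sample(n_molecules, rng)
    # accumulate Lambda on a dense H reference grid, then interpolate
    lo, hi = H_mol.min(), H_mol.max()
    H_ref = np.linspace(lo, hi if hi > lo else lo + 1.0, 2048)
    t, T = schedule.fine(max_dt)
    safeT = np.clip(T, 1e-12, None)
    k = prefactor * np.exp(-H_ref[:, None] / (R_GAS * safeT[None, :]))
    k[:, T <= 0] = 0.0
    lam_ref = np.trapezoid(k, t, axis=1)
    # interpolate in log space (Lambda is log-linear in H)
    log_lam = np.interp(H_mol, H_ref, np.log(np.clip(lam_ref, 1e-300, None)))
    p_survive = np.exp(-np.exp(log_lam))
    survived = rng.random(n_molecules) < p_survive
    return float(survived.mean())


# ---------------------------------------------------------------------------
# kinetic models


@dataclass
class Exchange:
    """Thermal transfer between two photoproduct bands (e.g. CO rotation)."""

    source: int  # index into the photoproduct band list
    target: int
    barriers: BarrierDistribution


@dataclass
class Substate:
    """One taxonomic substate: a heme-bound A band plus its photoproduct bands."""

    label: str
    bound_band: GaussianBand
    photoproduct_bands: list
    population_fraction: float  # percent
    barriers: BarrierDistribution
    exchange: Exchange | None = None


@dataclass
class SubstateModel:
    """CO-type kinetic model: independent substates, one photoproduct each."""

    sample: str
    ligand: str
    substates: list
    extinction_ratio: float = 20.0
    photolysis_coeff: float = 3e-3  # 1/(s mW): 300 mW x 10 s saturates
    photoproduct_sets: dict = field(default_factory=dict)  # column -> band list

    def __post_init__(self):
        tot = sum(s.population_fraction for s in self.substates)
        if abs(tot - 100.0) > 1e-6:
            raise ValueError(f"substate population fractions sum to {tot}, not 100")

    def bound_bands(self):
        return [s.bound_band for s in self.substates]


@dataclass
class SpeciesNetwork:
    """Multi-species NO photochemistry network.

    States: 6C-ferric-NO, NO-photoproduct (broad, unbound), 6C-ferrous-NO,
    5C-ferric-NO, 4C-heme.  Total heme is conserved.
    """

    sample: str
    bound_bands: list  # 6C-ferric A bands (GaussianBand, signed +)
    photoproduct_band: GaussianBand  # broad unbound NO band
    ferrous_band: GaussianBand  # 6C-ferrous marker (1616 cm^-1)
    fivec_bands: list  # 5C-ferric-NO bands (1814/1818/1822 region)
    rebind_barriers: BarrierDistribution
    recovery_barriers: BarrierDistribution  # 5C -> 6C-ferrous, dark
    photolysis_coeff: float = 3e-3  # 6C-ferric -> photoproduct, 1/(s mW)
    ferrous_to_5c_coeff: float = 2e-6  # photo-only, 1/(s mW)
    fivec_to_4c_coeff: float = 2e-9  # photo-only, 1000x smaller
    extinction_ratio: float = 20.0
    initial_ferric: float = 0.8
    initial_ferrous: float = 0.2
    ligand: str = "NO"

    STATES = (
        "6C-ferric-NO",
        "NO-photoproduct",
        "6C-ferrous-NO",
        "5C-ferric-NO",
        "4C-heme",
    )

    def __post_init__(self):
        if self.initial_ferric < 0 or self.initial_ferrous < 0:
            raise ValueError("initial fractions must be non-negative")
        if abs(self.initial_ferric + self.initial_ferrous - 1.0) > 1e-9:
            raise ValueError("initial ferric + ferrous fractions must sum to 1")


@dataclass
class ProtocolResult:
    """Recorded population trajectories plus the ground-truth record."""

    times: np.ndarray
    temperatures: np.ndarray
    populations: dict
    truth: dict
    final_state: dict = field(default_factory=dict, repr=False)


def _record_indices(n_steps, schedule_T, kind):
    if kind in ("tds_ramp", "slow_cool"):
        # one record per 1-K change
        T0, T1 = schedule_T[0], schedule_T[-1]
        targets = np.arange(0, n_steps + 1)
        Ts = np.interp(targets, [0, n_steps], [T0, T1])
        keep = [0]
        for i in range(1, n_steps + 1):
            if abs(Ts[i] - Ts[keep[-1]]) >= 1.0 - 1e-9:
                keep.append(i)
        if keep[-1] != n_steps:
            keep.append(n_steps)
        return np.array(keep)
    n_rec = min(n_steps, 256)
    return np.unique(np.linspace(0, n_steps, n_rec + 1).round().astype(int))


def _substate_truth(model, protocol, prefactor, seed, n_nodes, dt):
    return {
        "model": "SubstateModel",
        "sample": model.sample,
        "ligand": model.ligand,
        "substates": [
            {
                "label": s.label,
                "bound_center": s.bound_band.center,
                "bound_fwhm": s.bound_band.fwhm,
                "population_fraction": s.population_fraction,
                "mean_H": s.barriers.mean_H,
                "sigma_H": s.barriers.sigma_H,
                "photoproduct": [
                    (b.center, b.fwhm, b.area) for b in s.photoproduct_bands
                ],
            }
            for s in model.substates
        ],
        "extinction_ratio": model.extinction_ratio,
        "photolysis_coeff": model.photolysis_coeff,
        "protocol": protocol.to_dict(),
        "prefactor": prefactor,
        "seed": seed,
        "n_nodes": n_nodes,
        "dt": dt,
    }


def _run_substates(model, protocol, state, prefactor, n_nodes, dt, seed):
    sched = protocol.schedule()
    t, T = sched.fine(dt)
    n_steps = t.size - 1
    P = sched.power if protocol.kind != "tds_ramp" else 0.0
    kp = model.photolysis_coeff * P

    if state is None:
        state = {}
        for s in model.substates:
            H, w = s.barriers.nodes(n_nodes)
            state[s.label] = {
                "H": H,
                "b": (s.population_fraction / 100.0) * w,
                "p": np.zeros_like(w),
                "weights": np.array(
                    [abs(b.area) for b in s.photoproduct_bands], float
                ),
            }
            tot = state[s.label]["weights"].sum()
            if tot > 0:
                state[s.label]["weights"] /= tot

    rec = _record_indices(n_steps, T, protocol.kind)
    pops = {
        s.label: {
            "bound": np.empty(rec.size),
            "photoproduct": np.empty(rec.size),
            "band_weights": np.empty((rec.size, len(s.photoproduct_bands))),
        }
        for s in model.substates
    }

    def record(j):
        for s in model.substates:
            st = state[s.label]
            i = np.searchsorted(rec, j)
            pops[s.label]["bound"][i] = st["b"].sum()
            pops[s.label]["photoproduct"][i] = st["p"].sum()
            pops[s.label]["band_weights"][i] = st["weights"]

    record(0)
    rec_set = set(rec.tolist())
    for step in range(n_steps):
        Tm = 0.5 * (T[step] + T[step + 1])
        h = t[step + 1] - t[step]
        for s in model.substates:
            st = state[s.label]
            kr = _arrhenius(st["H"], Tm, prefactor)
            ksum = kp + kr
            tot = st["b"] + st["p"]
            with np.errstate(invalid="ignore", divide="ignore"):
                beq = np.where(ksum > 0, kr / np.where(ksum > 0, ksum, 1.0) * tot, st["b"])
            st["b"] = beq + (st["b"] - beq) * np.exp(-ksum * h)
            st["p"] = tot - st["b"]
            if s.exchange is not None:
                kex = _arrhenius(
                    np.array([s.exchange.barriers.mean_H * 1e3]), Tm, prefactor
                )[0]
                if kex > 0:
                    w = st["weights"]
                    move = w[s.exchange.source] * -np.expm1(-kex * h)
                    w[s.exchange.source] -= move
                    w[s.exchange.target] += move
        if (step + 1) in rec_set:
            record(step + 1)

    return ProtocolResult(
        times=t[rec],
        temperatures=T[rec],
        populations=pops,
        truth=_substate_truth(model, protocol, prefactor, seed, n_nodes, dt),
        final_state=state,
    )


def _run_network(model, protocol, state, prefactor, n_nodes, dt, seed):
    sched = protocol.schedule()
    t, T = sched.fine(dt)
    n_steps = t.size - 1
    P = sched.power if protocol.kind != "tds_ramp" else 0.0

    if state is None:
        H_reb, w_reb = model.rebind_barriers.nodes(n_nodes)
        H_rec, w_rec = model.recovery_barriers.nodes(n_nodes)
        state = {
            "H_reb": H_reb, "w_reb": w_reb,
            "H_rec": H_rec, "w_rec": w_rec,
            "ferric": model.initial_ferric * w_reb,
            "photo": np.zeros_like(w_reb),
            "ferrous": model.initial_ferrous,
            "fivec": np.zeros_like(w_rec),
            "fourc": 0.0,
        }

    kp1 = model.photolysis_coeff * P
    kp2 = model.ferrous_to_5c_coeff * P
    kp3 = model.fivec_to_4c_coeff * P

    rec = _record_indices(n_steps, T, protocol.kind)
    pops = {label: np.empty(rec.size) for label in SpeciesNetwork.STATES}

    def record(j):
        i = np.searchsorted(rec, j)
        pops["6C-ferric-NO"][i] = state["ferric"].sum()
        pops["NO-photoproduct"][i] = state["photo"].sum()
        pops["6C-ferrous-NO"][i] = state["ferrous"]
        pops["5C-ferric-NO"][i] = state["fivec"].sum()
        pops["4C-heme"][i] = state["fourc"]

    record(0)
    rec_set = set(rec.tolist())
    for step in range(n_steps):
        Tm = 0.5 * (T[step] + T[step + 1])
        h = t[step + 1] - t[step]
        # geminate subsystem: exact two-state relaxation per barrier node
        kr = _arrhenius(state["H_reb"], Tm, prefactor)
        ksum = kp1 + kr
        tot = state["ferric"] + state["photo"]
        with np.errstate(invalid="ignore", divide="ignore"):
            feq = np.where(ksum > 0, kr / np.where(ksum > 0, ksum, 1.0) * tot,
                           state["ferric"])
        state["ferric"] = feq + (state["ferric"] - feq) * np.exp(-ksum * h)
        state["photo"] = tot - state["ferric"]
        # redox subsystem: ferrous -> 5C (photo), 5C -> ferrous (thermal),
        # 5C -> 4C (photo, slow)
        d_ferrous = state["ferrous"] * -np.expm1(-kp2 * h)
        state["ferrous"] -= d_ferrous
        krec = _arrhenius(state["H_rec"], Tm, prefactor)
        r = krec + kp3
        out = state["fivec"] * -np.expm1(-r * h)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac_rec = np.where(r > 0, krec / np.where(r > 0, r, 1.0), 0.0)
        state["fivec"] = state["fivec"] - out
        state["ferrous"] += float((out * frac_rec).sum())
        state["fourc"] += float((out * (1.0 - frac_rec)).sum())
        state["fivec"] = state["fivec"] + d_ferrous * state["w_rec"]
        if (step + 1) in rec_set:
            record(step + 1)

    truth = {
        "model": "SpeciesNetwork",
        "sample": model.sample,
        "protocol": protocol.to_dict(),
        "prefactor": prefactor,
        "seed": seed,
        "n_nodes": n_nodes,
        "dt": dt,
        "photolysis_coeff": model.photolysis_coeff,
        "ferrous_to_5c_coeff": model.ferrous_to_5c_coeff,
        "fivec_to_4c_coeff": model.fivec_to_4c_coeff,
        "rebind_barriers": (model.rebind_barriers.mean_H, model.rebind_barriers.sigma_H),
        "recovery_barriers": (
            model.recovery_barriers.mean_H,
            model.recovery_barriers.sigma_H,
        ),
        "initial": {"ferric": model.initial_ferric, "ferrous": model.initial_ferrous},
    }
    return ProtocolResult(t[rec], T[rec], pops, truth, final_state=state)


def run_protocol(
    model,
    protocol: Protocol,
    seed: int = 0,
    prefactor: float = DEFAULT_PREFACTOR,
    n_nodes: int = 96,
    dt: float = 1.0,
    initial_state: dict | None = None,
) -> ProtocolResult:
    """Integrate the kinetic model through one protocol stage.

    Chaining stages: pass ``result.final_state`` of the previous stage as
    ``initial_state``.  The truth record embeds every input parameter.
    """
    if protocol.kind not in ("flash_4K", "slow_cool", "constant_illumination", "tds_ramp"):
        raise ValueError(f"unknown protocol kind {protocol.kind!r}")
    if isinstance(model, SubstateModel):
        return _run_substates(model, protocol, initial_state, prefactor, n_nodes, dt, seed)
    if isinstance(model, SpeciesNetwork):
        return _run_network(model, protocol, initial_state, prefactor, n_nodes, dt, seed)
    raise TypeError(f"unsupported model type {type(model).__name__}")


# ---------------------------------------------------------------------------
# rendering

A_TOTAL = 1.0  # integrated bound extinction at full population, AU cm^-1


def _components(model, pops, i):
    """Component list [(center, fwhm, signed area)] at record ``i``.

    Ordering is deterministic, so component-wise differences between two
    records are meaningful.
    """
    comps = []
    if isinstance(model, SubstateModel):
        for s in model.substates:
            b = pops[s.label]["bound"][i]
            p = pops[s.label]["photoproduct"][i]
            w = pops[s.label]["band_weights"][i]
            comps.append((s.bound_band.center, s.bound_band.fwhm, A_TOTAL * b))
            for k, band in enumerate(s.photoproduct_bands):
                comps.append(
                    (band.center, band.fwhm,
                     A_TOTAL * p * w[k] / model.extinction_ratio)
                )
        return comps
    tot_bound = sum(abs(b.area) for b in model.bound_bands)
    for band in model.bound_bands:
        comps.append(
            (band.center, band.fwhm,
             A_TOTAL * pops["6C-ferric-NO"][i] * abs(band.area) / tot_bound)
        )
    comps.append(
        (model.photoproduct_band.center, model.photoproduct_band.fwhm,
         A_TOTAL * pops["NO-photoproduct"][i] / model.extinction_ratio)
    )
    comps.append(
        (model.ferrous_band.center, model.ferrous_band.fwhm,
         A_TOTAL * pops["6C-ferrous-NO"][i])
    )
    tot_5c = sum(abs(b.area) for b in model.fivec_bands)
    for band in model.fivec_bands:
        comps.append(
            (band.center, band.fwhm,
             A_TOTAL * pops["5C-ferric-NO"][i] * abs(band.area) / tot_5c)
        )
    return comps


def _render_components(grid, comps):
    y = np.zeros(len(grid))
    for center, fwhm, area in comps:
        y += gaussian_profile(grid, center, fwhm, area)
    return y


def _spectrum_at(model, pops, grid, i):
    return _render_components(grid, _components(model, pops, i))


def _tallest_amp(comps):
    from .spectra import GAUSS_AREA_FACTOR

    return max(abs(a) / (w * GAUSS_AREA_FACTOR) for _, w, a in comps)


def _add_noise(values, sigma, seed):
    rng = np.random.default_rng(seed)
    return values + rng.normal(0.0, sigma, values.shape)


def render_series(
    model,
    result: ProtocolResult,
    grid: WavenumberGrid | None = None,
    noise_pct: float = 0.0,
    seed: int = 0,
) -> SpectrumSeries:
    """Absorbance spectrum series from recorded populations.

    Requires strictly increasing recorded temperatures (a TDS ramp).  Noise
    is additive white Gaussian with sigma = noise_pct% of the tallest
    single-band amplitude anywhere in the series.
    """
    if grid is None:
        grid = WavenumberGrid.default()
    n = result.times.size
    comp_rows = [_components(model, result.populations, i) for i in range(n)]
    values = np.array([_render_components(grid, comps) for comps in comp_rows])
    if noise_pct > 0:
        sigma = noise_pct / 100.0 * max(_tallest_amp(c) for c in comp_rows)
        values = _add_noise(values, sigma, seed)
    meta = {"seed": seed, "noise_pct": noise_pct, "truth": result.truth}
    return SpectrumSeries(grid, result.temperatures, values, "absorbance", meta)


def _diff_from_components(grid, after, before, noise_pct, seed, temperature=4.0):
    delta_comps = [
        (c, w, a1 - a0) for (c, w, a1), (_, _, a0) in zip(after, before)
    ]
    delta = _render_components(grid, delta_comps)
    if noise_pct > 0:
        delta = _add_noise(delta, noise_pct / 100.0 * _tallest_amp(delta_comps), seed)
    return DifferenceSpectrum(grid, delta, temperature)


def render_difference(
    model,
    result_after: ProtocolResult,
    grid: WavenumberGrid | None = None,
    noise_pct: float = 0.0,
    seed: int = 0,
) -> DifferenceSpectrum:
    """Difference spectrum: final state of ``result_after`` minus its start."""
    if grid is None:
        grid = WavenumberGrid.default()
    after = _components(model, result_after.populations, result_after.times.size - 1)
    before = _components(model, result_after.populations, 0)
    return _diff_from_components(
        grid, after, before, noise_pct, seed, float(result_after.temperatures[-1])
    )


def _analytic_populations(model, photolysis, column):
    """Populations before/after an idealized photolysis of given yield."""
    if isinstance(model, SubstateModel):
        before, after = {}, {}
        for s in model.substates:
            f = s.population_fraction / 100.0
            weights = np.array([abs(b.area) for b in s.photoproduct_bands])
            weights = weights / weights.sum() if weights.sum() else weights
            before[s.label] = {
                "bound": np.array([f]),
                "photoproduct": np.array([0.0]),
                "band_weights": np.array([weights]),
            }
            after[s.label] = {
                "bound": np.array([f * (1 - photolysis)]),
                "photoproduct": np.array([f * photolysis]),
                "band_weights": np.array([weights]),
            }
        return before, after
    before = {k: np.array([0.0]) for k in SpeciesNetwork.STATES}
    before["6C-ferric-NO"] = np.array([model.initial_ferric])
    before["6C-ferrous-NO"] = np.array([model.initial_ferrous])
    after = {
        "6C-ferric-NO": np.array([model.initial_ferric * (1 - photolysis)]),
        "NO-photoproduct": np.array([model.initial_ferric * photolysis]),
        "6C-ferrous-NO": np.array([model.initial_ferrous * (1 - photolysis)]),
        "5C-ferric-NO": np.array([model.initial_ferrous * photolysis]),
        "4C-heme": np.array([0.0]),
    }
    return before, after


def photolysis_difference(
    model,
    photolysis: float = 1.0,
    grid: WavenumberGrid | None = None,
    noise_pct: float = 0.0,
    seed: int = 0,
    column: str = "flash",
) -> DifferenceSpectrum:
    """Idealized light-minus-dark difference spectrum at a given yield.

    A bands appear negative, photoproduct (and, for the NO network, 5C and
    depleted 6C-ferrous) features with their conventional signs.
    """
    if grid is None:
        grid = WavenumberGrid.default()
    before, after = _analytic_populations(model, photolysis, column)
    return _diff_from_components(
        grid, _components(model, after, 0), _components(model, before, 0),
        noise_pct, seed,
    )


def render_class_difference(
    model,
    band_class: str = "bound",
    column: str = "flash",
    photolysis: float = 1.0,
    grid: WavenumberGrid | None = None,
    noise_pct: float = 0.0,
    seed: int = 0,
) -> DifferenceSpectrum:
    """Difference spectrum restricted to one band class.

    ``band_class``: "bound" renders the depleted A bands (negative);
    "photoproduct" renders the photoproduct gain bands (positive; for the
    NO network these are the 5C-ferric-NO bands); "ferrous" renders the
    depleted 6C-ferrous marker band of the NO network (negative).  The CO
    ``column`` selects the flash or slow-cool photoproduct inventory.
    """
    if grid is None:
        grid = WavenumberGrid.default()
    comps = []
    if isinstance(model, SubstateModel):
        if band_class == "bound":
            for s in model.substates:
                comps.append(
                    (s.bound_band.center, s.bound_band.fwhm,
                     -A_TOTAL * photolysis * s.population_fraction / 100.0)
                )
        elif band_class == "photoproduct":
            bands = model.photoproduct_sets.get(column)
            if bands is None:
                bands = [b for s in model.substates for b in s.photoproduct_bands]
            tot = sum(abs(b.area) for b in bands)
            for b in bands:
                comps.append(
                    (b.center, b.fwhm,
                     A_TOTAL * photolysis * abs(b.area) / tot / model.extinction_ratio)
                )
        else:
            raise ValueError(f"unknown band class {band_class!r}")
    else:
        if band_class == "bound":
            tot = sum(abs(b.area) for b in model.bound_bands)
            for b in model.bound_bands:
                comps.append(
                    (b.center, b.fwhm,
                     -A_TOTAL * photolysis * model.initial_ferric * abs(b.area) / tot)
                )
        elif band_class == "photoproduct":
            if not model.fivec_bands:
                raise ValueError(f"{model.sample}: no 5C photoproduct bands")
            tot = sum(abs(b.area) for b in model.fivec_bands)
            for b in model.fivec_bands:
                comps.append(
                    (b.center, b.fwhm,
                     A_TOTAL * photolysis * model.initial_ferrous * abs(b.area) / tot)
                )
        elif band_class == "ferrous":
            comps.append(
                (model.ferrous_band.center, model.ferrous_band.fwhm,
                 -A_TOTAL * photolysis * model.initial_ferrous)
            )
        else:
            raise ValueError(f"unknown band class {band_class!r}")
    delta = _render_components(grid, comps)
    if noise_pct > 0:
        delta = _add_noise(delta, noise_pct / 100.0 * _tallest_amp(comps), seed)
    return DifferenceSpectrum(grid, delta)
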