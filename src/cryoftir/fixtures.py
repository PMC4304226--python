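"""Pre-parameterized kinetic models for the four iNOSoxy sample preparations.

Band centers and fractional areas of heme-bound and photolyzed CO/NO are the
published 4-K values for the substrate-free, L-Arg, NOHA and H4B samples.
Band widths are package defaults (the source reports positions and fractions
only); rebinding-barrier means are placed so that the simulated TDS peaks
fall in the temperature windows reported for each sample (e.g. L-Arg/NOHA CO
rebinding maximal at 50-60 K, substrate-free maximal at 4 K extending to
~70 K, 5C-NO dark recovery at 80-120 K).
"""

from __future__ import annotations

from .bandfit import GaussianBand
from .simulate import (
    BarrierDistribution,
    Exchange,
    SpeciesNetwork,
    Substate,
    SubstateModel,
)

__all__ = ["TABLE_BANDS", "SAMPLES", "LIGANDS", "make_fixture", "fixture_names",
           "normalize_sample", "model_to_dict", "model_from_dict"]

SAMPLES = ("wo_substrate", "L-Arg", "NOHA", "H4B")
LIGANDS = ("CO", "NO")

#: (center cm^-1, fractional area %) per sample and band class.
TABLE_BANDS = {
    "wo_substrate": {
        "bound_CO": [(1921, 9), (1945, 40), (1959, 51)],
        "photo_CO_flash": [(2124, 55), (2129, 45)],
        "photo_CO_slow_cool": [(2124, 85), (2132, 15)],
        "bound_NO": [(1870, 100)],
        "photo_NO": [(1814, 23), (1818, 77)],
    },
    "L-Arg": {
        "bound_CO": [(1904, 69), (1921, 13), (1951, 18)],
        "photo_CO_flash": [(2120, 28), (2131, 28), (2144, 32), (2150, 12)],
        "photo_CO_slow_cool": [(2120, 20), (2131, 34), (2145, 30), (2150, 16)],
        "bound_NO": [(1829, 56), (1847, 16), (1870, 28)],
        "photo_NO": [(1814, 13), (1822, 87)],
    },
    "NOHA": {
        "bound_CO": [(1903, 13), (1937, 57), (1956, 30)],
        "photo_CO_flash": [(2122, 75), (2133, 19), (2145, 6)],
        "photo_CO_slow_cool": [(2117, 20), (2124, 44), (2133, 36)],
        "bound_NO": [(1851, 15), (1870, 85)],
        "photo_NO": [(1814, 30), (1818, 70)],
    },
    "H4B": {
        "bound_CO": [(1924, 18), (1951, 82)],
        "photo_CO_flash": [(2124, 75), (2133, 25)],
        "photo_CO_slow_cool": [(2122, 10), (2126, 61), (2134, 29)],
        "bound_NO": [(1872, 82), (1890, 18)],
        "photo_NO": [],  # only a very weak, unresolvable feature
    },
}

FWHM_BOUND_CO = 10.0
FWHM_PHOTO_CO = 6.0
FWHM_BOUND_NO = 14.0
FWHM_PHOTO_NO = 8.0
FWHM_PHOTO_NO_BROAD = 20.0  # the broad 1822 cm^-1 5C feature of the L-Arg sample
FWHM_NO_UNBOUND = 120.0  # unresolved, very broad unbound-NO photoproduct

#: (mean_H, sigma_H) kJ/mol per bound substate, placed to match the reported
#: TDS peak windows with the default ramp (1 K / 180 s) and prefactor 10^8.5.
_CO_BARRIERS = {
    "wo_substrate": {1921: (5.0, 4.0), 1945: (5.0, 4.0), 1959: (5.0, 4.0)},
    "L-Arg": {1904: (11.7, 1.8), 1921: (11.7, 1.8), 1951: (11.7, 1.8)},
    "NOHA": {1903: (11.7, 1.8), 1937: (11.7, 1.8), 1956: (5.0, 4.0)},
    "H4B": {1924: (12.8, 1.5), 1951: (4.1, 3.0)},
}

#: NO geminate rebinding (starts at the lowest temperatures) per sample.
_NO_REBIND = {
    "wo_substrate": (4.0, 4.0),
    "L-Arg": (5.0, 1.5),
    "NOHA": (4.0, 4.0),
    "H4B": (6.0, 4.0),
}

#: 5C -> 6C-ferrous thermal recovery: dark decay in the 80-120 K window.
_NO_RECOVERY = (21.5, 2.5)

_ALIASES = {
    "wo_substrate": "wo_substrate", "w/o": "wo_substrate", "none": "wo_substrate",
    "substrate-free": "wo_substrate", "wo": "wo_substrate",
    "l-arg": "L-Arg", "larg": "L-Arg", "arg": "L-Arg",
    "noha": "NOHA", "h4b": "H4B",
}


def normalize_sample(name: str) -> str:
    key = _ALIASES.get(str(name).lower())
    if key is None:
        raise ValueError(f"unknown sample name {name!r}; choose from {SAMPLES}")
    return key


def fixture_names():
    return [f"{s}:{l}" for s in SAMPLES for l in LIGANDS]


def _photo_no_bands(sample):
    bands = []
    for center, frac in TABLE_BANDS[sample]["photo_NO"]:
        fwhm = FWHM_PHOTO_NO_BROAD if (sample == "L-Arg" and center == 1822) else FWHM_PHOTO_NO
        bands.append(GaussianBand(center, fwhm, float(frac)))
    return bands


def make_fixture(sample: str, ligand: str):
    """Build the pre-loaded kinetic model for one sample x ligand pair."""
    sample = normalize_sample(sample)
    ligand = str(ligand).upper()
    if ligand not in LIGANDS:
        raise ValueError(f"unknown ligand {ligand!r}; choose CO or NO")

    if ligand == "CO":
        flash = [
            GaussianBand(c, FWHM_PHOTO_CO, float(f))
            for c, f in TABLE_BANDS[sample]["photo_CO_flash"]
        ]
        slow = [
            GaussianBand(c, FWHM_PHOTO_CO, float(f))
            for c, f in TABLE_BANDS[sample]["photo_CO_slow_cool"]
        ]
        exchange = None
        if sample == "L-Arg":
            # thermal CO rotation transfers photoproduct population
            # 2131 -> 2144 cm^-1 around 12 K
            exchange = Exchange(source=1, target=2,
                                barriers=BarrierDistribution(2.4, 0.0))
        substates = []
        for center, frac in TABLE_BANDS[sample]["bound_CO"]:
            mean, sigma = _CO_BARRIERS[sample][center]
            substates.append(
                Substate(
                    label=f"A{center}",
                    bound_band=GaussianBand(center, FWHM_BOUND_CO, float(frac)),
                    photoproduct_bands=[
                        GaussianBand(b.center, b.fwhm, b.area * frac / 100.0)
                        for b in flash
                    ],
                    population_fraction=float(frac),
                    barriers=BarrierDistribution(mean, sigma),
                    exchange=exchange,
                )
            )
        return SubstateModel(
            sample=sample,
            ligand="CO",
            substates=substates,
            photoproduct_sets={"flash": flash, "slow_cool": slow},
        )

    bound = [
        GaussianBand(c, FWHM_BOUND_NO, float(f))
        for c, f in TABLE_BANDS[sample]["bound_NO"]
    ]
    mean, sigma = _NO_REBIND[sample]
    ferrous0 = 0.05 if sample == "H4B" else 0.2
    return SpeciesNetwork(
        sample=sample,
        bound_bands=bound,
        photoproduct_band=GaussianBand(1820.0, FWHM_NO_UNBOUND, 100.0),
        ferrous_band=GaussianBand(1616.0, FWHM_BOUND_NO, 100.0),
        fivec_bands=_photo_no_bands(sample),
        rebind_barriers=BarrierDistribution(mean, sigma),
        recovery_barriers=BarrierDistribution(*_NO_RECOVERY),
        initial_ferric=1.0 - ferrous0,
        initial_ferrous=ferrous0,
    )


# ---------------------------------------------------------------------------
# human-editable serialization


def _band_dict(b: GaussianBand):
    return {"center": b.center, "fwhm": b.fwhm, "area": b.area}


def model_to_dict(model) -> dict:
    """Serialize a kinetic model to plain keys (states, bands, barriers, rates)."""
    if isinstance(model, SubstateModel):
        return {
            "model": "SubstateModel",
            "sample": model.sample,
            "ligand": model.ligand,
            "extinction_ratio": model.extinction_ratio,
            "photolysis_coeff": model.photolysis_coeff,
            "photoproduct_sets": {
                k: [_band_dict(b) for b in v] for k, v in model.photoproduct_sets.items()
            },
            "states": [
                {
                    "label": s.label,
                    "bound_band": _band_dict(s.bound_band),
                    "photoproduct_bands": [_band_dict(b) for b in s.photoproduct_bands],
                    "population_fraction": s.population_fraction,
                    "barriers": {"mean_H": s.barriers.mean_H, "sigma_H": s.barriers.sigma_H},
                    "exchange": None if s.exchange is None else {
                        "source": s.exchange.source,
                        "target": s.exchange.target,
                        "mean_H": s.exchange.barriers.mean_H,
                        "sigma_H": s.exchange.barriers.sigma_H,
                    },
                }
                for s in model.substates
            ],
        }
    if isinstance(model, SpeciesNetwork):
        return {
            "model": "SpeciesNetwork",
            "sample": model.sample,
            "ligand": model.ligand,
            "extinction_ratio": model.extinction_ratio,
            "rates": {
                "photolysis_coeff": model.photolysis_coeff,
                "ferrous_to_5c_coeff": model.ferrous_to_5c_coeff,
                "fivec_to_4c_coeff": model.fivec_to_4c_coeff,
            },
            "bands": {
                "bound": [_band_dict(b) for b in model.bound_bands],
                "photoproduct": _band_dict(model.photoproduct_band),
                "ferrous": _band_dict(model.ferrous_band),
                "fivec": [_band_dict(b) for b in model.fivec_bands],
            },
            "barriers": {
                "rebind": {"mean_H": model.rebind_barriers.mean_H,
                           "sigma_H": model.rebind_barriers.sigma_H},
                "recovery": {"mean_H": model.recovery_barriers.mean_H,
                             "sigma_H": model.recovery_barriers.sigma_H},
            },
            "initial": {"ferric": model.initial_ferric, "ferrous": model.initial_ferrous},
        }
    raise TypeError(f"unsupported model type {type(model).__name__}")


def _band_from(d):
    return GaussianBand(d["center"], d["fwhm"], d["area"])


def model_from_dict(d: dict):
    kind = d.get("model")
    if kind == "SubstateModel":
        substates = []
        for s in d["states"]:
            ex = s.get("exchange")
            substates.append(
                Substate(
                    label=s["label"],
                    bound_band=_band_from(s["bound_band"]),
                    photoproduct_bands=[_band_from(b) for b in s["photoproduct_bands"]],
                    population_fraction=s["population_fraction"],
                    barriers=BarrierDistribution(s["barriers"]["mean_H"], s["barriers"]["sigma_H"]),
                    exchange=None if ex is None else Exchange(
                        ex["source"], ex["target"],
                        BarrierDistribution(ex["mean_H"], ex["sigma_H"]),
                    ),
                )
            )
        return SubstateModel(
            sample=d["sample"], ligand=d["ligand"], substates=substates,
            extinction_ratio=d["extinction_ratio"],
            photolysis_coeff=d["photolysis_coeff"],
            photoproduct_sets={
                k: [_band_from(b) for b in v]
                for k, v in d.get("photoproduct_sets", {}).items()
            },
        )
    if kind == "SpeciesNetwork":
        return SpeciesNetwork(
            sample=d["sample"],
            bound_bands=[_band_from(b) for b in d["bands"]["bound"]],
            photoproduct_band=_band_from(d["bands"]["photoproduct"]),
            ferrous_band=_band_from(d["bands"]["ferrous"]),
            fivec_bands=[_band_from(b) for b in d["bands"]["fivec"]],
            rebind_barriers=BarrierDistribution(
                d["barriers"]["rebind"]["mean_H"], d["barriers"]["rebind"]["sigma_H"]
            ),
            recovery_barriers=BarrierDistribution(
                d["barriers"]["recovery"]["mean_H"], d["barriers"]["recovery"]["sigma_H"]
            ),
            photolysis_coeff=d["rates"]["photolysis_coeff"],
            ferrous_to_5c_coeff=d["rates"]["ferrous_to_5c_coeff"],
            fivec_to_4c_coeff=d["rates"]["fivec_to_4c_coeff"],
            extinction_ratio=d["extinction_ratio"],
            initial_ferric=d["initial"]["ferric"],
            initial_ferrous=d["initial"]["ferrous"],
        )
    raise ValueError(f"unknown model kind {kind!r}")
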