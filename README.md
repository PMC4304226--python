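# cryoftir

Analysis toolkit for **cryogenic FTIR photolysis-difference spectroscopy** and
**temperature derivative spectroscopy (TDS)** of heme–ligand rebinding, paired
with a forward simulator of photodissociation/rebinding kinetics that
generates every input the analysis consumes.

## The scientific problem

Heme enzymes such as the oxygenase domain of inducible nitric oxide synthase
(iNOSoxy) bind small ligands (CO, NO, O₂) at the heme iron. The ligand
stretching vibration (ν(CO) ≈ 1900–1960 cm⁻¹ bound, ~2080–2160 cm⁻¹ after
photolysis; ν(NO) ≈ 1820–1890 cm⁻¹) is an exquisitely sensitive probe of the
active site. At cryogenic temperature, a laser flash photodissociates the
ligand, which stays trapped inside the frozen protein; the **photolysis
difference spectrum**

> ΔA(ν) = log₁₀( I_dark(ν) / I_light(ν) )

contains only photolysis-induced features — depleted heme-bound bands
(*A bands*, negative) and photoproduct bands (positive). Decomposing ΔA into
Gaussian components gives band positions and fractional occupancies of the
taxonomic substates.

In a TDS experiment, the photolyzed sample is warmed linearly in the dark
(one spectrum per 1-K step). Rebinding is a thermally activated first-order
process over a static distribution of enthalpy barriers g(H), so the
survival fraction of photolyzed ligands is

> N(t)/N₀ = ∫ g(H) · exp( −∫ k₀ e^(−H/RT(t′)) dt′ ) dH.

Successive-spectrum differences, plotted as a temperature × wavenumber
contour map, separate rebinding processes by their barrier heights. For a
sharp barrier H under a linear ramp with rate β, the temperature T_p of
maximal rebinding rate satisfies the Kissinger-type condition

> H / (R·T_p²) = (k₀ / β) · exp( −H / (R·T_p) ),

which this package inverts numerically to convert TDS peak temperatures into
barriers (kJ/mol).

## What's in the package

| module | contents |
|---|---|
| `cryoftir.spectra` | wavenumber grids, spectra, difference spectra, band integrals |
| `cryoftir.bandfit` | peak picking and multi-Gaussian least-squares decomposition (lmfit) |
| `cryoftir.tds` | TDS map construction, peak extraction, log-spaced contours, Kissinger inversion |
| `cryoftir.simulate` | barrier-distribution survival kinetics, illumination protocols (flash, slow-cool, constant illumination, TDS ramp), multi-species NO photochemistry, spectrum rendering |
| `cryoftir.fixtures` | pre-parameterized models of the four iNOSoxy preparations (substrate-free, L-Arg, NOHA, H4B) × (CO, NO) |
| `cryoftir.io` / `cryoftir.cli` | wide tabular CSV series I/O, minimal JCAMP-DX import, `cryoftir` command line |

## Worked example

Simulate a 10-s, 300-mW flash on the L-Arg/CO sample (1% noise) and
decompose the heme-bound window:

```sh
cryoftir simulate --fixture L-Arg:CO --protocol flash_4K --noise-pct 1 --seed 0 --out diff.csv
cryoftir fit --in diff.csv --window 1800 2000 --n-bands 3 --out bands.csv
```

prints

```
  1904.01 cm-1   68.7 %  fwhm  10.11 cm-1
  1920.87 cm-1   12.9 %  fwhm   9.90 cm-1
  1951.03 cm-1   18.4 %  fwhm  10.03 cm-1
```

— the three A bands of the L-Arg–bound enzyme (published values 1904/69%,
1921/13%, 1951/18%), recovered within the experimental error bars of
±0.5 cm⁻¹ and ±3 points. The red-shifted dominant band at 1904 cm⁻¹ reflects
the positively charged guanidinium group of L-Arg next to the bound CO.

Run the TDS protocol (flash, then dark 1 K/180 s ramp) and locate the
rebinding peak:

```sh
cryoftir simulate --fixture L-Arg:CO --protocol tds_ramp --noise-pct 0 --seed 0 --out series.csv
cryoftir tds --in series.csv --out map.csv --min-amplitude 1e-3
```

```
peak: T=  54.1 K  nu= 1904.0 cm-1  gain  amplitude=4.507e-02
```

CO returns to the L-Arg–stabilized active site at 50–60 K. Inverting the
peak temperature with the default attempt frequency k₀ = 10^8.5 s⁻¹:

```sh
cryoftir invert --t-peak 54.1 --ramp 1/180
# 11.477
```

i.e. a rebinding enthalpy barrier of ≈ 11.5 kJ/mol (the fixture's input
barrier mean is 11.7 kJ/mol).

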