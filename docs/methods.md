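# Methods

## Spectra and difference spectra

Spectra live on uniform ascending wavenumber grids; the default window is
1700–2300 cm⁻¹ at 2 cm⁻¹ (InSb detector range), with an extended
1100–2300 cm⁻¹ window (MCT range) selectable. Absorbance is defined base-10,
A = log₁₀(I_ref/I); the photolysis difference is ΔA = log₁₀(I_dark/I_light),
so depleted heme-bound (A) bands are negative and photoproduct bands
positive. Difference spectra are treated as baseline-free: all modeled
features are Gaussian bands on a flat zero background, and no baseline
correction stage exists. Band integrals use the trapezoid rule with optional
sign selection (positive part, negative part, absolute value, raw).

## Gaussian band decomposition

Bands are pure Gaussians parameterized by center, FWHM and signed integrated
area (amplitude = area / (fwhm·√(π/ln 16))). Initial guesses come from local
extrema of a Savitzky–Golay-smoothed spectrum (window 7, order 3), strongest
first; refinement is Levenberg–Marquardt least squares (lmfit) with centers
constrained to the fit window and widths bounded to [2, 200] cm⁻¹. Widths
are free per band by default. Components converging to within 1 cm⁻¹ of each
other are merged (areas added, area-weighted center) and the reduced model
refitted once. `fit_n_bands` grows the model greedily — when peak picking
finds fewer components than requested, one band is added at the largest
residual extremum of the expected sign and the model refitted — which
recovers shoulders such as the 2150 cm⁻¹ companion of the 2144 cm⁻¹ CO
photoproduct band.

Fractional occupancies are reported as 100·|areaᵢ|/Σ|area| within one band
class; mixed amplitude signs within a class are rejected.

**Identifiability limit.** Two equal-width Gaussians separated by half a
width (the 1814/1818 cm⁻¹ five-coordinate NO features, FWHM 8 cm⁻¹) cannot
be decomposed with free widths at 1% noise: even fits initialized at the
true parameters show median center errors of ~1.7 cm⁻¹, i.e. the information
is not in the data. For such blends the recovery procedure holds widths at
the class default, which restores center errors to ~0.3 cm⁻¹ and fraction
errors to ~2.7 points — at, not comfortably inside, the ±3-point
experimental error bar; a single noisy realization of these rows lands on
either side of that bar with near-even odds, so recovery contracts for them
are stated on medians over noise seeds.

Default widths by class (the source data report positions and fractions
only; widths are package choices matching the described band shapes):
heme-bound CO 10 cm⁻¹, CO photoproduct 6 cm⁻¹, heme-bound NO 14 cm⁻¹,
narrow NO photoproduct features 8 cm⁻¹, the broad 1822 cm⁻¹ L-Arg feature
20 cm⁻¹, the unresolved unbound-NO band 120 cm⁻¹.

## TDS maps and barrier inversion

A TDS map holds successive-spectrum differences, row t = A(T_{t+1}) − A(T_t);
rows telescope exactly to (last − first). Midpoint temperatures label rows
internally; serialized maps are labeled by the lower temperature of each
pair. Contour levels are geometric, max|Δ|/r^(n−1) … max|Δ| with ratio r = 2,
mirrored for negative levels. Peaks are extracted from band-integrated step
traces (not single wavenumber columns, to suppress noise) as local extrema
above an amplitude threshold, with three-point parabolic refinement of the
peak temperature; ramp-endpoint maxima (rebinding already maximal at the
starting temperature) are retained.

`invert_peak_enthalpy` solves H/(R·T_p²) = (k₀/β)·exp(−H/(R·T_p)) by Brent
bracketing on [0.1, 200] kJ/mol; the condition is monotone in H for physical
parameters, so the root is unique. Defaults: ramp rate β = 1 K/180 s
(4→160 K in ≈7.8 h) and attempt frequency k₀ = 10^8.5 s⁻¹, a typical
geminate heme–ligand rebinding prefactor; both are configurable and recorded
in output metadata, and both are package defaults rather than measured
values. Simulated delta-barrier peaks round-trip through extraction and
inversion within 2% over H = 5–60 kJ/mol (ramps extended to 320 K so the
highest barriers rebind within the ramp).

## Forward kinetics simulator

Kinetics are first-order with **static** conformational heterogeneity:
below ~160 K protein motions are frozen, so each molecule keeps a fixed
rebinding barrier H drawn from a Gaussian g(H) truncated at H ≥ 0
(renormalized). Survival under an arbitrary piecewise-linear temperature
schedule is computed by quadrature over ≥200 barrier nodes and trapezoid
time integration with steps ≤ 1 s; a per-molecule Monte Carlo estimator
(barrier sampling + Bernoulli survival) serves as an independent oracle and
agrees within binomial error.

Protocol integration uses 1-s steps with the exact two-state
(photolysis ⇄ rebinding) relaxation per barrier node within each step, which
is unconditionally stable even for the near-barrierless nodes that rebind
essentially instantly at 4 K. Photolysis rate = coefficient × laser power,
linear, with the coefficient (3×10⁻³ s⁻¹ mW⁻¹) chosen so that the standard
10-s, 300-mW flash saturates photolysis. Illumination protocols: flash
(10 s at 4 K), slow-cool (160→4 K at 0.3 K/min under light, photolysis and
rebinding competing throughout), constant illumination (15,000 s at 0.3, 10
or 300 mW), and the dark TDS ramp (1 K/180 s, one record per 1 K).

**CO models** are lists of substates, each with an A band, photoproduct
bands, a population fraction and its own barrier distribution; an optional
exchange term transfers photoproduct population between two bands (CO
rotation by 180°, e.g. 2131→2144 cm⁻¹ around 12 K, barrier 2.4 kJ/mol),
producing mirror-imaged gain/loss contours in the dark.

**NO photochemistry** is a five-state network — 6C-ferric-NO, unbound NO
photoproduct, 6C-ferrous-NO, 5C-ferric-NO, 4C heme — with conserved total
heme. Ferric-NO photolysis/rebinding is the two-state subsystem above with
low barriers (rebinding starts at the lowest temperatures). The
6C-ferrous → 5C conversion (light-induced rupture of the iron–thiolate
bond) is photo-only with a coefficient of 2×10⁻⁶ s⁻¹ mW⁻¹, so 15,000 s at
0.3 mW converts <1% of the ferrous population while 300 mW saturates it;
5C → 4C is photo-only and 1000× slower still; 5C → 6C-ferrous recovery is
thermal with barriers (21.5 ± 2.5 kJ/mol) placing the dark decay at
80–120 K. Initial composition is 80% ferric / 20% ferrous (95/5 with H4B,
where the ferrous adduct is unstable).

Rendering sums Gaussian components scaled by state populations. The total
bound-state integrated extinction is normalized to 1 AU·cm⁻¹; unbound
(photoproduct) ligand bands carry 1/20 of the bound integrated extinction
(the A:photoproduct area ratio ≈ 20), while 5C- and 6C-ferrous-NO bands are
heme-bound species and keep full extinction. The unbound-NO band conserves
its integrated extinction but is 120 cm⁻¹ wide, so its peak amplitude stays
below twice the 1% noise floor — undetectable, as observed. Noise is
additive white Gaussian with σ expressed as a percentage of the tallest
single-band amplitude in the rendered result; every stochastic operation
takes an explicit seed, which the truth record embeds.

### What the generator emulates, and what it does not

The generator reproduces the published band inventories and fractional
areas, the A:photoproduct extinction contract, single-kinetic-state
rebinding over barrier distributions, protocol-dependent photolysis yields
and the power-dependent 6C→5C photoconversion. It does **not** emulate
baseline drift, water-vapor lines, detector nonlinearity, anisotropy or
photoselection, wavelength-dependent quantum yields, kinetic hole burning,
or barrier re-equilibration above the freezing transition — so passing
tests validate the analysis chain under the stated noise model, not
robustness to those artifacts. Barrier-distribution parameters of the
fixtures are chosen to place TDS peaks in the qualitatively reported
temperature windows (e.g. L-Arg/NOHA CO at 50–60 K, substrate-free maximal
at 4 K extending to ~70 K); they are illustrative, not fitted constants, and
the 6C→5C rate coefficients reproduce only the qualitative power dependence.

## Numerical choices and degenerate inputs

- Quadrature: 200 barrier nodes over ±6σ (survival), 96 nodes in protocol
  integration; σ_H = 0 collapses to a single node.
- T ≤ 0 K is the frozen limit (rate 0), handled explicitly.
- Temperature steps deviating from 1 K by more than 0.5 K produce a warning,
  not an error; a single-spectrum series is rejected for TDS.
- All-zero spectra: peak picking returns an empty band set; contour levels
  raise (no scale exists).
- Problem sizes in the test-suite simulations (ramp ends of 60–320 K,
  96 barrier nodes, 10⁵ Monte Carlo molecules) were chosen so every check
  runs in seconds while keeping discretization error far below the asserted
  tolerances.

## Known limitations

Full deconvolution of g(H) from TDS maps is out of scope (only
peak-position inversion is provided), as are baseline/atmospheric
correction, Voigt or Lorentzian band shapes, automatic band-count selection,
and absolute extinction coefficients. The Kissinger inversion assumes a
sharp barrier; for broad distributions the returned H is the barrier at the
rate maximum, not the distribution mean.
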