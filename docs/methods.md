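# Methods

This note documents the models behind `pharmera`, the defaults and why
they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions that matter for reproducibility.

## Exposure model

Per-capita daily use of the active moiety is derived from annual sales as
`(m_active + m_prodrug · MW_active/MW_prodrug) / population / 365`. The
year basis is fixed at 365 d; leap years are ignored. Prodrug conversion
assumes complete cleavage (one mole of active per mole of prodrug), which
is the documented metabolic fate of mycophenolate mofetil.

The STP influent PEC is use divided by per-capita wastewater volume
(default 200 L/person/d, the regulatory initial-tier default). The
surface-water PEC applies removal `R` to the treated fraction `f_t` of the
mass only — the untreated remainder passes unchanged — and divides by the
dilution factor `D`:

    PEC_SW = PEC_STP · (f_t(1−R) + (1−f_t)) / D.

The initial tier uses `f_t = 1, R = 0, D = 10`; refined tiers use
`f_t = 0.8` and country-specific `W`, `R`, `D`. A useful consequence is
that the ratio of PECs across removal scenarios,
`(f_t(1−R₂)+1−f_t)/(f_t(1−R₁)+1−f_t)`, is independent of `D`; the test
suite asserts this identity both on random scenarios and on the published
MPA PEC triplets.

When countries are aggregated, the package uses population-weighted means
and the lower weighted median (smallest value whose cumulative weight
reaches 50 %). The composition of published "weighted" cross-country
averages is not fully specified anywhere we know of; population weighting
of country surface-water PECs is this package's documented choice.
"Highest per-capita use" across years is selected per country before PEC
derivation; the operations themselves accept any use value so callers can
implement other policies.

## Fate kinetics

Rate constants are unit-tagged (`per_minute`, `per_hour`, `per_day`) and
converted exactly (×/÷ 60, 24). `DT50 = ln 2 / k`.

`fit_first_order` extracts `k` from a cumulative mineralization curve by
least squares on `C(t) = plateau·(1 − e^{−kt})` (scipy `curve_fit`,
bounded `k ≥ 0`, `plateau ∈ [0, 110] %`). The plateau is a free parameter
because real curves level off below 100 % (bound residues, biomass
incorporation). The functional form is an assumption — mineralization
data are rarely published with their fitting protocol — and is the
simplest model consistent with a rise-to-plateau CO₂ curve. Parameter
recovery on synthetic curves is within 1 % without noise; at 5 % relative
Gaussian noise on six sampling points the median error across seeds is
about 6 % and roughly three-quarters of seeds recover `k` within 10 %, so
a single noisy realisation is checked at the 10 % level with a fixed,
typical seed. Curves whose noise produces dips larger than the
`MineralizationCurve` smoothing tolerance (15 percentage points) are
rejected at construction.

`estimate_stp_removal` is a deliberate simplification: one continuously
stirred tank at steady state, `R = kτ/(1+kτ) (+ sorbed fraction)`. The
default hydraulic residence time τ = 7.7 h was calibrated once so that the
three published removal scenarios for MPA (12 %, 43.6 %, 73.1 % at
k = 0.0174 h⁻¹, 0.0017 min⁻¹, 0.006 min⁻¹) are reproduced within two
percentage points. It is documented as a calibration, not as a
reimplementation of any multi-compartment STP fate model; removal
fractions used in exposure scenarios remain plain inputs.

Sorption is carried as data (`K_OC = K_d / f_oc`); no sediment
two-compartment model is implemented — water/sediment study outcomes
enter only as their reported DT50s.

## Effect thresholds

Aquatic PNECs take the minimum chronic endpoint of the requested kind
(NOEC or EC10) across fish, daphnids, green algae and cyanobacteria and
divide by an assessment factor (default 10, the standard chronic AF for a
four-taxa base set). The STP PNEC divides the sludge respiration
inhibition EC10 by 10.

For the antibiotic-resistance PNEC the package implements both published
conventions: lowest MIC ÷ 100, and the species-count-adjusted variant
restricted to species with ≥ 10 MIC observations (one lowest MIC per
eligible species, scaled by `n_species/41` and a general factor 10). The
latter is rounded **down** to the standard two-fold antimicrobial dilution
series (2ⁿ µg/L: …, 0.25, 0.5, 1, …, 32, 64, 128 …), because the source
method reports PNECs at MIC test concentrations; 76 µg/L rounds to
64 µg/L. The quoted formula is ambiguous about operator precedence; the
implemented reading `lowest_MIC · (n/41) / 10` reproduces the published
worked value and is fixed here. The final PNEC_ABR is the lower of the
two candidates. The ÷ 41 constant is the species count of the reference
MIC dataset underlying the method and is exposed as a parameter.

The PBT screen is three independent legs with explicit rationales.
Persistence is an *evidence flag* (simulation-test outcome supplied by the
caller), not a computed half-life classification, because screening
practice argues from test outcomes. Bioaccumulation triggers at
max BCF ≥ 2000 or max log D ≥ 4.5; toxicity at any chronic NOEC < 10 µg/L
or a CMR flag. Missing inputs yield explicit `undetermined` legs rather
than defaults.

## Censored statistics

Nondetects are ordered before the smallest detect, by their LOQ; detects
reported below their own LOQ ("trace" values) are kept as detects.
Quantiles use the nearest-rank (ceiling) convention on the
censored-ordered list: percentile *p* is the value at rank
`⌈p·n/100⌉`, reported as `<LOQ` when that rank is a nondetect. With no
nondetects this reduces exactly to the ordinary nearest-rank empirical
quantile. Note the convention is deliberately conservative at rank
boundaries: for 5 nondetects followed by 5 detects the 50th percentile is
the last nondetect (`<LOQ`), and the lowest detect first appears at the
51st. Means substitute nondetects at half their LOQ (alternatives: zero,
full LOQ). Exceedance counting treats a nondetect as below the threshold
only when its LOQ does not exceed the threshold; otherwise the comparison
is indeterminate and the operation raises instead of guessing.
Maximum-likelihood and Kaplan–Meier censored estimators are out of scope;
substitution mirrors the conventions of the assessments this package
implements. Pooling of datasets of unequal size is unweighted.

## Secondary poisoning

ADE = PoD · body weight / ∏(adjustment factors), with every factor
carrying a rationale string, so the derivation is a machine-readable audit
trail. Rounding is an explicit named policy (`two_decimals`,
`down_one_sig_fig`, `nearest_0p005`, `none`) because published derivations
round inconsistently; the unrounded value is always retained and is
invariant under factor reordering. Across candidate derivations the
minimum (protective) ADE is selected. The MTDI scales the ADE linearly by
body weight (60-kg human → 10-kg otter).

Intake combines `fish_intake · BCF · C_water` with
`water_intake · C_water`. In the bundled MPA worst case the two routes use
deliberately mixed concentrations — the fish burden derives from the
highest modelled catchment PEC (0.671 µg/L) while the human drinking-water
route uses the highest *measured* concentration (0.656 µg/L), with no
drinking-water treatment removal credited. This reproduces the published
worst-case construction; users wanting a single consistent concentration
can build the `IntakeScenario` directly. The published extreme low-flow
top-predator quotients are not reproduced here: they are inconsistent
with the BCF and intake rates used in the mean-flow case (they imply an
effective intake factor two orders of magnitude larger) and are therefore
excluded as reproduction targets.

## Catchment simulator

The river network is a forest of segments draining to outlets; validation
rejects cycles and dangling references. Propagation is one topological
pass: upstream outlet loads decay first-order over the *receiving*
segment's travel time, the local STP load joins undecayed near the
segment outlet, and PEC = load / volumetric flow. Effluent volume is
neglected against river flow — the same convention as the dilution-factor
tier — which diverges from full georeferenced exposure models and
overestimates concentration slightly in effluent-dominated stretches.
Flow scenarios (mean/low/high) are static per-segment fields, not
hydrographs; decay defaults to 0 because in-stream fate evidence for the
bundled substance is qualitative. With zero decay, summed outlet load
equals total discharged load exactly, which the tests assert to 1e-12
relative tolerance. Percentiles over a PEC field include zero-PEC
headwater segments and report values below 0.0005 µg/L (half the typical
monitoring LOQ) as below-floor.

## Synthetic data

Generators are seeded (`numpy.random.default_rng`, one generator per
call, no global state) and deterministic per seed.

* **Use tables** (default 24 countries × 14 years): lognormal per-capita
  use (median 300 µg/person/d, log-sd 0.5 — chosen so that country-year
  values span roughly 100–900 µg/d, bracketing the highest observed
  Europe-wide value of ~600 µg/d), log-uniform populations between 10⁶
  and 8·10⁷. Not emulated: market growth trends, country-level
  autocorrelation, retail/hospital splits.
* **Censored datasets** (default n = 110, LOQ 0.001 µg/L, detection
  fraction 0.55, log-sd 1.8): the lognormal median is placed so that
  P(X > LOQ) equals the detection fraction; the realized detect count is
  binomial. Not emulated: spatial/seasonal structure, mixed LOQs across
  laboratories.
* **Mineralization curves**: exact first-order curves at the configured
  (k, plateau) with optional relative Gaussian noise; default sampling at
  1, 2, 4, 7, 14, 28 d.
* **River networks** (default 50 segments): random recursive trees with a
  branching probability, lognormal mean flows and a ×/÷ 4 seasonal flow
  envelope, STPs on a random 30 % of segments. Not emulated: real
  hydrography, flow accumulation downstream (flows are drawn
  independently, so a child segment can carry less flow than its
  parents — percentile monotonicity in the flow scenario still holds
  because scenarios scale each segment's own flow).

Because the generators are structural emulations, passing tests
demonstrate correctness of the computational chain and its invariants
(conservation, monotonicity, reduction to uncensored statistics), not
predictive skill on any real catchment or market.

## Bundled MPA constants

`pharmera.synthetic.mpa_fixture()` loads `data/mpa.json`: physicochemical
properties, chronic endpoints (NOECs 83.9/9/630/1.32 µg/L, EC10s
155/12/929/5.8 µg/L, sludge EC10 69 mg/L), the 23-record bacterial MIC
table, both ADE derivations with their factor chains, exposure scenario
constants and intake defaults. Strain-level MIC values between the
reported range endpoints of the *S. aureus* set are synthetic stand-ins
on the dilution series (only the lowest value and the observation count
enter any computation), and the highest-country dilution factor (15.0) is
back-computed from the published PEC pair rather than taken from a
hydrological dataset; both are flagged in the file's `notes`.

## Numerical conventions and edge cases

* Risk verdicts flip strictly above RQ = 1; RQ = 1 is still "no
  significant risk".
* Quotients are reported at 3 significant figures in human-readable
  outputs; machine-readable outputs keep full precision.
* Geometric-mean BCF selection uses a closed pH interval; duplicate pH
  keys (e.g. `"5"` and `5.0` colliding after float conversion) are
  rejected rather than silently merged.
* Division-by-zero style inputs (zero wastewater volume, zero organic
  carbon, zero PNEC, non-positive population) raise
  `InvalidParameterError`; empty observation sets raise `NoDataError`;
  fit failures carry diagnostics.
* CSV dialect: comma-separated, UTF-8, "." decimal; concentrations in
  µg/L everywhere in outputs (MICs are read in mg/L and converted).
* Full runs are deterministic: rerunning the same config byte-identically
  reproduces every output file.

## Problem sizes

The test suite runs synthetic networks of 40–120 segments, censored
datasets of 40–110 samples and six-point mineralization curves; the
acceptance script uses a 120-segment network and 11 noisy-curve
replicates. These sizes exercise every code path and keep the whole suite
in the tens of seconds on a single CPU; all headline MPA quantities are
closed-form and independent of them.

## Known limitations

* No probabilistic ERA (joint exposure × effect distributions), no
  mixture toxicity, no species-sensitivity distributions.
* The STP removal estimator is a one-parameter calibration, not a fate
  model; use measured or modelled removals as scenario inputs where
  available.
* The catchment simulator is an emulation for distributional testing; it
  has no GIS hydrology and should not be used for site-specific
  predictions.
* Censored statistics are substitution-based by design.
* Human pharmacokinetics beyond full prodrug cleavage (glucuronide
  excretion and deconjugation in sewers) is not modelled; per-capita use
  is treated as fully excreted active moiety, which is conservative.
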