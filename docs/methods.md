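# Methods

## Dose currency: absorbed photon density

All cross-agent comparisons use the photodynamic threshold model's dose
unit, photons absorbed by the photosensitizer per unit tissue volume
(hv cm⁻³).  For a flat-field exposure `H` [J cm⁻²] at wavelength `λ`,

    psi = H / (h c / λ)                     [hv cm⁻²]
    n_abs = psi · mu_a,ps                   [hv cm⁻³]
    mu_a,ps = ln(10) · eps · C              [cm⁻¹]

with CODATA 2018 `h` and `c`.  Note the printed reference value for
20 J cm⁻² at 530 nm (5.334×10¹⁹ hv cm⁻²) differs from the full-precision
result (5.336×10¹⁹) by < 0.05%; conversions are therefore checked at
0.5% slack.

Published absorbed-photon figures do not always state whether the
decadic→natural factor ln(10) is included in `mu_a,ps`.  Both conventions
yield assay-range implied LD50 concentrations here (≈23 vs ≈53 nM
Rutherrin; ≈0.33 vs ≈0.75 mM ALA), so the factor is a `natural_log`
switch (default True, standard Beer–Lambert) rather than a silent
choice.

## Dose–response

Percent kill is anchored on in-plate controls,
`kill% = 100·(1 − (v − mean_kill)/(mean_solvent − mean_kill))`, clipped
to [0, 100].  The four-parameter logistic is fitted on log₁₀
concentration with free asymptotes (assay floors and ceilings drift);
LD50 is the concentration at the midpoint of the fitted asymptotes.
Zero-concentration wells inform normalization but are excluded from the
log-dose fit.  LD50 uncertainty propagates to photon units by the
first-order delta method (the conversion is linear in concentration); a
bootstrap cross-check is exercised in the tests.  For ALA the
administered LD50 is divided by the 8:1 precursor stoichiometry,
assuming complete conversion to PpIX — no synthesis kinetics are
modeled, so the PpIX dose axis inherits that assumption.

## Light transport

Two routes, both for an ideal isotropic point emitter (the clinical
0.85 mm diffuser is not given finite extent):

- **Diffusion**: `phi(r) = P exp(−mu_eff r)/(4π D r)` with
  `D = 1/(3(mu_a+mu_s'))`, `mu_eff = sqrt(3 mu_a (mu_a+mu_s'))`; valid a
  few transport mean free paths from the source in high-albedo tissue.
- **Voxel Monte Carlo** (numba kernel): exponential steps `−ln(ξ)/mu_t`
  with the optics of the packet's current voxel, deposition
  `w·mu_a/mu_t` at the landing voxel, Henyey–Greenstein scattering,
  Russian roulette below weight 10⁻⁴ (survival probability 0.1, exact
  weight bookkeeping).  Fluence is the absorption estimator
  `deposited/(mu_a·V_voxel)`.  The random stream is an explicit PCG32
  generator seeded per run, so identical seeds reproduce fields bit for
  bit on any platform.  Grid boundaries are index-matched (escaping
  packets are lost); a step that crosses a tissue interface samples its
  length from the starting voxel's optics only, a first-order treatment
  adequate for the mildly heterogeneous gray/white/tumor phantoms used
  here.  Benchmarks against the diffusion form use grids whose edge lies
  several penetration depths beyond the region of interest, since a
  finite absorbing boundary genuinely depresses fluence relative to the
  infinite-medium solution.

Default voxel pitch is 0.2 mm (matching resampled small-animal MRI);
the transport benchmarks use 0.5 mm to keep suite runtimes at desk
scale, which only coarsens radial averaging below r ≈ 2 mm.

## Thresholds and selectivity

The threshold at an observed boundary radius `r_b` is
`T = phi(r_b)·t/E_photon · mu_a,ps(C_tissue)`.  Tissue concentrations in
µg/g convert to molar assuming density 1 g mL⁻¹.  Cohorts aggregate as
unweighted mean ± sample sd.  When the entire target is necrosed the
minimum enhancement distance gives the conservative upper-bound
threshold; this is the default boundary, with the maximum-distance
(lower-bound) variant selectable.  Homogeneous diffusion is the default
transport for threshold work; the Monte Carlo route (radially averaged,
log-interpolated) is available for heterogeneous phantoms.  Inversion
(`predict_necrosis_radius`) brackets the unique root of the monotone
absorbed-density profile and bisects to 1 µm.

Selectivity uses the heuristic that each factor of 3 in the specific
uptake ratio provides one effective penetration depth (`1/mu_eff`) of
selective margin: `depths = log3(SUR)` (20 → 2.73, 10.6 → 2.15).

The shipped per-tissue optics are **placeholders** consistent with the
quoted penetration depths (gray ≈ 1.0 cm and white ≈ 0.54 cm at 808 nm;
gray ≈ 0.84 cm and white ≈ 0.36 cm at 635 nm) because the study's own
optical-property tables and in vivo photosensitizer concentrations are
unpublished.  Likewise the in vivo tissue-concentration defaults
(tumor TLD1433 5 µg/g with ε₈₀₈ = 50 M⁻¹ cm⁻¹; tumor PpIX 1 µg/g) were
chosen once so that forward-modeled necrosis radii land at rat-brain
(millimeter) scale.  Consequently the *absolute* in vivo thresholds are
treated as generator truths to be recovered from synthetic cohorts, and
only the tissue-sensitivity ordering (normal brain threshold below
tumor threshold) is asserted as a result.

## Biodistribution

ICP-MS ppb (µg Ru per L of digest) × 2 mL digest volume gives Ru mass;
multiplying by MW(TLD1433)/AM(Ru) = 1007/101.07 gives drug mass (one Ru
atom per molecule; the ¹⁰¹Ru isotope mass, 0.16% lower, is switchable).
SUR is the ratio of group-mean concentrations and is invariant to the
concentration unit and to any common calibration scale.  Groups with
fewer than three animals are flagged; an all-zero reference group
returns an explicit "absent" sentinel (complete absence of drug in
normal tissue) instead of a division result, and an empty reference
group returns "undefined".

## Survival

Kaplan–Meier with Greenwood variance and the two-arm Mantel–Cox
log-rank ((O−E)²/V against χ²(1)) are implemented from their defining
formulas; an established survival library serves only as a cross-check
in the tests.  Ties: deaths precede censorings at equal times.  The
median is the first event time with S(t) ≤ 0.5 (an exact 0.5 reports
that time, which is how half-day medians arise with even n).  Zero
total variance returns an "undefined" sentinel.  Pairwise comparisons
are reported unadjusted, with Holm adjustment available but off by
default.  Note the chi-square reference is asymptotic: at n = 8 per arm
the empirical type-I error of this (or any standard) implementation is
≈ 0.066, so calibration checks run at n = 20 per arm, where it is
≈ 0.055.

## Synthetic-data generator

Every generator is a pure function of (design, seed) via a dedicated
PCG64 stream; regenerating with the stored seed is bit-identical, and
all tables round-trip losslessly through the CSV readers.

- **Plates**: viability = 4PL truth + Gaussian noise (sd 0.05 of the
  viability scale, i.e. 5% assay noise), clipped at 0, with 6 solvent
  and 6 kill-control wells; concentration grids are two-fold dilutions
  from 500 nM (Rutherrin) and 6000 µM (ALA); true LD50s are the
  concentrations implied by inverting the reference absorbed-photon
  LD50s; Hill slope 1.5 (typical of these assays).
- **Uptake**: lognormal per-tissue concentrations (15% CV), tumor mean
  20 µg/g with SUR 20 at 4/24 h and 12 at 48 h against both reference
  tissues, n = 3 per (timepoint × dose) group, lognormal tissue masses
  (0.1 g, 20% CV); an `absent_probability` exercises the sentinel path.
- **Boundaries**: forward threshold model plus 5% multiplicative radius
  jitter, n = 6 animals per condition.
- **Survival**: arms at medians 4.5 / 8.5 / 12.5 days, n = 8.  The
  default family is Weibull with shape k = 3 (CV ≈ 0.36): rodent glioma
  survival clusters tightly around its median, and arms this size only
  separate significantly — as the modeled study's did — when dispersion
  is well below exponential (CV = 1).  Under the Weibull default the
  4.5 vs 12.5 day comparison has log-rank power ≈ 1.0 at n = 8; under
  an exponential family (selectable) it would be ≈ 0.5.  Exponential
  arms are still used where memorylessness itself is wanted (the
  type-I-error null).

What passing tests on these synthetic data do **not** show: recovery of
the real study's numbers from its raw data (unpublished), correctness of
the placeholder optics/concentrations, PpIX photobleaching or oxygen
depletion during treatment (neither is modeled), ALA→PpIX conversion
kinetics, or finite-diffuser geometry effects near the source.

## Numerical choices

- Root finding: bracketed Brent to 1 µm (tighter on demand); a
  threshold above the near-source maximum returns radius 0, not an
  error.
- 4PL fitting: Levenberg–Marquardt from a monotone-interpolation
  midpoint guess; non-convergence and flat responses raise typed
  errors; fits with bottom > top are re-expressed with the asymptotes
  ordered and the slope sign flipped.
- Exposure times are kept at full precision internally and rounded to
  whole seconds only for display.
- Monte Carlo weight accounting (absorbed + escaped + roulette-killed −
  roulette-boosted = launched) is verified to 10⁻⁶ relative and
  typically closes at ~10⁻¹⁰.
- Problem sizes: transport benchmarks use 10⁶ packets on an 81³ grid;
  recovery studies use 200 seeds (plates, thresholds), 500 seeds (SUR,
  power) and 2000 null simulations — sizes at which the Monte Carlo
  error of each check is well below its decision margin.
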