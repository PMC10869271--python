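# Methods

This note documents the models and procedures `phagekit` implements, the
parameter choices that matter, what the synthetic-data generators emulate,
and the numerical decisions taken where the design was genuinely open.

## Growth-kinetics inhibition scoring (iAUC)

The input is a cumulative redox-dye signal per well (strain × agent pair),
nominally sampled every 0.25 h over 24 h. The score is computed in four
steps:

1. **Spline smoothing.** A penalized cubic smoothing spline minimizing
   `weight · Σᵢ (yᵢ − f(tᵢ))² + (1 − ρ) · ∫ f″(t)² dt` is fitted for every
   (ρ, weight) pair on the grid {0.1, 0.2, 0.3, 0.4, 0.5}², and the fit
   with the lowest mean absolute error against the raw signal is kept.
   Both knobs move the fit along the same fidelity-versus-curvature axis
   (only the ratio (1 − ρ)/weight matters for a uniform weight vector);
   the grid is retained as specified because the selection rule — lowest
   MAE — is defined over exactly those 25 candidates. The original
   fitter's exact parameterization of "weight" is not recoverable, so this
   standard penalized form was chosen; swapping in an alternative mapping
   is a one-line change in `kinetics.fit_smoothing_spline`. The solve is
   delegated to `scipy.interpolate.make_smoothing_spline` (which requires
   ≥ 5 points; a series with exactly 4 distinct timepoints falls back to
   the natural interpolating cubic, the ρ → 1 limit; fewer than 4 distinct
   timepoints is an error).
2. **Baseline removal.** The mean fitted signal over t ≤ 1.5 h (inclusive)
   is subtracted from the whole curve. Wells differ slightly in their
   initial dye load, which would otherwise inflate areas; the first 1.5 h
   precede measurable growth. Negative values are allowed.
3. **Area.** Riemann midpoint sums over consecutive sampling intervals.
   On sampled values the midpoint value is the mean of the two adjacent
   samples, making the rule coincide with the trapezoid rule — exact for
   piecewise-linear curves; when a callable fit is supplied, it is
   evaluated at the interval midpoints instead.
4. **Score.** `iAUC = 1 − AUC_sample / AUC_control`, where the control is
   the bacteria-only well of the same strain and replicate. Values outside
   [0, 1] (noise) are passed through unclipped. A control whose
   baseline-zeroed area is not positive (a non-growing control) is an
   error, detected with a scale-aware tolerance because a perfectly flat
   control's area is pure floating-point jitter.

**Susceptibility threshold.** Susceptible ⇔ iAUC ≥ 0.2, inclusive. The
source protocol states the threshold in three places with inconsistent
strictness/direction ("≥ 0.2" for susceptibility, "< 0.2" for host range,
"above 0.2" for complementarity — these cannot all hold simultaneously);
this package standardizes on **susceptible ⇔ iAUC ≥ 0.2** everywhere.

**Tie-breaking.** Grid selection ties resolve to the smallest ρ, then
smallest weight. MAEs within a small scale-relative tolerance (1e-8 of the
mean absolute signal) of the minimum count as ties, so a noiseless linear
series deterministically selects (0.1, 0.1) instead of whichever corner
wins by 1e-13.

## Host-range matrices and panel statistics

A `SusceptibilityMatrix` stores per-replicate boolean calls (and, for
plaquing data, the categorical outcome) for every strain × agent cell;
absent cells are masked and excluded from all denominators.

* **Plaquing outcomes** are ordered plaque > lysis zone > no effect; both
  plaque and lysis zone count as susceptible. The *conservative consensus*
  of two runs is the outcome with the lower plaquing efficiency under that
  ordering (a meet operation: idempotent, commutative, never above either
  input).
* **Host range** = per-replicate susceptible fraction, averaged. The
  reported dispersion follows the counts-then-normalize convention: s.d.
  of the per-replicate susceptible *counts*, divided by the panel size.
  A single replicate reports s.d. 0 (rather than undefined) so downstream
  tables never contain missing dispersion.
* **Category fractions** take each strain's best outcome across the agent
  subset (mutually exclusive plaque / lysis / no-effect categories),
  average the percentages over replicates; coverage% = plaque% + lysis%.
* **Resistance phenotypes** from MIC tables (mg/l): ESBL iff any of
  ceftriaxone/ceftazidime/aztreonam ≥ 2 (inclusive); carbapenem resistance
  iff any of imipenem/doripenem/meropenem > 2 (strict); FQR by a
  CLSI-style ciprofloxacin ≥ 1 or levofloxacin ≥ 2 default; MDR by the
  standard non-susceptible-in-≥3-classes convention with CLSI-style class
  breakpoints. FQR and MDR are conventions chosen here (the phenotypes are
  named but not defined in the source protocol) and are config-exposed.
  Raising a MIC never removes a flag.
* **Stratified coverage** restricts union-rule coverage to one resistance
  flag or phylogroup and reports integer susceptible/resistant counts
  (a strain counts as susceptible when covered in at least one replicate).
* **Redundancy distribution**: fraction of strains hit by ≥ k agents for
  k = 0..|subset|, per replicate then averaged; the k = 1 value equals the
  union coverage and the sequence is nonincreasing.

## Cocktail design

* **Union rule.** A combination inhibits a strain iff at least one member
  does. Combination coverage is computed per replicate and then averaged,
  mirroring host range (the ordering of union versus averaging is a
  convention; this one keeps singleton combinations exactly equal to
  single-agent host range).
* **Ancestor exclusion.** No combination may contain two agents derived
  from the same wild-type phage. Engineered derivatives have nearly
  identical inhibitory profiles; allowing them together would make a
  candidate's marginal gain unfairly low (its twin is already in the base)
  or unfairly high (the base is internally redundant).
* **Marginal host range** of candidate c over admissible base B:
  coverage(B ∪ {c}) − coverage(B). Default bases are all admissible
  combinations of sizes 1..(n−1) over the candidate set; the sizes are
  config-exposed because no canonical choice exists.
* **Mode utility.** The mode of each candidate's marginal distribution is
  the argmax of a Gaussian KDE evaluated on a 512-point grid spanning
  [min − 3h, max + 3h]. The bandwidth h follows Silverman's rule of thumb
  (the nrd0 default of R's `density()`, 0.9·min(sd, IQR/1.349)·n^(−1/5)),
  since the mode was originally located with that function's defaults.
  Zero-spread distributions return the common value directly. Ranking is
  by mode descending, ties broken by mean marginal, then label, so reports
  are byte-reproducible regardless of input order.
* **Cocktail selection** walks the ranking greedily, skipping candidates
  whose ancestor is already represented, until the requested size is
  reached. Exact set-cover optimization is deliberately out of scope; the
  ranking is a screening heuristic and final selection is left to the
  user.
* **Additive in-vivo prediction**: the predicted effect of a combination
  is the sum of its members' individual log₁₀ CFU/g reductions versus
  vehicle.

## Assay arithmetic

* Titer = count / (spot volume × 10^−d) for a spot of a 10^−d dilution;
  zero counts are left-censored at the configured LOD (defaults surfaced
  in `RunConfig`: 33 PFU/g for phage in feces, 371 CFU/g for bacteria in
  mouse feces, 200 CFU/ml for conjugation assays).
* EoP = titer_test / titer_reference. No plaque formation → *resistant*;
  plaques with a log₁₀ drop strictly > 1 → *reduced*; otherwise
  *sensitive*. No upper edge is imposed on "reduced" (the boundary
  phrasing ">1–2 log10" is ambiguous about it, so anything with plaques
  more than 10× below reference is reduced).
* Transduction frequency = transductants / lysate titer; zero
  transductants give the censored bound < 1/titer.
* Log-scale summaries follow the convention of averaging after log₁₀
  transformation; the back-transformed mean is the geometric mean.
  Censored values are imputed at their detection bound (not bound/2) and
  flagged, matching the practice of plotting censored points on the LOD
  line.
* **Competition calibration.** The band-intensity model is
  r = α(1 − f)/f, where f is the engineered-phage fraction and r the
  measured wild-type/engineered band-intensity ratio — band intensity
  proportional to template amount with a per-amplicon efficiency α. The
  source protocol says only that "a curve" was fitted; this physical
  single-parameter form was chosen and is fitted by least squares on
  log r (variance-stabilizing for multiplicative densitometry noise),
  giving the closed form log α = mean(log r − log((1−f)/f)). The inverse
  f = α/(α + r) maps measured ratios to fractions. The model is isolated
  behind `fit_competition_calibration` and swappable.

## Synthetic data: what it emulates, and what it does not

All generators take a seed and are byte-deterministic given it.

* **Growth curves**: cumulative logistic dye signal
  baseline + (1 − λ)·A/(1 + e^(−k(t − t_mid))) with additive Gaussian
  noise, sampled every 0.25 h over 24 h. Defaults: amplitude 200 units,
  rate 0.8 h⁻¹, midpoint 8 h, baseline 20 units, noise s.d. 5% of
  amplitude — a realistic signal-to-noise for microplate redox reads.
  Inhibition λ ∈ [0, 1] scales the amplitude only. The logistic was chosen
  over Gompertz as the simplest monotone sigmoid consistent with a
  cumulative signal. **Not modelled**: lysis crashes (phage-induced signal
  collapse mid-curve), diauxic shifts, plate-edge effects, well-to-well
  drift. Passing recovery tests therefore show the scoring machinery is
  correct for monotone curves, not that it classifies crash-shaped curves.
* **Panels**: per-strain phylogroup labels drawn from configurable weights
  (default B2-heavy, as in clinical bloodstream panels), per-agent
  per-phylogroup susceptibility probabilities, and same-ancestor agents
  emulated as copies of the sibling profile with a small symmetric flip
  probability. Observed plaquing replicates apply hit→miss and miss→hit
  misclassification and a plaque-versus-lysis-zone split.
* **Planted ranking panels**: four orthogonal block profiles (each planted
  agent fully covers its own quarter of the panel) plus decoy derivatives
  that inherit a planted agent's host set and lose each host with
  probability 0.25 (at least one host always lost). The subset constraint
  reflects receptor-specificity inheritance: an engineered derivative does
  not gain hosts its ancestor lacks. Under a symmetric flip model decoys
  would frequently *gain* unrelated hosts and legitimately outrank the
  planted agents, which tests nothing about the ranking; the degradation
  model makes the planted agents the true optimum the ranking should
  recover.
* **Competition mixtures**: r = α(1 − f)/f with multiplicative log-normal
  noise (default log-scale s.d. 0.1, consistent with the assay's stated
  < 20% error).
* **In-vivo counts**: per-animal log-normal CFU/g, left-censored at the
  LOD.

## Problem sizes and numerical choices

Test and acceptance runs use panels of 40–72 strains, 4–11 agents, 200
simulated wells (40 strains × 5 inhibition levels), 50 seeded ranking
panels and 500 competition draws — sizes at which the brute-force oracles
(exhaustive subset enumeration, fine-grid quadrature and KDE scans) remain
exact and fast while exercising every code path. Degenerate inputs are
handled explicitly: empty score sets build empty matrices; empty
combinations cover nothing; single-value marginal distributions return
their value as the mode; single-replicate dispersions are 0; flat controls
raise rather than divide by jitter.

## Known limitations

* The iAUC pipeline assumes a monotone cumulative signal; instruments
  reporting instantaneous (non-cumulative) optical density need their own
  curve template.
* The marginal-mode ranking is a screening heuristic; it does not optimize
  coverage subject to cardinality and can be indifferent between a
  candidate and a barely-degraded derivative of another.
* MDR/FQR breakpoint defaults are conventions and should be overridden
  when a study defines its own.
* The competition calibration assumes a single shared amplification
  efficiency α across mixtures; strongly nonlinear densitometry would need
  the documented model swap.
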