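# Methods

## Setting and model

The package analyses a paired diagnostic design: every patient in a
re-biopsy cohort has all triage tests (PSA density, mpMRI, PSMA-PET) and
a reference-standard fusion biopsy, so *any* binary referral rule can be
evaluated retrospectively on the same patients.  Clinically significant
prostate cancer (csPCa) is ISUP grade group ≥ 2; ISUP 0 encodes a
negative biopsy and ISUP 1 insignificant cancer.  A triage strategy is a
deterministic predicate over a patient record; the six built-ins are
biopsy-all, PSAD > 0.15 ng/mL/cc (strict inequality — a value of exactly
0.15 is not referred), PI-RADS ≥ 3, PRIMARY ≥ 3, their OR, and
PSAD-AND-mpMRI.  A rule that consults a missing imaging score treats it
as negative and logs a warning; this is conservative and the reference
fixture contains no missing values.

## Cost allocation

Unit costs (EUR): PSA 1.55, mpMRI 283.50, PSMA-PET 938.00, fusion biopsy
809.40, pathology 81.80.  All arithmetic is in integer euro-cents;
rounding to whole EUR (half away from zero) happens only at display
time.  Under **stepwise** allocation every patient incurs one PSA assay;
single-test strategies image everyone with their own modality; the OR
strategy images everyone with mpMRI and bills PET only for
mpMRI-negative / PET-positive patients (the stated accounting rule —
operationally one cannot know PET is positive before scanning, so this
is an accounting convention, not a care pathway); the AND strategy bills
mpMRI only for PSAD-elevated patients.  Every referred patient incurs
one biopsy plus exactly one pathology exam.  **Universal** allocation
bills every test a strategy consults for every patient and therefore
never costs less than stepwise; it is strictly costlier exactly for the
two combination strategies, whose stepwise path skips scans.

The PSA assay is billed once per patient by default.  Enrolment
protocols may require repeated PSA measurements, but the strategy totals
reconcile to the cent only with one assay per patient; the multiplier is
a config knob (`psa_multiplier`) and a warning is logged when it is not 1.

## Incremental comparison

With mpMRI triage as the default reference (overridable), each strategy
gets ΔE (csPCa detected, candidate − reference), ΔC (difference of the
two arms' *whole-EUR-rounded* totals — the convention under which the
reported tables are internally consistent; the cent-exact difference is
carried alongside), and:

- ICER = ΔC/ΔE when ΔE > 0 (dominant if also ΔC ≤ 0).  ΔE = 0 yields no
  ratio: the status is `no_delta_effect` when cost-saving (we do not
  label an equally effective, cheaper strategy "dominated") and
  `dominated` when costlier.  ΔE < 0 is `less_effective`, with no ratio
  reported — a ratio of a saving over forgone detections invites
  misreading.
- INB(λ) = (ΔE·λ − ΔC)/n per patient, for λ on a strictly increasing WTP
  grid (default 5,000 / 10,000 / 20,000 EUR per detected csPCa).  INB is
  affine in λ, so equal-detection strategies have WTP-constant INB.  The
  cohort-total INB is also emitted; per-patient is the headline.

## Uncertainty

Two tiers, deliberately kept distinct:

**Analytic, "approximate, as published".**  The effect difference gets a
two-arm binomial SE at the pooled prevalence p on the same n, scaled to
counts: SE(ΔE) = √(2·p·(1−p)·n) ≈ 6.45 cases at p = 0.2, n = 130.  Arm
costs get SE = CV·total with CV defaulting to 0.175 (midpoint of the
15–20% range typical of diagnostic costing studies), combined in
quadrature unless a covariance is supplied.  These SEs ignore the
paired design's between-arm correlation, which is why the bootstrap is
the preferred estimator.

The ICER interval uses Fieller's theorem: the roots of
(ΔE² − z²·se_E²)·R² − 2(ΔE·ΔC − z²·cov)·R + (ΔC² − z²·se_C²) = 0.
When ΔE² ≤ z²·se_E² the effect is indistinguishable from zero and the
confidence set is unbounded; the implementation reports the branch
containing the point ratio with an infinite endpoint (whole real line
when the roots are complex), and collapses to the point when all SEs are
zero.  When the denominator is bounded well away from zero the Fieller
endpoints coincide with the quantiles of the ratio of the bivariate
normal, which is the Monte-Carlo oracle used in the tests.

The INB interval is the delta method: SE_INB = √(se_C² + (λ·se_E)² ±
2·λ·cov), symmetric around the per-patient point after division by n.
The sign of the covariance term is convention-dependent (the variance
algebra of λ·ΔE − ΔC puts a minus on cov(ΔC, ΔE)); both conventions are
available via `cov_sign`, default the `+` form, and a negative radicand
raises an error naming the offending covariance.  Published interval
endpoints for such analyses depend on the unstated CV/covariance pair,
so the package checks interval *behaviour* (boundedness, ordering,
collapse) rather than endpoint values.

**Paired bootstrap.**  Patients are resampled with replacement and both
strategies are re-evaluated on each replicate cohort, preserving
within-patient correlation — the two-arm reformatting of a paired
design.  Per replicate the per-patient cost ledgers (which sum exactly
to the utilization totals, a tested invariant) give ΔE, ΔC and INB per
WTP; percentile intervals and CEAC(λ) = fraction of replicates with
INB > 0 follow.  Replicates with ΔE = 0 contribute no ICER draw; their
proportion is reported.  The RNG is `numpy.random.default_rng(seed)`;
identical seed and B give bit-identical output, and the seed is recorded
in every report.

## Synthetic cohorts

`fixture_cohort()` is the package's deterministic reference cohort:
130 patients, 26 csPCa (prevalence 0.2), built so that all six
strategies' (biopsied, detected) margins hold simultaneously —
(130, 26), (61, 17), (34, 17), (25, 18), (42, 22), (20, 12).  The
margins fix the mpMRI×PET joint distribution by inclusion–exclusion
(csPCa: both 13, MRI-only 4, PET-only 5, neither 4; benign: 4/13/3/84);
cells the margins do not determine (which individual carries elevated
PSAD) are completed greedily in a canonical patient order — any
consistent completion reproduces every margin, so the choice is free but
frozen for bit-stability.  PSAD values come from fixed cycles keeping a
≥ 0.01 margin from the 0.15 threshold; ISUP grades for csPCa cycle over
{2, 3, 4, 5} (the grade beyond the ≥ 2 threshold affects nothing).  A
margin self-check runs on every build.

`simulate_cohort(n, spec, seed)` draws disease status Bernoulli(prev),
then mpMRI/PET positivity jointly within each status stratum with a
correlation-style dependence parameter (default ρ = 0.25, the magnitude
implied by the fixture's joint cells; infeasible ρ raises with the
feasible range), PSAD positivity conditionally independent given status,
and a continuous PSAD from two families strictly straddling the
threshold.  What it emulates: marginal accuracies and the MRI–PET
dependence.  What it does not: PSAD–imaging dependence (conditional
independence given status), PSA kinetics, volume, age, or any covariate
the six rules do not consult — so passing simulation tests says nothing
about those structures in real data.

## Problem sizes and numerical choices

Tests run the full 130-patient pipeline (fast and exact); the bootstrap
checks use B = 2,000 on the fixture and, for coverage, 500 simulated
cohorts × B = 500, where 95% percentile intervals cover the closed-form
population INB of the OR-vs-mpMRI contrast at ~92–95% — the mild
undercoverage typical of percentile intervals at n = 130.  The Fieller
oracle uses 20 random bounded configurations against 10⁶-draw
Monte-Carlo ratio quantiles, agreeing within 1% of interval width.
Display conventions: EUR rounded half-away-from-zero; NNT shown to one
decimal; European dotted-thousands formatting behind `--locale eu`.

## Limitations

No QALY or long-term outcome modelling (the endpoint is detection); no
efficiency frontier across >2 strategies simultaneously; costs are
single-institution tariffs with no discounting or societal perspective;
the analytic SEs are the published approximations, not estimators of the
paired design's true sampling variance.
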