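# Methods

## The screen in one paragraph

`radgut` models a panel screen for natural variants that modulate
radiation-induced intestinal permeability in *Drosophila*. A panel of fully
inbred (homozygous) lines — the DGRP design, ~156 lines — is phenotyped with
the Smurf gut-permeability assay in paired conditions, 0 Gy and 100 Gy, with
on the order of 100 flies per line and condition. For every biallelic marker
with minor-allele frequency above 25%, the per-line Smurf proportion is fit
by ordinary least squares to

    phenotype = β0 + β1·Genotype + β2·Dose + β3·Genotype·Dose

and the genotype × dose interaction β3 — the irradiation-dependent part of
the genetic influence — is tested against zero with a two-sided t test on
n − 4 degrees of freedom. Significance is summarized by a permutation-based
empirical false-discovery rate, and markers at FDR ≤ 27% (or ≤ 25%; both are
presets) form the candidate shortlist. A companion scanner counts Musashi
Binding Elements (MBEs) in 3′UTRs and shortlists genes with ≥ 4 sites, the
rule used to nominate Musashi targets such as Ac13E.

## Model and assumptions

* **Genotype coding.** Lines are homozygous, so each marker carries a single
  0/1 call per line (0 = major, 1 = minor); there are no heterozygotes. The
  file's orientation is trusted, but the scan re-checks the empirical call-1
  frequency among phenotyped lines and re-orients (with a warning, and a
  per-marker flag in the result) when it exceeds 50% — line filtering can
  legitimately change which allele is minor. `ScanResult.oriented_params()`
  returns coefficients re-expressed in the input coding for effect-size
  comparisons.
* **Dose coding.** `binary` (default) codes any positive dose as 1. With the
  screen's two dose levels this is the raw-Gy coding up to a scale factor on
  β2/β3; the `gray` option keeps raw Gy for staggered-dose designs.
* **Response.** The raw per-line Smurf proportion (vials pooled) by default;
  a logit option uses log((s+0.5)/(n−s+0.5)), the Haldane–Anscombe
  correction, so all-Smurf and no-Smurf records stay finite. Per-vial
  observations are a flag.
* **No structure correction.** No kinship, inversion, or *Wolbachia*
  covariates and no mixed model — the fitted model is exactly the
  four-parameter OLS above. This is a deliberate fidelity choice and a known
  limitation: with related lines the test would be anticonservative.
* **MAF filter.** Strictly greater than `maf_min` (default 0.25), computed
  among non-missing calls; missing calls are dropped per marker at fit time,
  not globally.

The per-marker fit is computed in closed form from the normal equations,
assembled for all markers at once from per-line sufficient statistics (one
pass of matrix products), so a 2,000-marker × 156-line scan takes
milliseconds and permutation FDR at B = 50–1,000 is practical on a laptop.
Degenerate fits are flagged rather than guessed at: rank-deficient designs
(e.g. monomorphic after dropping missing calls, or fewer than
`min_lines_per_cell` lines on either side of the allele split) get NaN
coefficients and are excluded from ranking; zero-residual fits keep their
exact coefficients but an undefined p.

## Permutation FDR

The null is built by re-running the *entire* scan on phenotype tables whose
line labels are permuted as whole blocks: a line's complete record set (both
doses, all vials) moves together. Block permutation preserves the dose main
effect and the within-line pairing while severing every genotype–phenotype
link, which is what makes the null valid for the interaction term
specifically. Null p-values are pooled across markers within each
permutation (one panel-wide null), matching a single FDR% per marker:

    raw_fdr(p) = [ (1/B) Σ_b #{null p ≤ p} ] / max(1, #{observed p ≤ p})
    q(p)       = min over thresholds p' ≥ p of raw_fdr(p'),  capped at 1

The `max(1, ·)` guard avoids 0/0 at the most extreme threshold; the running
minimum makes q a valid step-up quantity, non-decreasing in p. The MAF
filter is genotype-only and therefore permutation-invariant, so it is
applied once to the observed data. B = 100 is the desk-scale default; FDR
quoted to 1% resolution wants B ≥ 1,000.

Under a global null, every call at q ≤ γ is a false discovery, so the
realized false-discovery proportion of a replicate is 1 if it makes any call
and 0 otherwise, and the quantity the procedure controls is
E[FDP] = P(at least one call) ≤ γ. The calibration tests check exactly this
(measured ≈ 0.20 at γ = 0.25 over 20 replicates).

## Synthetic data: what it emulates and what it does not

`SimConfig` defaults are the screen's study conditions: 156 lines, 4 vials
of 25 flies per line and condition, doses (0, 100) Gy. Where the design
fixes no number the defaults are documented choices, made once:

| parameter | default | meaning / rationale |
|---|---|---|
| `maf_range` | (0.05, 0.5) | uniform MAF spectrum; the scan's filter then thins realistically |
| `baseline_p` | 0.05 | control-arm Smurf incidence of a few percent |
| `dose_effect` | +0.15 | irradiated lines average ~20% Smurfs |
| `line_sd` | 0.05 | Gaussian per-line effect on the proportion scale; a loose calibration to the observed between-line spread, not a fit |
| `scale` | proportion | the regression response is the raw proportion; `logit` optional |
| `causal_maf_range` | None | when set, planted causal markers draw their MAF from this sub-range (e.g. (0.4, 0.5)) so a planted effect cannot be silently removed by the >25% MAF filter |

Phenotypes are generated by the same linear structure the scan fits, plus a
line-level Gaussian random effect shared across doses, then binomial
sampling per vial. On the proportion scale, out-of-range latent values are
clamped to [0, 1] and *counted* (`SimTruth.n_clamped`) rather than silently
resampled; on the logit scale no clamping can occur. One seed drives
everything; per-stage sub-streams are derived deterministically so the panel
draw is unchanged when only phenotypes are regenerated.

Deliberately **not** modeled: linkage disequilibrium, population structure,
inversion/*Wolbachia* covariates, overdispersion beyond the line effect, and
dose–response nonlinearity. Passing tests therefore demonstrate that the
machinery is correct and calibrated under the stated generative model — not
that a real DGRP screen is free of confounding from the features the model
omits.

UTR fixtures are uniform-random RNA with motif realizations inserted at
non-overlapping positions; the whole sequence is rejected and redrawn unless
the scanner's count equals the target exactly, so truth counts are exact by
construction (accidental matches, including across insertion junctions, are
excluded). Lifespans come from exponential or Gompertz laws with optional
right-censoring at a study-end day.

## MBE scanning

RBPmap's Musashi scoring matrix belongs to the web service, so the scanner's
default is the literature consensus MBE, (G/A)U(1–3)AGU, expressed as the
configurable pattern `[GA]U{1,3}AGU` on the RNA alphabet. DNA input is
normalized T→U; N never matches; the sense strand only is scanned (3′UTRs
are sense-strand by contract — reverse-complement matching is *not* motif
count-invariant and is never applied implicitly). Counting is greedy
left-to-right without overlap by default, since "n repeats" means n distinct
elements; an all-overlapping mode (one longest match per start) is
available and always counts at least as many. A log-odds PWM mode accepts a
user-supplied matrix and threshold. Reported intervals are 1-based closed;
BED export converts to 0-based half-open. Because the consensus stands in
for a proprietary scoring model, gene-level shortlists from real UTR sets
should be read as consensus-site counts, not as a reproduction of RBPmap
output.

## Phenotype statistics

The vial is the unit of replication: Smurf means, SDs and t tests are
computed across vial proportions, never across individual flies. The default
two-sample test is Welch's (the unequal-variance form, Satterthwaite df),
with pooled-variance as a flag; tests are run on raw proportions by default
(a transform is available, as published analyses rarely state which was
used). Survival uses the product-limit (Kaplan–Meier) estimator with
right-censoring and the one-degree-of-freedom log-rank test (both via
lifelines behind this module's interface); the reported median is the first
time with S(t) ≤ 0.5 and is undefined (NaN) when the curve never reaches
it. qPCR fold changes are 2^−ΔΔCt with per-condition normalization to a
reference gene (rp49 in the motivating assays), which makes the fold
invariant to global Ct shifts and to reference shifts shared by both
conditions.

## Numerical choices

* Ties in the significance ranking break by (p, chromosome, position) for
  stable output.
* Residual variance below 1e−12 of the response scale counts as exactly
  zero (degenerate fit, p undefined).
* Scan-result TSVs print floats with 17 significant digits so
  write-then-read is the identity on every numeric field.
* Empirical FDR uses sorted-array bisection; adding one permutation can
  move any raw FDR by at most M/((B+1)·denominator).

## Validation problem sizes

The test suite validates calibration at the screen's scale: global-null
calibration uses 2,000 markers × 156 lines × 20 replicates (KS uniformity
and type-I error within 3 binomial SE); FDR calibration uses B = 50 over 20
replicates; effect recovery uses 200 replicates with redrawn panels (a fixed
panel would leave a systematic cross-marker leakage term in per-marker β̂3);
shortlist power uses 100 replicates. The planted interaction effect for the
power experiment, +0.12 on the proportion scale at MAF 0.4–0.5, was chosen
analytically from the standard error of β̂3 under the generative model so
that per-marker power at the FDR-27% threshold is essentially 1; measured
joint recovery of all five planted markers is 93–97% of replicates. The
acceptance script (`scripts/acceptance.py`) re-runs the same designs at
slightly smaller replicate counts and prints every quantity it computes.

## Known limitations

* No mixed-model or kinship correction (faithful to the modeled screen).
* The empirical FDR is panel-wide, not marker-specific; Benjamini–Hochberg
  is intentionally not the primary output.
* The MBE consensus is a stand-in for a trained scoring model; counts on
  real UTRs are sensitive to the pattern chosen.
* The generator's binomial-plus-Gaussian noise model is a choice, surfaced
  in configuration, not a fitted description of real Smurf variance.
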