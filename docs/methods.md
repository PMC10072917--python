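# Methods

## Cause-of-death diversity

Deaths are classified into k mutually exclusive causes (default: the 21 GBD
level-2 causes, nested in 3 level-1 groups). The fractionalization index
F = 1 − Σ pᵢ² is computed on cause shares pᵢ of **life-table deaths**: the
death distribution d(x) of a period life table is split across causes within
each age group proportionally to the cause-specific rates (the standard
multi-decrement assumption, d(x,c) = d(x)·m(x,c)/m(x)), and shares are the
cause column sums. This removes the population's age structure from the
comparison; `fractionalization_observed` provides the uncorrected variant on
raw death counts. F is bounded by (k−1)/k, attained at the uniform
distribution, and any merging of causes (e.g. to level-1 groups via
`regroup`) can only decrease it — both facts are enforced by property tests.
Because F depends on the category count, cross-scheme comparisons should use
a fixed scheme; the regrouping operation supports sensitivity checks against
coarser schemes.

## Life tables, e0 and e†

Tables are built on the GBD abridged grid (<1, 1–4, then 5-year groups to an
open 95+ interval) from all-cause rates m(x), radix 1:

* q(x) = n·m / (1 + (n − a)·m) for closed intervals, capped at 1;
* a(x) = n/2 except the infant interval, where a₀ = 0.07 + 1.7·m₀ capped to
  [0.01, 0.35] (a conventional infant-separation approximation; configurable
  by swapping the `_nax` rule);
* open interval: q = 1, L = l/m (exponential closure), which is why the
  terminal rate must be strictly positive.

Life disparity is discretized as e† = Σₓ d(x)·ē(x) where, within each closed
interval, ē is the remaining expectancy evaluated at the mean age at death
x + a(x) with l and T linearly interpolated between tabulated boundaries;
deaths in the open interval carry e(ω), which is exact under the exponential
closure. This choice converges to the continuous ∫ d(x) e(x) dx on grid
refinement and is validated against a brute-force quadrature oracle at
1e-6 relative tolerance on a 0.05-year grid. On a single-year grid the
constant-hazard identities e₀ ≈ 1/μ and e† ≈ e₀ hold within 1–2%.

## Horiuchi decomposition

ΔF between two years is decomposed over covariates m(x,c) — cause-age
rates, not proportions, so the life table responds to every covariate. The
path between the endpoint grids is proportional (log-linear) per cell;
cells with a zero endpoint fall back to linear interpolation (the log path
is undefined there), and cells equal at both endpoints contribute exactly
zero. With n_steps segments (default 20), each covariate is stepped across
each segment with the others held at the segment midpoint. The midpoint-rule
residual — about 1e-5 in units of F at the default setting on synthetic
panels — is recorded and redistributed proportionally to absolute
contributions, so the matrix sums to ΔF exactly. Contributions at 20 vs 200
steps agree within 1e-4 (max norm) on synthetic panels, and reversing the
endpoints negates the matrix. The step count and residual policy are
configurable because the appropriate published defaults are conventions,
not identities.

## Uncertainty propagation

Each cell's (val, lower, upper) is resampled as a two-piece normal:
sd_low = (val − lower)/1.96 below the point, sd_high = (upper − val)/1.96
above it, truncated at zero — honouring the asymmetry of GBD-style
intervals; a symmetric-normal alternative is available. Cells are drawn
independently: cross-cell correlation of the underlying estimation process
is not recoverable from the intervals alone, and this assumption is the main
caveat on the envelope widths (positively correlated cells would widen
envelopes of sum-like statistics). Envelopes are empirical 2.5/97.5
percentiles over n_draws = 1000 by default. Significance of a difference
uses independent draw streams per panel, seeded from the run seed plus a
content hash of the panel so the verdict is invariant under argument order;
the flag fires when the central 95% interval of draw-wise differences
excludes zero. Calibration is verified by simulation: envelope coverage of
known synthetic truth within 90–98% over 200 replicates, and a null
rejection rate statistically compatible with 5%.

## Weighted LOESS

Local polynomial (degree 1 by default, span 0.75) weighted least squares at
each grid point, with weights tricube(d/h) × population, h the distance to
the ceil(span·n)-th nearest positively weighted point. Zero-weight points
are excluded from window counts; the grid never extends beyond the data
range (no extrapolation); fits reproduce straight lines exactly and agree
with a brute-force windowed WLS oracle to 1e-10. Span and degree are
conventional defaults — the analyses here are property-based, not
curve-shape reproductions — and both are exposed in the run config.
Curves are fitted per sex and per analysis year, for F against e₀ and
against e†.

## Synthetic panels

The generator emulates a stylized epidemiological transition on a
"transition clock" τ (years):

* communicable/maternal/neonatal/nutritional hazards are young-age
  concentrated (exp(−x/10) plus a small flat background) with overall level
  0.06·exp(−0.045·τ);
* non-communicable hazards are Gompertz, level 0.05 at age 80 with slope
  0.10/yr; the cardiovascular share is multiplied by a rise-and-fall factor
  1 + 1.3·exp(−((τ−45)/18)²);
* injuries are age-flat with a young-adult hump and a ×2.5 male multiplier.

These magnitudes were chosen once to give plausible transition dynamics —
e₀ rising monotonically from ≈40 to ≈70 years while F declines from ≈0.91
to ≈0.76 and rebounds to ≈0.83 — reproducing the qualitative
decline-then-rebound relationship between CoD diversity and life expectancy
that motivates the pipeline. Regions are offset along the clock (default
0–60 years across 7 regions) so a cross-section spans the transition;
countries get fixed per-cause lognormal jitter (sd 0.08), a ±3-year clock
offset and log-uniform populations between 10⁶ and 10⁸. Uncertainty bounds
are point × (1 ∓ width), width 5% by default; observed panels add relative
normal noise with sd = width/1.96 so the stated bounds are calibrated 95%
intervals for the truth.

What the generator does **not** emulate: real GBD magnitudes or cause
rankings, cause-age interactions beyond the three template shapes, HIV-like
epidemic shocks, migration or population age-structure feedback, and any
cross-cell correlation in the uncertainty. Passing tests therefore establish
internal correctness and calibration of the machinery, not agreement with
real-world GBD estimates.

## Pipeline conventions and numerical choices

* Regional rate grids are population-weighted means of member-country rates
  (age-specific population weights) built before life-table construction;
  pooling deaths and person-years is a defensible alternative and would
  differ only through within-region heterogeneity.
* Cause-fraction rows must sum to 1 within 1e-9 (opt-in renormalization);
  all-zero rows are tolerated only where the life table puts no deaths.
* Age groups with zero all-cause rates get zero cause fractions; the open
  interval requires a positive rate.
* Analysis scale: the shipped examples and tests use 2–7 regions × 1–3
  countries and 200-replicate calibration runs with 500 draws, sizes at
  which the full suite completes in about a minute on a laptop core while
  leaving Monte-Carlo error well inside the asserted bands.

## Known limitations

* Independence across cells in the uncertainty model (above).
* The e† discretization is one of several in use; alternatives differ at
  O(n²) within-interval terms and agree on fine grids.
* No cause-deleted (associated single-decrement) life tables, no smoothing
  or graduation of input rates, and no confidence bands on LOESS curves.
* Diversity indices other than fractionalization (entropy, Theil) are out
  of scope.
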