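# Methods

## Time use as a composition

A subject's waking day is summarized by minutes in four behaviors — MVPA,
HLPA, LLPA and SB — that partition accelerometer wear time. Dividing by wear
time yields a point on the 4-part simplex; all analyses operate on this
composition, so subjects who wore the monitor for different lengths of time
are comparable and "more of one behavior" necessarily means "less of the
others". Minute-scale results are displayed by re-closing proportions to the
cohort's mean wear time.

The package works in isometric log-ratio (ilr) coordinates
`z = B · log x`, with `B` a (D−1)×D matrix with orthonormal rows each
orthogonal to the ones vector. The default is the pivot basis (MVPA against
the geometric mean of the rest, then HLPA, then LLPA vs SB). The choice is
immaterial: any two valid bases differ by an orthogonal rotation of the
coordinates, the Cox partial likelihood is invariant under linear
reparameterization, and hazard-ratio predictions contract the rotation away.
The test suite verifies agreement to ~1e-14 between fits under rotated
bases; the optimizer is therefore run to a tight step tolerance (1e-11)
rather than lifelines' looser default.

## Accelerometer processing

Non-wear is detected on per-minute counts as runs of ≥ 90 zero-count
minutes. Up to two interruption minutes with counts 1–99 are absorbed into a
run when the interruption is flanked on both sides by ≥ 30 consecutive
zero minutes; a flank truncated by the start or end of the recording counts
as satisfied (the data that would disqualify it does not exist). Counts
≥ 100 always terminate a candidate run. The implementation merges maximal
zero runs across tolerable gaps, greedily from each run start; the tests
compare it against an independent brute-force enumeration of all
zero-bounded candidate segments. The 90/2/30 parameters and the intensity
cut points (SB ≤ 100, LLPA 101–760, HLPA 761–1951, MVPA ≥ 1952 counts/min)
are exposed as arguments but default to the standard hip-worn,
vertical-axis values. Epochs are fixed at 60 s. Days with < 10 h wear are
dropped before averaging, and subjects with < 4 remaining days are excluded
(exclusions are returned as a log, not an error).

## Rounded zeros

A subject with no whole recorded minute of MVPA has a rounded zero: the true
proportion lies below the detection limit DL = 1 minute / wear minutes. The
lrEM imputation models additive log-ratio coordinates (reference part: SB,
which is structurally zero-free here) as multivariate normal and iterates:
estimate the mean and covariance from the completed matrix; replace each
censored coordinate by its conditional expectation given the row's observed
coordinates, truncated above at the alr-transformed DL (inverse-Mills
formula); stop when the largest imputed-value change falls below `tol`
(default 1e-4, `max_iter` 100 — non-convergence raises with the iteration
trace). Observed parts of a row are rescaled by a common factor afterwards,
so their mutual ratios are untouched and the row re-closes to 1; imputed
values are strictly inside (0, DL). A multiplicative fallback (zero →
0.65·DL) provides an order-of-magnitude cross-check. Count-based Bayesian
multiplicative treatments and structural zeros are out of scope.

## Survival model

The compositional Cox model places the three ilr coordinates and the
covariates in one partial likelihood (Efron tie handling, via lifelines).
Follow-up time is years since accelerometer wear, with age as a covariate
rather than as the time scale. Wear minutes can be added as a covariate but
default off in the compositional model (proportions already remove wear) and
on in the standard comparator. Hazard ratios for a composition versus a
referent use only the ilr block of β and its covariance — covariates cancel
because they are held equal — and 95% Wald intervals on the log scale.

The referent is the compositional (geometric-mean) center of the
least-active quartile, ranking subjects by the active share of wear time
(1 − SB proportion); ranking by MVPA share is available as an alternative
since "total activity" admits more than one reading. Ties at the quartile
boundary are broken by stable subject order.

Proportional hazards are checked with the scaled-Schoenfeld test
(Kaplan–Meier time transform by default) and functional form with martingale
residuals returned against raw behavior minutes. The standard comparator
drops one behavior (SB by default) and regresses on raw minutes of the rest
plus wear time, so each coefficient prices a minute moved out of the dropped
behavior; its reallocation HR `exp(t·β_j)` is exactly log-linear in `t`,
which is the contrast the model-comparison analysis displays against the
compositional model's curvature.

## Reallocation analyses

Every analysis is a composition of exactly two primitives — a substitution
constructor and the HR predictor — so curve values are reproducible
point-by-point by hand:

* *single-behavior curves*: set one behavior to each grid value, rescale the
  others by a common factor (ratios preserved, total fixed);
* *pairwise curves*: move δ minutes between two behaviors, others untouched;
* *scenarios*: (a) +22 min/day MVPA from SB (meets the 150 min/week
  guideline, total 25 min/day); (b) +120 min/day LLPA from SB; (c) +60
  min/day HLPA from SB; (d) the mean composition of guideline-meeting
  subjects (MVPA ≥ 150/7 min/day), closed to the referent's total;
  (e) +90 HLPA and +120 LLPA from SB with MVPA fixed. The reallocation
  amounts in (a)–(c) and (e) are fixed design constants, not fitted;
* *ternary grids*: a barycentric lattice over three behaviors with the
  fourth at its referent proportion; nodes with any part below a one-minute
  floor are excluded because log-ratios diverge at zero;
* *model comparison*: 30 min/day out of SB into each activity intensity,
  priced by both models.

Curve grids default to feasibility bounds around the referent with a
configurable step (5 min in the pipeline driver, 1-min resolution available
where needed); CI bands are pointwise.

## Synthetic cohorts

The generator draws ilr coordinates from a multivariate normal
(logistic-normal compositions), wear time from a truncated normal
(mean 891.4, SD 75.2, ≥ 600 min), age (truncated normal 72 ± 5.7 on
62–101), a rare current-smoker indicator (3.5%) and prevalent-disease flags
(CVD 2.4%, cancer 11.9%) used by the sensitivity filters. Event times follow
a Weibull proportional-hazards model (shape 1.3) with linear predictor
`β·(z − μ) + 0.09·(age − 72) + 0.5·smoker`; administrative censoring is
uniform on 2.4–6.2 years (accrual spread with follow-up capped at 6.5 y),
giving mean follow-up ≈ 4.24 (SD 1.15) years. MVPA minutes are rounded to
whole minutes, so sub-half-minute MVPA becomes an exact zero — the rounded
zeros the imputation stage exists for. All draws flow from one seed and are
bit-reproducible.

The `whs-like` preset was moment-matched once on large pilot draws so that
minute-scale behavior means track 14.7 / 63.6 / 222.0 / 591.3 min/day and
the rounded-zero fraction lands near 0.5%; with events at ~3.1% of subjects.
One deliberate compromise: a logistic-normal cannot simultaneously match the
MVPA mean (14.7), its published SD (16.5) and a 0.5% sub-half-minute tail.
The preset favors the mean and the zero fraction — which drive the referent
and the imputation stage — leaving the synthetic MVPA SD at ≈ 19 min/day.
Its effect sizes are clr-scale log-hazard coefficients (−0.10, −0.19, −0.26,
+0.55) for (MVPA, HLPA, LLPA, SB), chosen by inverting the clr-linear model
at the published referent against published per-reallocation HRs; they
reproduce the qualitative field findings — protective activity, harmful SB,
and per-minute potency ordered MVPA > HLPA > LLPA by the log-ratio geometry.
An optional reverse-causation preset adds a latent illness that both lowers
activity and raises the death rate, to exercise the sensitivity filters.

What the generator does **not** emulate: diurnal/bout structure in the
minute streams (wear is one contiguous block with uniform in-band counts),
the full covariate set of a real cohort (only age, smoking and two
prevalence flags are drawn, independently of the composition),
non-proportional hazards, and dependence between censoring and exposure.
Passing tests therefore demonstrate the statistical machinery — estimator
consistency, CI calibration, basis invariance, shape contrasts — under the
model's own assumptions, not robustness to real-world violations of them.

## Problem sizes and numerical choices

Simulation-based checks use n = 2000 subjects per replicate (≈ 60 events)
with 200 replicates for CI coverage and type-I error, and the full cohort
size n = 16,676 for calibration-scale checks; these sizes resolve the
quantities being tested while keeping the default suite fast. Degenerate
inputs fail loudly: empty minute series, non-positive parts, fewer than two
events, a zero-bearing alr reference, mismatched composition totals and
infeasible reallocations all raise with the offending quantity named.
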