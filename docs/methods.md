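# Methods

## Setting and data model

The package operates on *disaggregated* health-indicator data: for each
stratum — a (setting, survey source, year, indicator, inequality dimension)
combination — it receives one estimate $y_j$ per population subgroup $j$,
the subgroup's population share $p_j$, and optionally the estimate's
standard error. Nothing below requires survey microdata; all computation is
on these published subgroup aggregates.

Dimensions come in three kinds, which determine both subgroup handling and
measure applicability:

* **ordered** (wealth quintiles, education levels): subgroups carry an
  explicit rank, 1 = most disadvantaged;
* **binary** (urban/rural residence, sex): a configured reference subgroup
  (defaults: urban, male) anchors pairwise and attributable measures;
* **unordered with many subgroups** (subnational regions): no social
  ordering; extremes and best performers are identified from the data.

Ordered dimensions admit 9 measures (D, R, PAR, PAF, ACI, RCI, SII, RII,
KMI), binary dimensions 4 (D, R, PAR, PAF), unordered dimensions 10
(D, R, PAR, PAF, BGV, MDB, MDM, IDIS, MLD, TI); the union is the full set
of 15 (7 absolute, 8 relative).

## Definitions and conventions

The national average is the share-weighted subgroup mean,
$\mu = \sum_j p_j y_j$. Population shares are renormalised to sum exactly
to one before computation (survey shares are typically rounded); the
renormalisation is logged. If an externally published national estimate
differs from $\mu$, the weighted mean is still used — it is the only choice
self-consistent with the shares used by the weighted measures.

The relative rank of subgroup $j$ in an ordered dimension is the midpoint
of its cumulative share interval, $X_j = \sum_{k \le j} p_k - p_j/2$,
computed in disadvantage→advantage order; $0 < X_j < 1$ always.

**Direction.** Indicators are flagged *favourable* (higher is better, e.g.
intervention coverage) or *adverse* (lower is better, e.g. mortality). The
flag switches the sign convention of SII and the orientation of KMI, and
decides which subgroup is "best performing" for MDB and for the unordered
reference of PAR/PAF (maximum estimate if favourable, minimum if adverse).

**Subgroup selection for D, R, PAR, PAF.** The printed formulas leave the
comparison subgroups open; the package resolves them as: ordered — most
advantaged vs most disadvantaged by rank (regardless of which estimate is
larger, so D can legitimately be negative); binary — reference subgroup vs
the other; unordered — maximum vs minimum estimate. The PAR/PAF reference
is the most-advantaged subgroup (ordered), the configured reference
(binary), or the best-performing subgroup (unordered). Negative PAR is
reported as computed; an explicit `floor_par` option clamps it at zero for
users who prefer the truncated convention, and the clamp is noted in the
result.

**Ties.** When two subgroups share the best estimate, the one with the
larger population share wins, then the lexicographically smaller label;
the chosen subgroup is recorded in the result notes.

**IDIS** uses the *unweighted* sum over subgroups,
$\frac{1}{n}\sum_j |y_j-\mu| / \mu \times 100$, deliberately unlike its
weighted neighbours — this matches the index's standard printed form.
MLD and TI include the conventional ×1000 reporting multiplier.

**Rank regression (SII, RII, KMI).** Default is weighted least squares of
$y_j$ on $X_j$ with weights $p_j$ (via statsmodels). A linear model keeps
the estimator transparent and exactly recovers a linear gradient, which is
what makes the package's hand-derivable examples and parameter-recovery
tests exact. Logit-link variants used by some monitoring tools for bounded
indicators are intentionally not the default; the linear WLS choice is a
documented convention of this package, not a claim of bit-compatibility
with any other toolkit.

**Degenerate inputs.** Division by zero (R with $y_{low}=0$, relative
measures with $\mu=0$, KMI with $v_0=0$) and logs of non-positive estimates
produce an *undefined result*: the measure is returned with a blank
estimate and an explanatory note, never silently dropped and never an
exception, so exported tables show why a cell is empty. Strata need at
least two subgroups; ordered strata need a complete, gapless rank sequence.

## Confidence intervals

All intervals are 95% by default (`level` configurable).

* **Analytic (D, R).** D: $D \pm z\sqrt{se_{high}^2 + se_{low}^2}$.
  R: log-delta method,
  $R \cdot \exp\!\big({\pm z \sqrt{(se_{high}/y_{high})^2 + (se_{low}/y_{low})^2}}\big)$.
* **Parametric bootstrap (the other 13).** Each draw resamples every
  subgroup estimate independently from $\mathrm{Normal}(y_j, se_j)$,
  clamps negative draws at zero (indicators are non-negative; the clamp
  rate is logged), recomputes the measure — re-resolving data-dependent
  subgroup selection (best performer, max/min) per draw so selection
  uncertainty is included — and a percentile interval is taken over the
  draws. Default 2000 draws; at least 100 are required for a reported CI.
  Draws on which a measure is undefined are dropped; if more than half are
  undefined the CI is suppressed with a note. The generator seed is an
  explicit parameter, so reported output is exactly reproducible.

Routing D and R to closed forms and everything else to the bootstrap is a
design choice: those two have uncontroversial analytic intervals, while
the weighted, rank-based and entropy measures do not have standard exact
formulas at small numbers of subgroups. Missing standard errors never fail
a computation — point estimates are still produced and the CI is suppressed
with a note.

The bootstrap is *parametric by necessity*: with only published aggregates
there is nothing to resample nonparametrically. It is correctly specified
exactly when the stated standard errors describe independent Gaussian
errors on the subgroup estimates — which is how the synthetic generator
builds data (below), making coverage experiments a clean test of the
interval machinery rather than of survey-design assumptions.

## Table views

*Explore* views reproduce the two within-setting tables: a disaggregated
table (one row per subgroup record; optional normal-approximation bounds
$y_j \pm 1.96\,se_j$) and a summary-measure table (one row per stratum and
measure). "Latest" selection keeps, per (setting, source, indicator,
dimension), only the maximum survey year; distinct sources (e.g. DHS and
MICS) are never merged and each contributes its own latest row. Decimals
(default 1) and the display multiplier (default 1) are presentation-only;
underlying values keep full precision. Measures requested for a dimension
they do not apply to yield an annotated blank cell, not an error.

*Compare* views benchmark a reference setting against comparators filtered
by income group and region, restricted to settings with data for the
indicator and dimension inside an inclusive window of 0–5 years around the
reference year (range 5 around 2007 spans 2002–2012). With several
eligible surveys, the year closest to the reference is used, ties broken
to the later year (logged). The reference setting is always shown, even
when it has no data in the window; manual include/exclude lists are
applied last, with includes overriding the income/region filter. Income
group and region are free-text metadata carried with the data — no
external taxonomy is embedded, so vocabularies cannot go stale.

All tables export as comma- or tab-separated text with lossless quoting.

## Synthetic data generator

A stratum is generated from a linear social gradient: subgroup $j$ at rank
$X_j$ gets $y_j = b + \beta X_j + \varepsilon_j$,
$\varepsilon_j \sim \mathrm{Normal}(0, \sigma)$, truncated at zero, with
the reported standard error set to $\sigma$. Consequences used by the test
suite: the true SII of the stratum is exactly $\beta$ (WLS recovers a
noiseless line), and the bootstrap's Normal model is exactly the data
model, so 95% intervals should cover truth at their nominal rate.
Generator specs whose truncation probability exceeds 1% for any subgroup
are rejected, keeping the log-based measures defined.

Full datasets cross settings × years × indicators × dimensions, drawing
per-stratum parameters from a seeded hyperprior — base $\sim U(30, 70)$,
slope $\sim U(-25, 25)$, $\sigma \sim U(0.5, 2)$, Dirichlet(8) shares —
so estimates behave like coverage percentages far from zero. Settings get
round-robin income groups and regions and alternating survey sources.
These defaults describe a realistic coverage-indicator regime; what they
deliberately do *not* emulate is survey reality — no sampling design,
clustering, share uncertainty, non-normal errors, or missingness — so
passing tests validate the estimators and intervals under a correctly
specified model, not robustness to survey artefacts.

## Experiment sizes and numerical choices

* Oracle-equivalence suites compare every measure against an independent,
  loop-coded transcription of the formulas on 1000 random strata at
  $10^{-10}$ relative tolerance.
* Parameter recovery uses 200 noisy replicates (gradient $b=30$,
  $\beta=40$, $n=5$, $\sigma=2$) and requires the mean SII within 3
  Monte-Carlo standard errors of $\beta$.
* CI coverage uses 500 simulated strata per measure (D, BGV, SII, RCI)
  with 2000 bootstrap draws each, asserting coverage in $95\% \pm 2$
  points; these sizes give a Monte-Carlo standard deviation of about 1
  point at the nominal level and run in seconds.
* Share renormalisation tolerance for validation findings defaults to
  0.01 (survey tables are typically rounded to two decimals); exact
  renormalisation is always applied before computation regardless.
* Multi-year survey labels ("2005-06") map to their end year at read time
  so window arithmetic stays integral.

## Known limitations

* No regression-adjusted or multivariate decomposition of inequality; the
  measures are univariate summaries per dimension.
* The WLS rank regression is the only regression family exposed by
  default; bounded indicators near 0 or 100 may prefer a link function.
* Analytic intervals exist only for D and R; all other intervals inherit
  percentile-bootstrap small-sample behaviour (slight under-coverage for
  strongly nonlinear functionals like BGV when noise is large relative to
  between-group spread).
* Standard errors are taken at face value and assumed independent across
  subgroups; correlated survey designs violate this.
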