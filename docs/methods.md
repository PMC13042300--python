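# Methods

## The assay and its data

The multisensory foraging-risk assay places 10 *C. elegans* on a plate inside
a 1 cm ring of 3 M fructose (an aversive hyperosmotic barrier) with an
attractive diacetyl odor outside, and counts after 15 min how many worms have
crossed the ring.  The per-plate observable is **percent exiting** =
100 · (placed − remaining) / placed, which with 10 worms lives on the lattice
{0, 10, …, 100}.  The unisensory chemotaxis variant scores a **chemotaxis
index** (worms at odor − worms at control) / total ∈ [−1, 1]; worms at
neither spot still count in the denominator.  Plates are the experimental
unit throughout; there are no per-worm trajectories.

The quantity of scientific interest is the **effect of food deprivation** for
one strain: food-deprived minus fed mean percent exiting, in percent points.
Mutant lines are always paired with wild-type controls tested on the same
days (the `control_group` field).

## The bootstrapped difference

Percent-exiting data are bounded counts and strongly skewed, which undermines
the normality assumption of a plain factorial ANOVA.  The pipeline therefore
estimates the effect of food deprivation by a paired bootstrap:

1. For each of R replicates (default R = 10,000), draw m values with
   replacement from the fed sample and m from the food-deprived sample, with
   m = min(N_fed, N_fd).
2. Form the element-wise difference vector (food-deprived − fed) and record
   its mean and SD (sample convention, ddof = 1, configurable).
3. Report the mean of the R replicate means (the effect estimate), the mean
   of the R replicate SDs, and a **trimmed percentile 95% CI**: sort the
   replicate means, drop ⌊α/2 · R⌋ = 250 from each end, and take the
   remaining extremes as bounds.

Numerical contract: one PCG64 stream per call, seeded from the
configuration, consumes first the block of fed resampling indices
(R × m draws) and then the food-deprived block.  Identical data,
configuration and seed give bit-identical results.  Degenerate m = 1
replicates have no sample SD; the implementation reports 0 with a warning.
Resampling both groups at m (rather than each at its own N and truncating)
is distributionally identical for independent draws and makes the seed
contract unambiguous.

An exhaustive **enumeration oracle** provides exact expectations of the
replicate mean and SD for small samples: within a replicate the m difference
entries are i.i.d. draws from the N_fed · N_fd equiprobable pairwise
differences, so enumerating all (N_fed · N_fd)^m tuples (capped at 2 × 10⁶)
is exactly the bootstrap's expectation.  The Monte-Carlo estimates are tested
against this oracle within 4 Monte-Carlo standard errors.

## Factorial ANOVA, pseudo-N, and post hocs

**Raw track.**  Percent-exiting values enter a fixed-effects factorial ANOVA
(strain × condition, optionally × a third factor) with all interactions.
Unbalanced designs use Type III (marginal) sums of squares under sum-to-zero
contrasts; balanced designs are SS-type invariant (tested).  Fits go through
statsmodels OLS.  Reporting follows the standard hierarchy, implemented as an
executable policy (`report_hierarchy`): the significant terms of the highest
interaction order that has any; main effects only if no interaction is
significant anywhere.  The renderer prints the full table regardless.

**Summary track.**  Each strain's bootstrapped difference is summarized as
(mean of means, mean of SDs, n), with **pseudo-N = N_fed + N_fd − 1**: the
difference sample spans both feeding groups, costing one degree of freedom
(N − k with k = 2 groups).  `anova_from_summary` reconstructs one
moment-matched raw vector per cell — exact to machine precision, since a
fixed-effects ANOVA depends on the data only through cell means and
within-cell sums of squares — and dispatches to the raw-track fit.  The
pseudo-N rule inflates the effective sample size relative to the number of
plates; the `type1_experiment` with `procedure="summary_effect"` measures
(rather than gates) the resulting rejection rate, because the rule itself is
an object of study.

**Post hocs.**  Multi-control designs compare each mutant to its matched
wild-type within each feeding condition, two-sided t on the pooled residual
mean square, Šidák-adjusted with p′ = 1 − (1 − p)^m where m is exactly the
number of planned comparisons (m = 1 short-circuits to the identity).
Single-control designs use Dunnett's many-to-one test: the two-sided p-value
is the complement of the equicorrelated multivariate-t box probability
P(|T_j| ≤ |t_i| ∀j) with correlation √(n_i n_j / ((n_i+n_0)(n_j+n_0))),
computed by seeded quasi-Monte-Carlo integration (scipy `multivariate_t.cdf`)
with tolerance ~1e−3; k = 1 is special-cased to the exact univariate t,
which is the analytic reduction.  Zero within-cell variance yields an
explicit degenerate status (F, p = NaN) instead of infinities.

## Synthetic plate generator

The generator emulates the data's statistical shape, not the biology: no
locomotion or decision model.  Exit propensity is additive on the logit
scale,

    logit p = baseline + strain + condition·[fd] + interaction·[fd],

so fed/food-deprived contrasts are well defined at any baseline, and the
truth table reports effects on the percent scale the statistics use
(100 · (p_fd − p_fed)).  Plate counts are binomial(10, p) at intra-plate
correlation ρ = 0, beta-binomial with mean p and intra-class correlation ρ
otherwise (variance inflated by 1 + 9ρ on 10-worm plates).  A beta-binomial
was chosen over truncated-Gaussian noise because the observable is a bounded
count and the real data are strongly skewed; ρ is the single overdispersion
knob.  The real assay's overdispersion is unknown (raw plate counts are not
published), so the default ρ = 0.05 is a calibration setting, not an
estimate.  Defaults otherwise mirror the assay: 10 worms/plate, wild-type
fed exit probability 0.2 rising to 0.6 after one hour of food deprivation
(a 40-point effect), 20 plates per cell.  Batch labels cycle across plates
and carry no effect unless a batch-effect logit is supplied.

What passing tests on generator data do **not** show: that real plate data
have beta-binomial noise, that day effects are ignorable, or that the
published experiments' coverage matches the simulated coverage.

## Calibration experiments and problem sizes

All calibration estimates carry binomial Monte-Carlo standard errors
√(r(1−r)/n_sims), and every report embeds the config and seed needed to
regenerate it.  Bootstraps inside simulations run at 2,000 replicates (a
recorded parameter) rather than 10,000; the replicate count affects only
Monte-Carlo noise on the summaries, not their expectations.  Default problem
sizes — 500 coverage simulations, 1,000 type-I simulations, 300 recovery
simulations per grid point, 2,000 Dunnett familywise simulations — were
chosen so each experiment resolves its target rate to ~0.01 while completing
in seconds to a couple of minutes on one CPU.

Measured properties under these conditions (recomputed by the test suite and
`scripts/acceptance.py`, not quoted from elsewhere): the raw-ANOVA
interaction F-test and the Dunnett familywise error sit inside
[0.035, 0.065] at nominal 0.05; trimmed-percentile CI coverage at 30
plates/cell and ρ = 0.05 falls in the 0.90–0.98 band typical of percentile
bootstraps (slightly below nominal at small n); the effect estimator is
unbiased within Monte-Carlo error at effects of 0 and 60 points, with RMSE
decreasing in plates per cell.

One statistical note on the expectation-identity check (estimate vs plain
difference of sample means): the deviation divided by its Monte-Carlo SE is
asymptotically standard normal, so over 1,000 independent pairs a few
~3-sigma excursions are expected; the test asserts the 3-sigma bound for at
least 99% of pairs and a 5-sigma bound for all, which is the sound
operationalization of "within 3 SEs" at that multiplicity.

## Known limitations

- Type III sums of squares are one convention for unbalanced data; other
  software defaults (e.g. Type II, or repeated-measures corrections) will
  disagree on unbalanced designs.
- The Dunnett QMC integration is accurate to ~1e−3; p-values nearer to a
  decision boundary than that should be recomputed at higher `maxpts`.
- The pipeline models no plate-level covariates beyond batch labels and no
  mixed effects; days are handled by matched controls, not by modeling.
- Plates with fewer than the nominal 10 countable worms are scored by the
  generalized formula (placed − remaining)/placed; whether the original
  assays excluded or rescaled such plates is unknown, so both policies are
  representable but neither is enforced.
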