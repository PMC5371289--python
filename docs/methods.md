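# Methods

## The estimand and the hierarchy

The analysis treats a species' *yearly pattern* — the 12-vector of monthly
proportions of its annual abundance — as the unit of observation. Years are
grouped into pre-defined multi-year periods (regimes between abrupt
ecosystem shifts, supplied as input; the package does not detect shifts).
Within a period the yearly patterns are exchangeable draws from a Dirichlet
distribution centred on the period-average pattern a_{s,j,·} with
species-level concentration λ_s:

    P_s(y) | year y in period j  ~  Dirichlet(λ_s · a_{s,j,·})

λ_s > 1 means dense years (each year resembles the period mean); λ_s < 1
sparse, erratic years. There is no transition structure between years or
periods: period means are a priori independent, and all temporal signal
enters through the period labels. Priors are flat — Dirichlet(1/12,…,1/12)
on each period mean and Uniform(0.3, 2000) on λ_s — so the posterior is
driven by the data except at the λ bounds (see Limitations). Species are
independent and fitted separately.

## Pretreatment

- **Monthly averaging.** All raw samples of a species in a calendar month
  (stations, depths, replicate hauls) are averaged arithmetically into one
  value; months without samples produce no row.
- **Occurrence filter.** Species are retained when the fraction of raw
  samples in which they were caught (abundance > 0) strictly exceeds the
  threshold (default 2%). A seasonal profile estimated from a handful of
  positive catches is meaningless; the filter's denominator is every row of
  the raw table.
- **Ecological years.** Dates are re-anchored to a per-species start month
  (March for spring/summer-maximal species, July for winter-maximal ones,
  configurable to any month) so that a single seasonal peak is not split
  across year boundaries. The remap is a bijection on dates.
- **Zero handling.** A Dirichlet density is undefined on the simplex
  boundary, so observed zeros cannot be scored directly. The default policy
  replaces each zero or unsampled monthly proportion by ε = 10⁻³ and
  renormalises (multiplicative replacement, the standard compositional-data
  fix; ε configurable). The alternative `aggregate-observed` policy treats
  months never sampled for a species as structural zeros outside the
  simplex support: the model then operates on the reduced set of sampled
  months (useful for protocols that skip winter months), while zeros among
  sampled months are still ε-replaced. Years with zero total abundance are
  dropped and logged; a species-period with no surviving year is *absent*
  and excluded from every comparison involving that period.
- **Modality.** A species is called bimodal when its all-years average
  pattern has at least two local maxima, each ≥ 20% of the global maximum,
  separated by a trough ≤ 50% of the smaller peak; overridable per species.
  Bimodal species get the peak-timing indicator per half-year (T1 months
  1–6, T2 months 7–12); quantiles and residence time stay whole-year, since
  they describe the occurrence season as a whole.

## Sampler

No probabilistic-programming backend is used; the posterior is low
dimensional (12 coordinates per present period plus λ) and the Dirichlet
log-likelihood reduces to sufficient statistics — the number of years and
the per-month sum of log-proportions — making a posterior evaluation O(12)
regardless of series length.

Each period pattern is parameterised through the gamma representation of
the Dirichlet: with z_m = log g_m and g_m ~ Gamma(1/12) independent,
a = softmax(z) carries exactly the flat Dirichlet prior, and every month
owns one well-pinned coordinate (log-gamma density 1/12·z − eᶻ). λ moves on
the log scale inside its bounds. Sampling is componentwise random-walk
Metropolis with per-coordinate, per-chain proposal scales adapted every 50
iterations *during burn-in only* (diminishing steps towards 35%
acceptance), which preserves the correct invariant distribution after
burn-in. Chains are initialised at the empirical mean pattern per period
(jittered per chain) with λ spread geometrically around 10 across chains,
so the Gelman–Rubin diagnostic starts from genuinely dispersed states.

Defaults follow common practice for this model class: 3 chains, 10,000
burn-in iterations, 50,000 kept per chain, R̂ < 1.05 required for every
scalar parameter (each a_{s,j,m} and λ_s; violations attach warnings to the
posterior object rather than raising). A `FAST_MCMC` profile (3 × 2,000
kept after 1,000 burn-in) is used by the test suite and calibration
experiments; on the experiment posteriors it reproduces the full-profile
intervals to well within their own Monte-Carlo error, and a three-period,
24-year species fits in a few seconds on one core.

Per-species seeds are derived from the species name (CRC32 mixed into the
seed sequence), so a fit is invariant to which other species share the
table and to fit order.

## Indicator conventions

- **Quantiles.** Cumulative mass is anchored at integer month boundaries
  with C(0) = 0: month m's mass accrues over (m−1, m], and the q-quantile
  is m + (q − C(m)) / (C(m+1) − C(m)) for the unique bracketing m. This
  makes the uniform pattern's Q50 exactly 6.0 and keeps quantiles in
  (0, 12].
- **Residence time.** The minimum *number* of months holding 90% of annual
  abundance is read literally: months need not be consecutive, and sorting
  proportions in decreasing order gives the provably optimal subset. A
  `contiguous=True` variant (shortest consecutive block within the
  ecological year) is provided for sensitivity analysis; it can only be
  longer.
- **Overlap.** O = Σ min(a₁, a₂) is computed from the two species' draws
  matched by chain and iteration. Species posteriors are independent, so
  this equals independent pairing in distribution while keeping the
  computation a deterministic function of the stored draws.
- All indicators are evaluated on *every* posterior draw; summaries are the
  posterior mean and equal-tailed 95% interval (2.5/97.5 percentiles of the
  draws).

## Trajectory classification

Two periods differ significantly when their 95% CIs are strictly disjoint
(intervals sharing an endpoint do not count). Signs come from posterior
means. The decision tree condenses the three pairwise outcomes:

1. no significant pair → `NS`;
2. with all three periods present and no significant end-to-end (P1 vs P3)
   trend, a significant difference placing period 2 below (above) its
   neighbours → dip (bump);
3. otherwise a consistent monotone direction → increase or decrease;
4. contradictory directions fall back to the majority of significant
   pairs, ties → `NS`; every ambiguity is logged, never silent.

Glyphs then depend on the indicator class: for timing indicators smaller
values mean *earlier*, so a monotone decrease prints "/" (precocity) and a
dip prints "C"; for magnitude indicators (Tr, overlap) "/" is an increase.
Symbols are serialised as ASCII tokens named after the glyph (`inc` = "/",
`dec` = "\", `C`, `revC` = "Ɔ", `NS`, `undef`). A `legacy_overlap_symbols`
switch swaps "/" and "\" for the overlap indicator only, reproducing table
conventions in which "/" denoted an overlap decrease; the bundled Gironde
reference interaction table is encoded in that legacy convention, as
printed. Units with fewer than three present periods can only receive
monotone shapes. Percentages in summaries are rounded half-up (one decimal
for cell fractions, integers for overlap change strings).

## Synthetic data: what it emulates, what it does not

The generator inverts the model: per species, yearly patterns are Dirichlet
draws around true period means with true concentration; yearly totals are
lognormal around a scale parameter (CV 0.5 by default — totals are
discarded by the normalisation, so this only exercises the pretreatment
arithmetic); optional Poisson resampling adds observation noise (off by
default, keeping proportions the exact estimand); months a protocol never
samples are emitted as *absent rows*, forcing pretreatment to handle them
explicitly; randomness is split into per-species substreams so appending a
species never perturbs existing data. Trajectory scenarios encode symbols
constructively: timing symbols as integer/fractional translations of a
compact seasonal bump (exact zeros outside the support, so the true centre
of gravity shifts exactly by the nominal amount), magnitude symbols as
plateau patterns whose true residence time is the plateau width by
construction.

The generator does **not** emulate station/depth/tidal structure, gear
selectivity, abundance trends within a period, autocorrelated years, or
environmental covariates. Passing calibration on these data therefore shows
that the estimation and classification machinery is correct and calibrated
under the model's own assumptions — not that real surveys satisfy those
assumptions.

## Calibration experiments (problem sizes)

- *Coverage*: 20 replicate single-period datasets, 14 years, λ = 50,
  smooth interior pattern; the 95% CI covers the true monthly proportion in
  ≈ 95% of the 240 month × replicate cells (≥ 90% required).
- *Trajectory recovery*: for each symbol, 10 replicate three-period
  datasets (8 years/period, λ = 200, 2-month shifts); the generating symbol
  is recovered end-to-end in ≥ 8/10 replicates.
- *Null specificity*: six species with identical patterns in all periods;
  ≥ 95% (observed: all) of species × indicator cells classify `NS` —
  CI-disjointness at 95% is a conservative test.

All use the fast MCMC profile and fixed seeds.

## Limitations

- With a single year in a period, the Dirichlet likelihood is maximised as
  λ → ∞, so near-zero months can be pinned *tighter* than with more years;
  total posterior uncertainty still shrinks with more data, but per-month
  CI width is not guaranteed monotone in sample size.
- When true patterns touch the simplex boundary, ε-replacement turns
  structural zeros into near-constant tiny proportions, which inflates the
  λ posterior (it absorbs their artificially low variance). Pattern means
  and timing indicators are unaffected in practice; λ should not be
  interpreted quantitatively for boundary-heavy species under the ε policy.
- The upper prior bound λ ≤ 2000 truncates the posterior for species with
  essentially identical years; the pattern posterior is then limited by the
  bound, not the data.
- CI-disjointness is a conservative multiple-comparison-free criterion; no
  further multiplicity correction is applied, by design.
- Trajectory symbols with a single significant pair depend on *which* pair
  fired; the classification records the firing pair and direction so such
  calls are auditable.
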