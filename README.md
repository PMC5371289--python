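# phenomatch

Bayesian analysis of seasonal abundance phenology across ecosystem regimes,
built around the match–mismatch question: when the timing of a predator's
presence and its prey's availability drift apart, trophic interactions can
weaken even if both species remain abundant.

The package targets long-term monthly survey data (e.g. estuarine fish and
zooplankton monitoring) partitioned into multi-year *periods* between abrupt
ecosystem shifts. For every species it estimates the average yearly pattern
of abundance in each period, computes phenological indicators and
predator–prey temporal overlap on every posterior draw, and classifies
inter-period changes into trajectory symbols.

## Model

For species *s*, the yearly pattern
P<sub>s</sub>(y) = {A<sub>s</sub>(y,1)/A<sub>s</sub>(y), …,
A<sub>s</sub>(y,12)/A<sub>s</sub>(y)} — the 12-vector of monthly proportions
of that year's total abundance — is modelled hierarchically within each
period *j*:

    P_s(y) ~ Dirichlet(λ_s · {a_s,j,1, …, a_s,j,12})
    {a_s,j,1, …, a_s,j,12} ~ Dirichlet(1/12, …, 1/12)
    λ_s ~ Uniform(0.3, 2000)

a<sub>s,j,m</sub> is the average proportion of month *m* in period *j* and
λ<sub>s</sub> the Dirichlet concentration (how tightly single years track
the period mean). Posteriors are sampled by MCMC (3 chains, Gelman–Rubin
R̂ < 1.05 required), and on every draw the package computes:

- **T** — centre of gravity of the pattern (month coordinate of the
  seasonal peak; per half-year for bimodal species),
- **Q10 / Q50 / Q90** — months at which 10/50/90% of annual abundance has
  accrued (beginning, middle, end of the occurrence period),
- **Tr** — residence time: minimum number of months holding 90% of annual
  abundance,
- **O** — temporal overlap Σ<sub>m</sub> min(a<sub>s1,j,m</sub>,
  a<sub>s2,j,m</sub>) between a predator and a prey.

Two periods differ *significantly* for an indicator when their equal-tailed
95% credibility intervals are disjoint. The pattern of significant pairwise
differences maps to one trajectory symbol per species × indicator:
`/` (precocity or increase), `\` (delay or decrease), `C` (period-2 dip /
earlier), `Ɔ` (period-2 bump / later), `NS` (no change).

Because raw multi-decade survey data of this kind are rarely public, the
package ships a first-class synthetic-data generator that inverts the model
(known period-mean patterns, concentration, presence, sampling gaps) so the
entire pipeline is testable against recorded ground truth.

## Worked example

`examples/04_trajectory_classification.py` generates a species whose
seasonal peak dips two months earlier in the middle of three 8-year
periods, runs pretreatment → MCMC → indicators → classification, and
prints:

```
             T    Q10    Q50    Q90  Tr
species
dipper   C (2)  / (3)  C (2)  C (2)  NS
```

The peak-timing indicator T recovers the generated "C" trajectory with two
significant pairwise period differences; the residence time, which the
scenario leaves untouched, stays `NS`. The fit itself
(`examples/02_fit_seasonal_patterns.py`) reports `max R-hat: 1.005` and
flags months `[3, 4, 5, 7, 8, 9]` as having disjoint 95% CIs between the
shifted and unshifted periods — the flanks of the old and new peaks.

The other examples cover simulation (`01`), indicator and overlap
posteriors (`03`), and the bundled Gironde-estuary reference tabulation
(`05`).

A thin CLI mirrors the library for shell-driven runs:

```bash
phenomatch run --config config.yaml --fast     # full pipeline
phenomatch simulate|pretreat|fit|indicators|classify|report ...
```

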