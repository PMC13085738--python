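# cleanstation

Analysis pipeline for a before-after-control-impact (BACI) habitat
manipulation experiment on a coral-reef cleaning mutualism. Cleaner
gobies service client fish at fixed coral-head "stations"; temporarily
covering a station with a net reduces live-coral and refuge access, and
the question is how the mutualism's behaviours respond — and whether
they recover once the net is removed.

The package provides every stage of that analysis as a tested library:

* **Behavioural metrics** — eight response variables per
  station-replicate survey (cleaning rate and duration, client posing
  rate, cleaner responsiveness measured as flight-initiation distance,
  cleaner selectivity, potential client abundance, potential and actual
  client species richness) extracted from event logs, frame censuses
  and disturbance trials.
* **Electivity index** — the Vanderploeg-Scavia-type selectivity
  statistic `W_i = (r_i/p_i) / Σ_j(r_j/p_j)`,
  `E_i = (W_i − 1/n)/(W_i + 1/n)`, comparing cleaning-time shares r to
  client availability p on a −1 (avoidance) … 0 (no preference) … +1
  (preference) scale.
* **Chain rugosity** — structural complexity of a station transect as
  the span-to-chain-length ratio `R = span / (n_links · link)` of a
  virtual 2 cm-link chain draped over the surface profile (1 = flat,
  lower = more rugose).
* **BACI differencing** — per station and variable, the signed change
  from baseline (`value_r − value_before`) and its excess over the mean
  change at untouched control stations.
* **Bayesian hierarchical inference** — Gaussian mixed models
  `y = μ + β_obs + u_station + v_area + ε` fitted by an exact blocked
  Gibbs sampler (weakly informative normal priors, half-t scale
  priors), with directional hypothesis summaries: posterior probability
  PP, evidence ratio ER = PP/(1−PP), 75%/95% credible intervals,
  intraclass correlations and rank-normalized R-hat / bulk-ESS
  diagnostics.
* **Synthetic-study generator** — ground-truthed studies with the
  experimental design (20 stations allocated 10/5/5 to experimental /
  sham / control, four replicate surveys each), Poisson event streams,
  multinomial client identities, tagged frame censuses and
  midpoint-displacement surface profiles.

See `docs/methods.md` for the models, their assumptions and the design
decisions.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
data; results land under `results/`.

```sh
python analysis/01_simulate_study.py      # raw observation CSVs
python analysis/02_behaviour_metrics.py   # eight responses per survey
python analysis/03_station_structure.py   # chain rugosity per station
python analysis/04_differencing.py        # BACI difference table
python analysis/05_fit_models.py          # hierarchical models + tests
```

`01` prints the design bookkeeping (80 surveys = 20 stations × 4
replicates; 10/5/5 allocation). `02` prints the experimental-station
means per replicate — under the default scenario cleaning rate falls
from 4.98 to 2.41 cleans/hr between the before and first surveys and
rebounds to 6.85 after net removal, while mean FID climbs from 10.67 cm
to 13.97 cm and stays high (13.82 cm) after removal. `03` reports
station rugosity 0.168–0.357 (mean 0.277). `05` then prints the
directional hypothesis table, e.g.:

```
             variable      hypothesis  estimate  posterior_probability  evidence_ratio
        cleaning_rate  before > first     0.659                  0.991         110.111
        cleaning_rate before > second     0.370                  0.932          13.706
        cleaning_rate  before > after    -0.370                  0.067           0.072
    responsiveness_cm  after > before     3.136                  0.997         332.333
```

Read: there is a 99.1% posterior probability that experimental-station
cleaning rates were higher before the manipulation than during its
first phase (posterior odds ≈ 110:1), no evidence of a deficit
remaining after net removal (PP 0.067) — the simulated recovery — and
near-certain evidence that responsiveness (FID) stayed ~3 cm above
baseline after removal, the simulated persistent fear response.
Estimates for the three sqrt-transformed behaviours are on the
square-root scale.

The same stages are available as a CLI (`cleanstation simulate |
validate | metrics | rugosity | diff | run-all`) and as library
functions (`simulate_study`, `build_metric_table`,
`station_selectivity`, `rugosity`, `difference_table`,
`fit_hierarchical`, `one_sided_test`, `run_pipeline`).

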