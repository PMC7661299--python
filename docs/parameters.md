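# Parameter document schema

`HmmParams.to_yaml()` / `from_yaml()` (and the `params` block of a fit
JSON) use one document shape.  All lists over states are ordered as in
`state_names`; dive-state lists cover states 2..N−1 in the same order.

```yaml
state_names: [haulout, surface, shallow, epipelagic, pelagic, benthic]  # optional
duration:              # gamma, one entry per state (seconds)
  mean_s: [10080.0, 2274.0, 60.0, 444.0, 846.0, 1140.0]
  sd_s:   [5040.0, 1140.0, 24.0, 180.0, 252.0, 300.0]
hunting_depth:         # gamma, dive states only (metres)
  mean_m: [8.8, 38.5, 193.8, 413.1]
  sd_m:   [3.0, 12.0, 35.0, 50.0]
hunting_proportion:    # beta, dive states only
  mean:      [0.51, 0.55, 0.49, 0.43]     # in (0, 1)
  precision: [30.0, 30.0, 30.0, 30.0]     # > 0;  a = mean*prec, b = (1-mean)*prec
benthic_probability: [0.005, 0.005, 0.005, 0.89]   # Bernoulli p, dive states
salinity:              # normal, dive states only (psu)
  mean_psu: [34.18, 34.29, 34.44, 34.61]
  sd_psu:   [0.04, 0.04, 0.04, 0.04]
transition_coefficients:   # (N*(N-1)) rows x K columns
  # row order: (i, j) row-major over ordered state pairs, j != i
  # columns: design entries (1, cos h, sin h, w, cos*w, sin*w) for the
  # "full" design; (1, cos h, sin h, w) for "no_interaction"; (1) for
  # "intercept".  w = (week - 15)/10.
  - [ -1.79, 0.0, 0.0, 0.0, 0.0, 0.0 ]
  # ... one row per off-diagonal cell
initial_logits: [0.0, 0.0, 0.0, 0.0, 0.0]   # only when initial == "estimated"
```

Validation rules: every sd and precision strictly positive; means of the
beta and Bernoulli families strictly inside (0, 1); transition coefficients
finite.  `HmmParams.validate(spec)` additionally checks all shapes against
the spec (state count, dive-state count, design width, initial rule).
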