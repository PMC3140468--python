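# spikesort

Scalable Bayesian spike identification for dense multi-electrode arrays
(MEAs).

Extracellular recordings from a dense electrode grid superimpose the action
potentials of many neurons on correlated background noise; assigning each
spike to the neuron ("unit") that produced it — including spikes that
overlap in space and time — is the spike-sorting problem. This package
implements a template-matching sorter built for that setting: it clusters a
small subset of the data into unit templates with a density-ordering
(OPTICS) workflow, then explains the full recording by greedy Bayesian
template fitting with the spike amplitude integrated out, and finally
screens every unit with quantitative reliability checks. A ground-truthed
synthetic-recording simulator makes every stage testable without real data.

## The model

A firing event `V` (channels x samples, whitened) is modeled as

    V = Σ_k λ_k T_{c_k}(t − t_k) + n,      n ~ N(0, C),

with templates `T_c` local to a 3x3 electrode neighborhood, amplitudes
`λ ~ N(μ_c, σ_c²)`, Poisson firing at rate `r_c`, and noise that is
independent across channels after spatial whitening and AR(1) in time
(`Cov = σ² e^{−|Δt|/τ}`, inverse tridiagonal). For a candidate spike
`(c, t)` the amplitude is marginalized analytically: with
`A = TᵀC⁻¹T + 1/σ_c²` and `b = TᵀC⁻¹V + μ_c/σ_c²`,

    log R(c, t) = log(r_c Δt) + b²/2A − μ_c²/2σ_c² − ½ log(σ_c² A),

the log odds of "one more spike of unit c at t" against "no additional
spike". Fitting is matching pursuit: fit the best candidate at the current
peak, subtract it, repeat until no unit's ratio summed over candidate times
exceeds one. The rate factor `r_c Δt ≪ 1` and the tight amplitude prior are
the overfitting penalty — no ad-hoc threshold enters the stopping rule.
Residuals still crossing threshold after fitting are recycled into new
templates and a second pass refits everything.

See `docs/methods.md` for the full model, parameter defaults, and design
rationale.

## Worked example

```python
import spikesort as ss

# 6 units on a 5x6 grid at 10 kHz, 24 s, Poisson firing at 4 Hz,
# peaks 6-10x the noise sd, 10% amplitude jitter, AR(1)+spatially
# correlated Gaussian noise. Ground truth records every planted spike.
cfg = ss.SimConfig(n_units=6, duration_s=24.0, rate_hz=4.0, seed=1,
                   peak_min_sigma=6.0, peak_max_sigma=10.0)
rec, truth = ss.simulate_recording(cfg)
rec.filtered = True          # simulated noise carries no baseline drift

res = ss.run_pipeline(rec, ss.PipelineConfig(cluster_subset_s=24.0))
print(len(res.bank), len(res.assignments))

from spikesort.synthetic import match_units
mapping = match_units(truth.templates, res.bank, rec.n_channels)
table = ss.score_sorting(truth, res.assignments, 0.5e-3, mapping)
print(table[["unit_id", "n_true", "n_fit", "fn_rate", "fp_rate"]].to_string(index=False))
print("reliable units:", sum(r.reliable for r in res.reports), "of", len(res.reports))
```

Output from this exact run:

```
6 614
 unit_id  n_true  n_fit  fn_rate  fp_rate
       0     106    107 0.000000 0.009346
       1     111    107 0.036036 0.000000
       2     112    108 0.035714 0.000000
       3     108    104 0.037037 0.000000
       4      98     94 0.040816 0.000000
       5      97     94 0.030928 0.000000
reliable units: 6 of 6
```

The sorter rebuilt the template bank from the recording alone, fitted 614
spikes, recovered every planted unit's train with false-negative and
false-positive rates of a few percent at ±0.5 ms tolerance, and passed all
six units through the reliability screen — the planted overlap statistics,
amplitude jitter, and noise correlations are all at their default
study-condition values.

The same stages are scriptable from the shell:

```bash
spikesort simulate --seed 5 --out rec.h5 --truth truth.csv
spikesort preprocess --in rec.h5 --out white.h5 --cutoff-hz 200
spikesort fit-noise --rec white.h5 --noise noise.json
spikesort cluster --rec white.h5 --noise noise.json --out bank.h5
spikesort fit --rec white.h5 --templates bank.h5 --noise noise.json --out spikes.csv
spikesort validate --spikes spikes.csv --templates bank.h5 --noise noise.json
spikesort score --truth truth.csv --spikes spikes.csv
```

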