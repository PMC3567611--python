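# p3dif

Observer models of trial-by-trial P300 amplitude fluctuations, with
hierarchical Bayesian model comparison.

The amplitude of the P300 event-related potential tracks how surprising a
stimulus is to the observer.  `p3dif` implements three computational
observers of a binary (generally K-ary) stimulus stream and the machinery
to ask which of them best explains measured single-trial amplitudes:

* **MAR** — a Bayesian event counter without forgetting:
  `P_k(n) = (c̃_L,k(n) + 1)/(n − 1 + K)`.
* **SQU** — the classical expectancy account:
  `E_k(n) = 0.505·P_k + 0.235·c̆_S,k(n) − 0.033·c̆_Δ,k(n) − 0.027`, mixing
  the (known) global probability, a 5-trial decaying memory and an
  alternation-expectancy term in {−3, −2, 0, 2, 3}.
* **DIF** — a digital-filter observer:
  `P_k(n) = α_L·c_L,k(n) + α_S·c_S,k(n) + α_Δ·c_Δ,k(n) + 1/C`, the sum of
  a short-term one-pole IIR low-pass (forgetting factor
  `γ_S = e^{−1/β_S}`), a long-term one-pole IIR low-pass whose forgetting
  factor grows toward 1 with experience, and a 4-tap FIR high-pass
  capturing alternation structure — all driven by the same input signal
  `g_k` (uniform prior 1/K before the block, event indicator after).

Trial-by-trial amplitudes are linked to each observer's predictive
surprise `I(n) = −log2 P_{k=s(n)}(n)` (bits) — or expectancy, for SQU —
through a three-level hierarchical linear-Gaussian model
`Y_ℓ(n) = θ_ℓ + ϑ_ℓ·I_ℓ(n) + ε`, fitted by parametric empirical Bayes
with EM-estimated variance hyperparameters.  Models are compared by the
log-Bayes factor `ln BF = F_a − F_b` of their log-evidences (values > 5:
"very strong" evidence).  A two-iteration coordinate grid search
identifies the DIF parameters by evidence maximization, and a
sequence-tree module averages amplitudes by the pattern of up to three
preceding stimuli.  A synthetic-data generator reproduces the study
design (16 participants, 192-trial blocks at [0.5, 0.5] and [0.3, 0.7],
six repetitions averaged) so the full pipeline is testable end to end
without EEG data.  See `docs/methods.md` for the model details and design
choices.

## Worked example

```python
import numpy as np
from p3dif import (SimulationConfig, simulate_dataset, peb_fit, build_design,
                   model_trace, regressor, log_bayes_factor, SQUParams)
from p3dif.simulate import design_from_dataset

ds = simulate_dataset(SimulationConfig(seed=1))   # DIF-generated amplitudes
fits = {"DIF": peb_fit(design_from_dataset(ds))}
for name in ("MAR", "SQU"):
    parts = []
    for seq in ds.sequences:
        params = SQUParams(P_k=seq.probs) if name == "SQU" else None
        parts.append(regressor(model_trace(name, seq, params), seq))
    fits[name] = peb_fit(build_design([np.concatenate(parts)] * ds.config.L,
                                      list(ds.Y)))

f = fits["DIF"]
print(f"group intercept {f.theta2_mean[0]:.2f} ± {f.theta2_sd[0]:.2f} uV, "
      f"slope {f.theta2_mean[1]:.2f} ± {f.theta2_sd[1]:.2f} uV/bit")
for name in ("MAR", "SQU"):
    bf = log_bayes_factor(fits["DIF"], fits[name])
    print(f"ln BF(DIF, {name}) = {bf.value:.1f} ({bf.label})")
```

prints

```
group intercept 3.58 ± 0.25 uV, slope 0.76 ± 0.25 uV/bit
ln BF(DIF, MAR) = 9.3 (very strong)
ln BF(DIF, SQU) = 22.1 (very strong)
```

The data were generated with group intercept 3.5 μV and slope 1.0 μV/bit
under the DIF observer; the fit recovers the group parameters within their
posterior uncertainty, and the evidence correctly prefers the generating
model over both competitors on 16 × 384 trials.

The same workflow is available from the shell:

```sh
p3dif simulate --seed 1 --out data/
p3dif compare --data data/ --models DIF,MAR,SQU --out results/
p3dif gridsearch --data data/ --resolution 20 --out search/
p3dif tree --data data/ --order 3 --out trees.csv
```

Every run writes a manifest (config hash, seed, version) next to its
outputs, and identical seeds give byte-identical files.

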