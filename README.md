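# mmnsim

Spiking-network simulation of auditory novelty detection (mismatch
negativity-like deviance detection), built around a clock-driven leaky
integrate-and-fire engine with conductance-based AMPA/NMDA/GABA
synapses, release-fraction short-term depression, transmission delays,
and pair-based STDP.

The package provides:

* **`mmnsim.core`** — the simulation engine (numba-accelerated
  exponential-Euler integration, default dt = 0.1 ms), Bernoulli
  connectivity, heterogeneity sampling, and text-serializable spike
  records.
* **`mmnsim.stimuli`** — oddball stimulus sequences (frequency,
  omission, duration and inverse-duration deviants, roving,
  double-deviant, random control; 50-ms short / 100-ms long tones at
  2 Hz by default) and phase-locked input trains with per-neuron jitter.
* **`mmnsim.mmn`** — the nine-population novelty-detection network
  (ES/IS, ED/ID, ESD/EDD, EP/EP2, EO; 40 neurons each) with depressing
  projections onto the output population, plus ablation, delay, NMDA
  blockade and jitter manipulations.  `REFERENCE_PARAMS` is a calibrated
  parameter set that detects all four deviant types.
* **`mmnsim.metrics`** — deviance index (deviant-minus-standard rate
  over 0.5-s peristimulus windows), the model acceptance criterion
  (>= 80% of output neurons firing for the deviant, deviant spikes
  >= 6x the standard average), Gaussian rate curves, ISI burst
  detection, entrainment scoring, and rank-sum group statistics with
  Bonferroni correction.
* **`mmnsim.gridsearch`** — the full-factorial eight-axis parameter
  search (5x5x5x7x2x6x2x2 = 42,000 combinations) with acceptance
  filtering, per-protocol accepted sets and their intersection;
  checkpointed and resumable.
* **`mmnsim.synfire`** — a 70-population synfire chain (50 neurons per
  population, p = 0.5, 5-ms feedforward delays) with STDP feedback
  synapses onto the base population that entrains to 2-Hz stimulation
  and keeps firing rhythmically after stimulus cessation.
* **`mmnsim.scz`** — f-I curves and AUC-based excitability mapping onto
  membrane capacitance, disease-associated perturbations (capacitance
  increase, reduced excitatory conductance), the cortical output
  population (CO) fitted to standard/deviant firing rates, and a
  synthetic subject-AUC cohort generator.

## CLI

```bash
mmn protocol make --kind omission --out omission.json
mmn run --protocol frequency_deviant --seed 7 --out run1/
mmn run --protocol omission --ablate EP --ablate EP2 --out run2/
mmn grid --subsample 200 --out grid_out/
mmn entrain --rate 2.0 --aplus 0.029 --alpha -1.2 --reps 20 --out entrain/
mmn perturb --mode conductance --magnitude 0.81 --out pert/
mmn fit-co --out fit_co.csv
mmn report run1/results.json run2/results.json --out summary.csv
```

## Units

Time in ms, potentials in mV, conductances in nS, capacitances in pF,
currents in nA at the API surface.  `Cm/g_leak` is then directly the
membrane time constant in ms.
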