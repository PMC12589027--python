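# critsnn

A noise-driven spiking-neural-network simulator with the analysis
pipeline used to study self-organised criticality, excitation–inhibition
(EI) balance and stimulus-specific fading memory:

* **Model** — escape-noise leaky integrate-and-fire neurons with
  conductance-based synapses, Tsodyks–Markram short-term depression,
  and dual spike-timing-dependent plasticity (asymmetric excitatory
  window, symmetric "Mexican-hat" inhibitory window). 80 excitatory +
  20 inhibitory neurons, fully connected, weights grown from zero under
  pure noise drive.
* **Protocols** — long noise-driven development, repetitive patterned
  stimulation (4 spatial patterns × 900 pulses at 1 Hz in random
  order), spontaneous activity with hourly 10-minute monitoring, and
  evoked-response trial measurement with per-trial noise seeds.
* **Analyses** —
  * avalanche segmentation by the mean-inter-spike-interval rule,
    log–log power-law fitting with automatic lower-cutoff selection,
    and the signed one-sided criticality index **ΔCr**;
  * EI balance: zero-lag correlation of per-neuron excitatory and
    inhibitory synaptic-current traces, input magnitudes and I/E ratio;
  * fading-memory decoding: 20-ms population rate vectors, sparse
    (L1) multinomial logistic regression with 10-split stratified
    shuffle cross-validation, exact-binomial leave-one-out decay time,
    and paired condition comparisons (Wilcoxon / Friedman);
  * in-vitro-style preprocessing (1-ms stimulation-artifact exclusion,
    saturated-electrode exclusion).
* **Synthetic data** — seeded generators with known ground truth for
  every analysis stage: Galton–Watson avalanche trains with a chosen
  branching ratio, labeled evoked responses with controllable class
  separation, current-trace pairs with a target correlation, and
  MEA-like recordings with injected stimulation artifacts.

## Command-line interface

```bash
critsnn develop  --preset crt --duration-h 72 --out-prefix runs/dev
critsnn stimulate --preset crt --checkpoint runs/dev.state.h5 --out-prefix runs/stim
critsnn monitor  --preset crt --checkpoint runs/stim.state.h5 --minutes 10 --out-prefix runs/mon
critsnn evoked   --preset crt --checkpoint runs/stim.state.h5 --n-trials 40 --out runs/trials.h5
critsnn avalanche runs/mon.spikes.tsv --s-max 100 --out runs/avalanche.json
critsnn decode   --trials runs/trials.h5 --bin-ms 20 --out runs/decoding.json
critsnn full-experiment --preset crt --scaled --out-dir runs/full
```

Presets `crt`, `sub` and `sup` select the STDP balance parameters
(β_E, β_I) = (1, 1.15), (1.2, 1.2) and (1, 1) producing critical,
subcritical and supercritical networks. Configuration files (YAML/JSON)
may override any model, plasticity or protocol parameter; missing
fields take the reference defaults. Spike trains are TSV
(`time_s`, `unit_id`) with a JSON sidecar of unit metadata; state
checkpoints and trial sets are HDF5; analysis results and run manifests
are JSON.

## Full-scale behaviour (not CI)

The reference behaviour at full scale: the critical preset
self-organises into burst-driven activity whose excitatory and
inhibitory input currents are tightly coupled (cross-correlation
> 0.75), the subcritical preset stays excitation-dominated
(correlation < 0.5, I/E ≈ 0), and repetitive stimulation transiently
lowers ΔCr with recovery during subsequent spontaneous activity. These
cluster-scale runs are config-selectable
(`critsnn full-experiment --full`) but are not part of the test suite.
In this implementation the subcritical and supercritical regimes
develop as described, while the critical preset's balanced state is
only transiently visited during development (it collapses into a tonic
excitation-only state after ignition); the stability analysis is
recorded in the project notes.
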