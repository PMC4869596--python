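# synchnet

Phase-synchronization brain-network analysis of epoched EEG.

`synchnet` turns multichannel Go/NoGo-style EEG epochs into per-condition
phase-synchrony networks and characterizes their small-world organization:

- **simulate** — coupled-oscillator surrogate EEG with known ground truth
  (per-band phase coupling `kappa` among chosen channel sets, phase-locked
  evoked transients, injectable artifacts, white noise);
- **preprocess** — zero-phase Butterworth filtering, mastoid re-referencing,
  moving-window/absolute/EOG artifact rejection, per-condition ERP
  subtraction (isolating induced activity), half-open window extraction;
- **spectral** — Hamming-tapered FFT band power and task-vs-baseline percent
  change;
- **phasesync** — Hilbert-transform instantaneous phase and mean-phase-
  coherence (PSI) matrices per epoch, averaged per condition;
- **network** — proportional thresholding to exactly K edges, weighted
  degree, Onnela clustering, harmonic characteristic path length, and
  gamma / lambda / sigma normalized against degree-preserving rewired nulls,
  swept over an edge-number range (default 60..180 step 20);
- **groupstats** — ROI-averaged node degree, Welch / paired t-tests, two-way
  mixed ANOVA (within: task; between: group), per-channel degree t-maps, and
  the "significant at >= 3 of 7 density levels" convention.

## Test

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the seeded acceptance properties (PSI null
calibration, graph-metric oracle equivalence, small-worldness, parameter
recovery, ANOVA type-I calibration); the rest are per-module unit and
property tests.

## CLI

```bash
synchnet simulate   --config config.yaml --seed 1 --out sim/
synchnet preprocess sim/S01.csv --config config.yaml --out pre/
synchnet power      pre/S01_preprocessed.csv --out power/
synchnet psi        pre/S01_preprocessed.csv --config config.yaml --out psi/
synchnet network    psi/S01_Go_theta_psi.csv --seed 1 --out net/
synchnet stats      results/network_metrics.csv results/roi_degree.csv --out stats/
synchnet run-all    sim/S01.csv sim/S02.csv --config config.yaml --seed 1 --out results/
```

Epoch files are either a delimited long table
(`subject, group, condition, epoch, channel, time_ms, value_uV`) or EDF+
(one data record per epoch, condition labels in the annotation channel).
Configuration is YAML with `simulation:` and `pipeline:` sections mirroring
`synchnet.config.SimulationConfig` / `PipelineConfig`; every analysis
constant (bands, artifact thresholds, windows, K sweep, number of rewired
nulls) is a config default, never hard-coded.

## Library example

```python
from synchnet import (
    PipelineConfig, generate_epochs, run_pipeline, default_montage,
)
from synchnet.config import nogo_like_config

epochs, truth = generate_epochs(nogo_like_config(kappa=0.6, seed=1))
result = run_pipeline(PipelineConfig(seed=1), [epochs], default_montage())
print(result.network_metrics.head())
```
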