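# glica

Analysis toolkit for synaptic integration and calcium signalling in
non-spiking glial cells. It reimplements, as a tested and reusable
pipeline, the computational workflow of a mock-PSP / two-photon
calcium-imaging study:

- **`glica.stim_waveforms`** — injected-current stimulus construction:
  quantal EPSC templates (difference of exponentials, 12 pA default),
  regular 100 Hz trains, Gaussian-dispersed quantal barrages (25 ms SD
  default), and `Q * R_in` stimulus-strength normalization in multiples of
  250 MOhm.
- **`glica.synthetic_data`** — forward models standing in for slice
  recordings: a single-compartment membrane with phenomenological A-type
  K, fast Na, delayed-rectifier K and low-threshold Ca conductances
  (exponential-Euler at 20 kHz), calcium/dye-fluorescence dynamics with
  seconds-scale extrusion, a Poisson-noise two-channel line-scan/frame
  renderer with laser-off dark lines, and a dataset generator emitting
  ground-truth manifests.
- **`glica.ephys_analysis`** — PSP amplitude/half-width metrics with
  sub-sample half-amplitude crossings, ratios against scaled passive
  responses, train broadening, spikelet detection, responding-fraction
  curves, Fisher exact / paired-t / Wilcoxon-Mann-Whitney / Pearson
  statistics.
- **`glica.imaging_analysis`** — background subtraction from laser-off
  lines, line-scan profiles, sliding-average smoothing, separable Gaussian
  filtering, dF/F and dG/R window quantification, and mono/bi-exponential
  decay fitting with nested F-test model selection (amplitude-weighted
  tau).
- **`glica.detection`** — scaled-template detection: least-squares
  scale+offset fit, criterion = scale / standard error with response
  threshold 3.0, and sliding-template onset estimation on 1 kHz resampled
  profiles.
- **`glica.diffusion`** — buffered-calcium diffusion: differential binding
  ratios, apparent diffusion coefficient (95 um^2/s with the default dye
  and endogenous-buffer constants), and the two-regime purely diffusional
  propagation front with its numerical inverse.

The channel kinetics and photon-budget defaults in `synthetic_data` are
declared model fiction, calibrated only against qualitative behaviours
(half-width shortening above -60 mV, amplitude balance of Na and A-type
currents, activity-dependent train broadening, spikelets without the
A-current); see `tests/test_calibration.py`.

## Command line

A single `glica` entry point exposes one sub-group per module:

```sh
glica stim quantal --out quantal.csv
glica stim gaussian --n-syn 1000 --q-per-syn 10 --seed 1 --out train.csv
glica synth generate --config cfg.yaml --seed 1 --out dataset/
glica ephys metrics --in voltage.csv --stim-onset 0.02
glica ephys fisher --a 9 --b 31 --c 22 --d 21
glica imaging dff --green scan.tif --line-rate 200 --stim-onset 0.5
glica imaging decay --profile profile.csv
glica detect classify --profile profile.csv --template template.csv
glica detect onset --profile profile.csv --template template.csv
glica diffusion dapp
glica diffusion front --t 0.316
glica diffusion delay --distance 30
```

Traces are two-column CSV (`time_s,value_<unit>`); scan images are
single-channel TIFFs (line-scans: rows = lines in time; frame series:
pages = frames).

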