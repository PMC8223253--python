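# scalphfo

Scalp-EEG high-frequency-oscillation (HFO) analysis as a tested pipeline:

- **`scalphfo.synth`** — synthetic annotated EEG cohorts: 19-channel 1/f
  background, injected gamma (40–80 Hz) / ripple (80–200 Hz) / fast-ripple
  (200–300 Hz) bursts, sleep spindles, spike + slow-wave discharge
  complexes, and configurable multiplicative (group × state × band) energy
  factors with full ground truth.
- **`scalphfo.eeg_io`** — 16-bit EDF read/write (plus a plain-text
  annotation sidecar), average-reference and longitudinal-bipolar montages,
  zero-phase Butterworth band filters, state-labelled segment extraction.
- **`scalphfo.detect`** — HFO event detection: band-passed Hilbert
  envelope, mean + k·SD background threshold with one re-estimation pass,
  ≥ 4 consecutive regular oscillation peaks, and the ≥ 2-events-per-5-min
  rate rule.
- **`scalphfo.energy`** — complex-Morlet time–frequency power
  (amplitude-calibrated: a unit sinusoid yields unit peak power at any
  frequency), average band energy per subject × channel × state × band,
  responsible-lead ranking with lobe summaries.
- **`scalphfo.based`** — BASED severity scoring (2–5) from discharge
  density and bipolar slow-wave amplitude, treatment-efficacy
  classification (effective ⇔ controlled/improved AND BASED ≤ 3), and the
  efficiency percentage.
- **`scalphfo.stats`** — aligned-rank-transform (ART) mixed factorial
  ANOVA with split-plot error terms, Holm step-down correction, post hoc
  pairwise cell contrasts, median/IQR description, and a normality-gated
  paired comparison (Shapiro–Wilk → paired t or Wilcoxon).

## CLI

```bash
# generate a cohort (EDF + annotation sidecars + ground-truth JSON)
synth-cohort --config cohort.yaml --out cohort/ --seed 1

# re-reference / filter / segment one recording
eeg-prep --in rec.edf --montage average --state SED --out prepped.edf

# detect HFO events (TSV: channel, band, onset, offset, cycles, amplitude)
hfo-detect --in prepped.edf --band gamma --amp-factor 3 --min-rate 2 --out events.tsv

# band-energy table per subject x channel x state x band
hfo-energy --in cohort/ --bands gamma,ripple,fr --out energies.tsv

# ART ANOVA + Holm-corrected post hoc contrasts
hfo-stats --in energies.tsv --between group --within state,band \
          --posthoc state,band --out results/
```

Example `cohort.yaml`:

```yaml
n_subjects_per_group: 10
channels: [C3, C4, O1, O2]
interictal_duration_s: 30.0
states_per_group:
  IS: [wake, sleep, PreS, S, PostS]
  NC: [wake, sleep]
band_effects:
  - {group: IS, state: sleep, band: gamma, factor: 2.0}
```

## Notes

- All randomness flows from integer seeds; identical config + seed gives
  bit-identical cohorts.
- Detection thresholds are declared, tunable operationalizations of a
  visual marking rule (`DetectorParams`), not published constants.
- Binary EDF files are produced only at run/test time; the repository
  itself is text-only.
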