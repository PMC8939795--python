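# File formats

## Circuit YAML

```yaml
populations:
  M2.SP: {sign: excitatory, tau: 0.006, gain: 40.0, slope: 1.5,
          noise_sd: 0.0, noise_scale: 1.0}
  # ... one entry per population (M2.SP, M2.MP, M2.DP, M2.II, STR, GPe,
  #     STN, GPi, Thal)
inter:                      # source-level long-range connections
- {from: GPe, to: STN, weight: -12.0, delay: 0.003}   # seconds
intra:                      # M2 microcircuit (from_pop, to_pop, weight)
- {from: M2.MP, to: M2.SP, weight: 18.0}
observation:                # observed population per source
  M2: M2.SP
```

Units: `tau`, delays in seconds; `gain` in mV; `slope` in mV^-1;
`noise_sd` in input units; weights dimensionless and signed by the source's
neurotransmitter type.

## Time-series HDF5 (`cbgt simulate` / `cbgt stimulate`)

* `/data`  — float64, channels x samples
* `/labels` — channel names (bytes)
* `/fs` — sampling rate, Hz
* attribute `meta` — JSON (seed, dt, burn-in, config hash, stimulated flag)
* optional group `/stimulation`: `stim_onsets` (s), `waveform` (injected
  voltage per output sample), `phase_estimates` (rad per update),
  `update_times` (s), `gate_log` (bool, update x [envelope, refractory]),
  attributes `fs` and `config` (JSON ControllerConfig).

Every CLI output gains a `<file>.provenance.json` sidecar with the package
version, seed, configuration and its hash.

## Feature CSV (ABC target format)

Tidy long format with columns `freq, channel, feature, value`; `feature`
is one of `psd`, `coh`, `npd_forward`, `npd_reverse`, `npd_zero_lag`, and
`channel` is a source name or `A:B` pair.  `cbgt fixtures --kind
abc_target` writes this format; `cbgt fit --target` reads it.

## Analysis tables

* Burst table CSV: `onset, offset, duration, band_low, band_high, threshold`.
* PLV table CSV: `a, b, plv, band_low, band_high` (upper triangle).
* ARC CSV: `phase_deg, signal, band, pct_change, n_epochs`, where `signal`
  is a source name or `coh:A:B`.
* Recovery tables CSV: `strength?, phase_deg, state, feature_set, r2,
  best_state?`.
* State YAML (`cbgt states`): per state name, `pathway`, `multiplier` and
  the calibration record (target ratio, achieved ratio, tolerance, seeds).
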