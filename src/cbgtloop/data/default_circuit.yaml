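# Packaged fitted-surrogate parameterization of the CBGT circuit.
#
# Tuned to the lower-beta-dominant regime: the STN/GPe loop (taus 4-5 ms,
# 3 ms loop delays, +-12 coupling) resonates in beta1 (14-21 Hz); the
# cortical SP<->II loop resonates in upper beta so that strengthening the
# hyperdirect pathway raises broadband beta, while the pallido-subthalamic
# weight acts as a broadband gain on STN beta power.  Cortical populations
# carry self-inhibition matched to their excitatory input so each operates
# near the sensitive point of its activation function.
populations:
  M2.SP: {sign: excitatory, tau: 0.006, gain: 40.0, slope: 1.5, noise_sd: 0.0, noise_scale: 1.0}
  M2.MP: {sign: excitatory, tau: 0.008, gain: 40.0, slope: 1.5, noise_sd: 0.3, noise_scale: 1.0}
  M2.DP: {sign: excitatory, tau: 0.010, gain: 40.0, slope: 1.5, noise_sd: 0.0, noise_scale: 1.0}
  M2.II: {sign: inhibitory, tau: 0.006, gain: 50.0, slope: 1.5, noise_sd: 0.0, noise_scale: 1.0}
  STR:   {sign: inhibitory, tau: 0.010, gain: 50.0, slope: 1.5, noise_sd: 0.1, noise_scale: 1.0}
  GPe:   {sign: inhibitory, tau: 0.005, gain: 50.0, slope: 1.5, noise_sd: 0.1, noise_scale: 1.0}
  STN:   {sign: excitatory, tau: 0.004, gain: 40.0, slope: 1.5, noise_sd: 0.1, noise_scale: 1.0}
  GPi:   {sign: inhibitory, tau: 0.010, gain: 50.0, slope: 1.5, noise_sd: 0.1, noise_scale: 1.0}
  Thal:  {sign: excitatory, tau: 0.008, gain: 40.0, slope: 1.5, noise_sd: 0.1, noise_scale: 1.0}
inter:
- {from: Thal, to: M2, weight: 2.0, delay: 0.008}
- {from: M2, to: STR, weight: 1.5, delay: 0.006}
- {from: STR, to: GPe, weight: -1.5, delay: 0.006}
- {from: STN, to: GPe, weight: 12.0, delay: 0.003}
- {from: M2, to: STN, weight: 12.0, delay: 0.003}
- {from: GPe, to: STN, weight: -12.0, delay: 0.003}
- {from: STR, to: GPi, weight: -1.0, delay: 0.008}
- {from: STN, to: GPi, weight: 1.5, delay: 0.004}
- {from: GPi, to: Thal, weight: -1.5, delay: 0.004}
intra:
- {from: M2.MP, to: M2.SP, weight: 18.0}
- {from: M2.SP, to: M2.DP, weight: 18.0}
- {from: M2.SP, to: M2.II, weight: 18.0}
- {from: M2.II, to: M2.SP, weight: -18.0}
- {from: M2.SP, to: M2.SP, weight: -1.0}
- {from: M2.MP, to: M2.MP, weight: -2.0}
- {from: M2.DP, to: M2.DP, weight: -18.0}
- {from: M2.II, to: M2.II, weight: -18.0}
observation:
  M2: M2.SP
  STR: STR
  GPe: GPe
  STN: STN
  GPi: GPi
  Thal: Thal
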