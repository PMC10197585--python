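# Scaled-down simulation study: 90/60/45-degree crossings under the
# multi-shell protocol at three SNR levels, super-CSD lmax=12, 25 reps per
# condition. Run with: mccsd simulate --config examples/study.yaml --out-dir out/
conditions:
  - {n_fibers: 2, crossing_angles: [90.0], iso_vf: 0.4, snr: 20.0, protocol: P3, n_reps: 25, seed: 101, lmax: 12, super_csd: true}
  - {n_fibers: 2, crossing_angles: [90.0], iso_vf: 0.4, snr: 30.0, protocol: P3, n_reps: 25, seed: 102, lmax: 12, super_csd: true}
  - {n_fibers: 2, crossing_angles: [90.0], iso_vf: 0.4, snr: 40.0, protocol: P3, n_reps: 25, seed: 103, lmax: 12, super_csd: true}
  - {n_fibers: 2, crossing_angles: [60.0], iso_vf: 0.4, snr: 30.0, protocol: P3, n_reps: 25, seed: 104, lmax: 12, super_csd: true}
  - {n_fibers: 2, crossing_angles: [45.0], iso_vf: 0.2, snr: 30.0, protocol: P3, n_reps: 25, seed: 105, lmax: 12, super_csd: true}
  - {n_fibers: 3, crossing_angles: [90.0, 60.0], iso_vf: 0.2, snr: 30.0, protocol: P3, n_reps: 25, seed: 106, lmax: 12, super_csd: true}
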