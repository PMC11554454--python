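# Demo cohort for the worked analysis: a 19-channel, 250 Hz miniature of
# the study design (healthy controls vs depressed patients whose
# microstate-D dwell time is reduced, patients split into acupuncture
# responders and non-responders through their HAMD-24 outcomes).
seed: 7
cohort:
  n_channels: 19
  sampling_rate: 250.0
  recording_length_s: 60.0
  subject_variability_cv: 0.1
  groups:
    - name: HC
      n_subjects: 10
      hamd_baseline: [2.6, 1.0]
      hamd_post: [2.6, 1.0]
    - name: PSD_RP
      n_subjects: 26
      dwell_effect: [1.0, 1.0, 1.0, 0.8]
      hamd_baseline: [20.0, 2.0]
      hamd_post: [8.0, 3.0]
    - name: PSD_NRP
      n_subjects: 14
      dwell_effect: [1.0, 1.0, 1.0, 0.55]
      hamd_baseline: [20.0, 2.0]
      hamd_post: [17.0, 2.0]
segment:
  n_peaks: 500
predict:
  n_folds: 4
  n_rounds: 200
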