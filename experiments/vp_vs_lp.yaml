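# Contralateral VP-vs-LP comparison: n=5 lobes per group, 90 h culture,
# morphometry at 10-h marks, paired t-test on total tip number.
name: vp_vs_lp
seed: 1
metric: total_tips
times: [0, 10, 20, 30, 40, 50, 60, 70, 80, 90]
imaging: false
pairing: true
groups:
  VP: {preset: vp, treatment: control, n: 5}
  LP: {preset: lp, treatment: control, n: 5}
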