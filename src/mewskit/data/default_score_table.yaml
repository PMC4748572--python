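# Default MEWS banding rubric.  Bands are inclusive upper bounds at the
# parameter's granularity (1 mmHg / 1 bpm / 1 breath/min / 0.1 degC);
# upper: null marks the open top band.  Maximum total: 15.
sbp:
  - {upper: 70, points: 3}
  - {upper: 80, points: 2}
  - {upper: 100, points: 1}
  - {upper: 199, points: 0}
  - {upper: null, points: 2}
hr:
  - {upper: 40, points: 2}
  - {upper: 50, points: 1}
  - {upper: 100, points: 0}
  - {upper: 110, points: 1}
  - {upper: 129, points: 2}
  - {upper: null, points: 3}
rr:
  - {upper: 8, points: 2}
  - {upper: 14, points: 0}
  - {upper: 20, points: 1}
  - {upper: 29, points: 2}
  - {upper: null, points: 3}
temp:
  - {upper: 35.0, points: 2}
  - {upper: 38.4, points: 0}
  - {upper: null, points: 2}
consciousness: {alert: 0, voice: 1, pain: 2, unresponsive: 3}
concern: {"no": 0, "yes": 1}
missing_policy: zero
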