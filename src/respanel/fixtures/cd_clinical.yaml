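# Baseline clinical covariates for the Crohn's disease test cohort:
# per-group mean/SD of the published cohort summary, with physiological
# truncation bounds for the truncated-normal simulator.
disease: CD
cohort: test
covariates:
  age:
    responder: {mean: 36.2, sd: 14.6}
    nonresponder: {mean: 36.0, sd: 15.4}
    bounds: [18.0, 90.0]
  CDAI:
    responder: {mean: 319.6, sd: 41.3}
    nonresponder: {mean: 351.5, sd: 33.1}
    bounds: [0.0, 600.0]
  CRP:
    responder: {mean: 22.7, sd: 20.2}
    nonresponder: {mean: 13.5, sd: 28.9}
    bounds: [0.0, .inf]
  hemoglobin:
    responder: {mean: 125.1, sd: 17.6}
    nonresponder: {mean: 120.6, sd: 27.6}
    bounds: [40.0, 200.0]
  leukocytes:
    responder: {mean: 9.0, sd: 3.3}
    nonresponder: {mean: 8.0, sd: 3.1}
    bounds: [0.0, .inf]
  neutrophils:
    responder: {mean: 70.0, sd: 8.9}
    nonresponder: {mean: 74.5, sd: 8.9}
    bounds: [0.0, 100.0]
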