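# Baseline clinical covariates for the rheumatoid arthritis test cohort:
# per-group mean/SD of the published cohort summary ("nonresponder" pools
# non- and moderate responders, i.e. ACR0/ACR20), with truncation bounds.
disease: RA
cohort: test
covariates:
  age:
    responder: {mean: 44.3, sd: 9.3}
    nonresponder: {mean: 47.0, sd: 10.7}
    bounds: [18.0, 90.0]
  DAS28:
    responder: {mean: 5.6, sd: 0.3}
    nonresponder: {mean: 5.2, sd: 0.7}
    bounds: [0.0, 9.4]
  HAQ:
    responder: {mean: 1.2, sd: 0.7}
    nonresponder: {mean: 2.0, sd: 0.6}
    bounds: [0.0, 3.0]
  CRP:
    responder: {mean: 16.8, sd: 18.3}
    nonresponder: {mean: 28.3, sd: 23.8}
    bounds: [0.0, .inf]
  DMARDs:
    responder: {mean: 2.8, sd: 0.9}
    nonresponder: {mean: 2.6, sd: 0.7}
    bounds: [0.0, 10.0]
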