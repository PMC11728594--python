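# Default Monte Carlo input distributions for the drinking-water pathway.
# cw is a placeholder: in practice it is replaced per compound by the lognormal
# fitted to the site concentration field (see gwrisk.uncertainty.default_specs).
cw:
  family: lognormal
  mu: 0.0
  sigma: 1.0
gwcr:
  family: lognormal
  mu: 0.8713
  sigma: 0.3
  lower: 0.5
  upper: 8.0
ef:
  family: triangular
  left: 200.0
  mode: 365.0
  right: 365.0
ed:
  family: triangular
  left: 1.0
  mode: 24.0
  right: 40.0
bw:
  family: normal_truncated
  mean: 60.0
  sd: 10.0
  lower: 40.0
  upper: 100.0
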