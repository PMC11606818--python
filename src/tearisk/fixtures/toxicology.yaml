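# Oral reference doses (RfD, mg/kg bw/day) and carcinogenic slope factors
# (CSF, (mg/kg bw/day)^-1) for the three metals assessed.  Cadmium has no
# published oral CSF, so carcinogenic risk is not evaluated for it.
arsenic:
  rfd: 3.0e-4
  csf: 1.5
cadmium:
  rfd: 1.0e-3
  csf: null
lead:
  rfd: 4.0e-3
  csf: 8.5e-3
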