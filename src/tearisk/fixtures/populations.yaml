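# Consumer groups: body weight (kg) and daily black-tea infusion
# consumption (L/day).  Body weights follow the study populations
# (under/over 15 years).  Daily consumption is not fixed by the source
# surveys to a single figure; these defaults are mid-range values for
# Iranian tea drinkers and every report echoes the value actually used.
children:
  bw: 50.0
  dc: 0.5
adults:
  bw: 65.0
  dc: 1.0
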