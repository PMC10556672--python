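# Trichromatic chlorophyll equations, expressed as linear coefficients on
# the turbidity-corrected absorbances A664, A647, A630 (1-cm path).
# Concentrations come out in ug/mL of extract.
acetone90:
  chl_a: {A664: 11.85, A647: -1.54, A630: -0.08}
  chl_c: {A664: -1.67, A647: -7.60, A630: 24.52}
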