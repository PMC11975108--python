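# EXAMPLE muscle-architecture constants — representative values only.
#
# Optimal lengths and maximal forces are inputs to the scaling equations and
# are not published alongside the protocol; these numbers are of the order
# used in human lower-limb musculoskeletal models and in the mouse literature.
# Replace lo_mouse_mm / fmax_mouse_mn with your own measured values
# (fmax_mouse_mn comes from each muscle's pre-force-frequency maximum).
soleus:
  lo_mouse_mm: 12.0
  lo_human_mm: 44.0
  fmax_human_n: 2800.0
  fmax_mouse_mn: 280.0
EDL:
  lo_mouse_mm: 12.5
  lo_human_mm: 69.0
  fmax_human_n: 350.0
  fmax_mouse_mn: 380.0
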