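{
  "_comment": "SYNTHETIC illustrative endmember map for examples and tests only. Region polygons are (delta18O, SP) vertices in per mil; real analyses must substitute literature coordinates.",
  "regions": {
    "bacterial denitrification": [[10, -10], [35, -10], [35, 0], [10, 0]],
    "fungal denitrification": [[25, 25], [45, 25], [45, 40], [25, 40]],
    "nitrification": [[15, 10], [30, 10], [30, 22], [15, 22]]
  },
  "anchor": [22.0, -4.0],
  "slope_min": 0.2,
  "slope_max": 0.6,
  "eta_sp_reduction": -6.0
}
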