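{
  "version": 1,
  "comment": "Half-range HSV threshold table (H in 0-180, S/V in 0-255). Reconstructed canonical table; the printed source table is mis-aligned (one extra H column), see docs/methods.md. Red carries two hue intervals.",
  "colors": {
    "black":  {"h": [[0, 180]],            "s": [0, 255],  "v": [0, 46]},
    "gray":   {"h": [[0, 180]],            "s": [0, 43],   "v": [46, 220]},
    "white":  {"h": [[0, 180]],            "s": [0, 30],   "v": [221, 255]},
    "red":    {"h": [[0, 10], [156, 180]], "s": [43, 255], "v": [46, 255]},
    "orange": {"h": [[11, 25]],            "s": [43, 255], "v": [46, 255]},
    "yellow": {"h": [[26, 34]],            "s": [43, 255], "v": [46, 255]},
    "green":  {"h": [[35, 77]],            "s": [43, 255], "v": [46, 255]},
    "cyan":   {"h": [[78, 99]],            "s": [43, 255], "v": [46, 255]},
    "blue":   {"h": [[100, 124]],          "s": [43, 255], "v": [46, 255]},
    "purple": {"h": [[125, 155]],          "s": [43, 255], "v": [46, 255]}
  },
  "aliases": {"ash": "gray", "young": "cyan"}
}
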