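# Van Krevelen compound-class boundary sets.
#
# Each set names ordered rules assigning a biochemical compound class to a
# formula from its O:C and H:C ratios (closed intervals; earlier rules win on
# overlap; anything unmatched is "Other").  The numeric windows are
# reconstructions of ranges commonly used in the dissolved/soil organic
# matter literature — edit or replace this file to use your own boundaries.
bs1:
  - {label: Lipid,                     oc: [0.0, 0.3],   hc: [1.5, 2.5]}
  - {label: Unsaturated hydrocarbon,   oc: [0.0, 0.125], hc: [0.8, 1.5]}
  - {label: Protein,                   oc: [0.3, 0.55],  hc: [1.5, 2.3]}
  - {label: Amino sugar,               oc: [0.55, 0.7],  hc: [1.5, 2.2]}
  - {label: Carbohydrate,              oc: [0.7, 1.5],   hc: [1.5, 2.5]}
  - {label: Lignin,                    oc: [0.125, 0.65], hc: [0.8, 1.5]}
  - {label: Tannin,                    oc: [0.65, 1.1],  hc: [0.8, 1.5]}
  - {label: Condensed aromatic,        oc: [0.0, 0.95],  hc: [0.2, 0.8]}
bs2:
  - {label: Lipid,                     oc: [0.0, 0.2],   hc: [1.7, 2.5]}
  - {label: Unsaturated hydrocarbon,   oc: [0.0, 0.1],   hc: [0.7, 1.7]}
  - {label: Protein,                   oc: [0.2, 0.6],   hc: [1.5, 2.3]}
  - {label: Carbohydrate,              oc: [0.6, 1.2],   hc: [1.5, 2.5]}
  - {label: Lignin,                    oc: [0.1, 0.6],   hc: [0.7, 1.5]}
  - {label: Tannin,                    oc: [0.6, 1.2],   hc: [0.5, 1.5]}
  - {label: Condensed aromatic,        oc: [0.0, 1.2],   hc: [0.2, 0.7]}
bs3:
  - {label: Lipid,                     oc: [0.0, 0.3],   hc: [1.34, 2.5]}
  - {label: Carbohydrate,              oc: [0.55, 1.5],  hc: [1.34, 2.5]}
  - {label: Protein,                   oc: [0.3, 0.55],  hc: [1.34, 2.5]}
  - {label: Lignin,                    oc: [0.08, 0.65], hc: [0.7, 1.34]}
  - {label: Tannin,                    oc: [0.65, 1.1],  hc: [0.53, 1.34]}
  - {label: Unsaturated hydrocarbon,   oc: [0.0, 0.08],  hc: [0.7, 1.34]}
  - {label: Condensed aromatic,        oc: [0.0, 0.95],  hc: [0.2, 0.7]}
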