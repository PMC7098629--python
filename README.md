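# ftmspeaks

Exploratory analysis of formula-assigned FT-MS peak lists in Python.

Ultra-high-resolution mass spectrometry (FT-MS / FT-ICR-MS) of complex
organic mixtures — soil and aquatic extracts, plant material, petroleum —
yields peak lists of thousands of exact masses per sample, many of which can
be assigned a unique molecular formula over C, H, N, O, S, P. `ftmspeaks` is
for the scientist who receives such formula-assigned peak lists (the output
of upstream peak picking and formula-assignment tools) and needs to explore,
filter, compare and visualize them reproducibly: what compounds are present,
how oxidized or aromatic are they, and which are unique to one experimental
group?

## What it computes

A study is carried as a `PeakDataset` built from three tables: a peak × sample
intensity matrix, a sample metadata table, and a peak annotation table with
formulas or element counts (zero or missing intensity means "not observed").
On top of that, the package provides:

- **Chemical property calculators** per formula C_c H_h N_n O_o S_s P_p:
  - element ratios O:C, H:C, N:C, P:C, N:P;
  - Kendrick mass `KM = m · nominal(base)/exact(base)` and defect
    `KMD = ⌈KM⌉ − KM` for base units CH₂ (default), CO₂, O₂, CHO — members
    of a homologous series share one defect;
  - nominal oxidation state of carbon,
    `NOSC = 4 − (4c + h − 3n − 2o + 5p − 2s)/c`, in [−4, 4] from methane to CO₂;
  - Cox Gibbs free energy of the carbon oxidation half reaction,
    `ΔG°cox = 60.3 − 28.5 · NOSC` (kJ per mol C);
  - aromaticity index `AI = (1 + c − o − s − h/2)/(c − o − s − n − p)` and its
    modified form discounting half the oxygen, both clamped at 0;
  - double bond equivalents `DBE = 1 + c − h/2 + n/2 + p/2` and DBE − O;
  - elemental-composition classes ("CHO", "CHNO", ...) and van Krevelen
    compound classes (lipid, protein, lignin, ...) from configurable
    O:C × H:C boundary sets.
- **Filters** (mass window, minimum observation count, formula-assigned,
  annotation-column ranges/categories, sample subsets) that are previewed —
  counts and plot-ready histograms — before being applied.
- **Group comparison**: per-group presence summaries and a qualitative
  two-group uniqueness call, by thresholds or by the likelihood-ratio
  **G-test** on the 2×2 present/absent × group table,
  `G = 2 Σ O ln(O/E)` referred to χ²₁.
- **Plot data + rendering**: van Krevelen, Kendrick, density, scatter and
  summary figures, each backed by a plain table (a pure function of the
  data), plus per-subset cognostics tables for sorting small multiples.
- **Formula-keyed mapping** of peaks to a user-supplied
  compound → reaction → pathway database.
- **A synthetic-data generator** that emulates a grouped FT-MS study with
  known ground truth, so every method is testable without downloads.

## Worked example

```python
import ftmspeaks as fp

# generate a small synthetic study: 4 groups of 5 samples, 2,000 peaks
ds, truth = fp.synthetic_dataset(fp.SynthSpec(seed=7))
print(ds.summarize())

# trusted mass range, then require observation in >= 2 samples and a formula
for spec in [fp.make_filter("mass", min_mass=200, max_mass=900),
             fp.make_filter("molecule", min_num=2),
             fp.make_filter("formula")]:
    ds = fp.apply_filter(spec, ds)
    print(f"after {spec.describe()}: {ds.n_peaks} peaks")

# chemical properties and a two-group uniqueness comparison
ds = fp.compound_calcs(ds, ["calc_element_ratios", "calc_nosc", "calc_kendrick"])
cmp_ = fp.compare_groups(ds, "G1", "G2", method="gtest", pvalue=0.05)
print(cmp_.table["verdict"].value_counts())
```

prints

```
Samples               20
Peaks                 2000
Assigned formulae     1005
Missing values (%)    81.72
  group G1            5
  ...
after mass(max_mass=900, min_mass=200): 1671 peaks
after molecule(min_num=2): 1504 peaks
after formula(): 753 peaks
verdict
observed_in_neither    645
observed_in_both        42
unique_to_g2            35
unique_to_g1            31
```

The summary says 20 samples share 2,000 aligned peaks, about half of them
formula-assigned, with ~82% of matrix cells absent (a peak is typically seen
in a few samples only). The filter cascade keeps peaks in the trusted
200–900 Da range, observed at least twice, with a formula. The comparison
then classifies each surviving peak: most are below the presence threshold
("more than half the samples") in both groups; 31 and 35 peaks are called
unique to groups G1 and G2 respectively at G-test p < 0.05.

The same workflow is available from the shell via the `ftmspeaks` CLI
(`synth`, `summarize`, `calc`, `filter`, `compare`, `map`, `plot`
subcommands); run `ftmspeaks --help`.

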