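# Methods

This note documents the models, conventions and numerical choices behind
`ftmspeaks`, in the order a study flows through the package.

## The three-table data model

A study is a peak × sample intensity matrix (`e_data`), a sample metadata
table (`f_data`) and a peak annotation table (`e_meta`) sharing keys: every
annotation row matches a peak row, and the sample-metadata keys equal the
intensity matrix's sample columns. Validation enforces unique peak ids,
non-negative intensities, and consistency between formula strings and
element-count columns (whichever is absent is derived from the other; both
together are cross-checked).

**Absence semantics.** An intensity of zero and a missing cell both mean the
peak was not observed in that sample; they are normalized to a single absent
sentinel. On the intensity and presence/absence scales that sentinel is 0;
log transforms map it to NaN (log of a non-observation is undefined, not
−∞). Percent missing is therefore a property of the raw matrix and is
invariant under scale transforms.

**Scale transforms** (log2 — the default for intensity profiles — log10,
natural log, presence/absence) always start from the retained raw matrix,
never from an already-transformed one, so transforms cannot compound.
Reverting is re-deriving from the original object.

**Isotope-flagged peaks** (e.g. ¹³C peaks marked by the assignment tool) are
retained in the matrix — they are real observations — but excluded from
everything formula-based: calculators, class assignment, the
formula-assigned count, the formula filter, and database mapping. An
isotopic peak duplicates the chemistry of its monoisotopic parent, and
counting it would double-weight that formula.

**Groups** come from one or two sample-metadata columns; two-effect labels
are joined with `_` and distinct effect combinations colliding onto one
label are rejected rather than silently merged.

## Chemical property calculators

All properties are closed-form functions of the element counts
(and the observed mass, for Kendrick quantities); peaks without a usable
formula get missing values, never zeros.

- Element ratios O:C, H:C, N:C, P:C, N:P. N:P is missing (not infinite)
  when P = 0.
- Kendrick: `KM = m · nominal/exact` with base-unit mass pairs
  CH₂ = (14, 14.01565), CO₂ = (44, 43.98983), O₂ = (32, 31.98983),
  CHO = (29, 29.00274). The defect is `⌈KM⌉ − KM` ∈ [0, 1) — the convention
  under which a homologous series shares one defect value — with the
  round-based alternative (`round(KM) − KM` ∈ [−0.5, 0.5]) available as an
  option, since both are in common use. A 10⁻⁹ rounding guard keeps the
  defect of an exactly-integer Kendrick mass at 0 instead of flipping to ~1
  through float noise.
- `NOSC = 4 − (4C + H − 3N − 2O + 5P − 2S)/C`. The familiar [−4, 4] range
  (methane to CO₂) is a property of redox-plausible organic formulas: on the
  full CHO grid with H ≤ 2C+2 and O ≤ 2C it holds exactly, but heteroatom-rich
  corner cases (e.g. C₂H₁N₂S₂) can leave it. The tests pin the CHO-grid bound
  and check generated organic-matter-like formulas empirically.
- `ΔG°cox = 60.3 − 28.5 · NOSC` kJ (mol C)⁻¹. The intercept and slope are the
  standard-state constants of the carbon-oxidation half-reaction regression
  used in the biogeochemistry literature; both live in one constants module
  and are deliberately easy to change.
- Aromaticity index `(1 + C − O − S − H/2)/(C − O − S − N − P)` and the
  modified form with O discounted by half. A non-positive numerator or
  denominator carries no aromaticity information, so such values clamp to 0;
  the index is never negative. Note the O-discount moves the index toward 1
  (ai_mod ≥ ai only where ai ≤ 1).
- `DBE = 1 + Σ nₑ(vₑ − 2)/2` with default covalences C=4, H=1, N=3, P=3
  (O and S at 2 contribute nothing), reducing to `1 + C − H/2 + N/2 + P/2`;
  `DBE−O` subtracts the oxygen count. Covalences are caller-overridable.
- Elemental-composition classes concatenate the present element symbols in
  the fixed order C, H, N, O, S, P.

**Compound-class boundary sets.** Van Krevelen class windows are data, not
code: three bundled YAML sets (`bs1`/`bs2`/`bs3`) list ordered rules
`(label, O:C interval, H:C interval)` with closed bounds, first match
winning, `"Other"` as fallback. The shipped numeric windows are
reconstructions of ranges commonly used for dissolved/soil organic matter
(lipid, protein, amino sugar, carbohydrate, lignin, tannin, condensed
aromatic, unsaturated hydrocarbon); users with a preferred scheme should
supply their own file with the same schema.

## Filters

Filters are immutable declarative specs, previewed before application:
preview returns retained/removed counts (plus a mass histogram or a
retained-vs-minimum-count curve) without touching the dataset, and apply is
guaranteed to keep exactly the previewed peaks. All numeric bounds are
closed intervals; "observed" means a positive, non-missing intensity. A
filter that would empty the dataset is rejected with its report attached.
Sample subsetting removes columns (and metadata rows) instead of peaks and
never renormalizes intensities.

## Group summaries and the two-group comparison

`summarize_groups` counts, per peak per group, the samples in which the peak
is observed (and/or the proportion). `compare_groups` classifies each peak
for two chosen groups: presence in a group is a strict `prop > 0.5` by
default ("more than half the samples"), or a count threshold; a peak present
in both groups is `observed_in_both`, in neither `observed_in_neither`, and
a peak present in exactly one group is unique to it when the absence
criterion holds in the other — a count (`nsamps`) or proportion (`prop`)
ceiling, or significance of the **G-test**:

`G = 2 Σ O ln(O/E)` over the 2×2 present/absent × group table with
independence expecteds, `0·ln 0 := 0`, no Yates or Williams correction,
p from χ² with 1 df. Degenerate margins (present or absent everywhere) give
G = 0, p = 1. The plain LR variant is pinned deliberately: corrections trade
type-I error differently at these tiny group sizes, and the calibration test
below measures the uncorrected statistic's true behavior instead of hiding
it. No multiple-testing adjustment is applied by default (the conventional
workflow thresholds raw p at 0.05); Benjamini–Hochberg is available via
`adjust="bh"`. At n = 5 per group the χ² reference is anti-conservative —
the exact size of the nominal-0.05 test is ≈ 0.109 under a 0.5 presence
probability — so the acceptance check compares the empirical size to the
exhaustive enumeration of the null 2×2 outcome distribution, not to 0.05.

## Mapping

Peaks join a user-supplied three-relation database (compounds with
formulas; reaction membership; pathway membership) on the canonical formula
string alone — FT-MS provides no structural information, so formula-level
ambiguity (zero/one/many compounds per peak) is surfaced, not resolved, and
mass-tolerance matching is deliberately excluded. Formulas are canonicalized
on load so dialect differences never break the join. No reference database
content is bundled.

## Plot data, rendering, cognostics

Every figure is backed by a `PlotData` table built by a pure function —
double invocation yields identical tables, which the tests assert — and
rendering is deterministic (fixed draw order, salted SVG ids, no
timestamps), so the same data gives byte-identical SVG. Density curves use a
Gaussian kernel with the normal-reference (Silverman) bandwidth, evaluated
on a 256-point grid extended 4 bandwidths past the data range so the curve
integrates to 1 within 10⁻³; bandwidth and grid are options. Group-level
curves pool the member samples' values. Two-group comparison plots carry the
both/neither verdicts as an explicit deselection mask rather than dropping
them. Cognostics rows (peak counts, composition-class proportions,
display-kind-relevant property means) are recomputed directly from the
subset they describe.

## Synthetic data

The generator emulates a grouped FT-MS study: CHONSP formulas drawn with
element-ratio ranges typical of natural organic matter (C ∈ [4, 40],
H/C ∈ [0.5, 2.2], O ~ Binomial(C, 0.35), small N/S/P), observed masses equal
to the formula's monoisotopic mass times a 0.5 ppm Gaussian relative error
(rounded to 5 decimals, collisions nudged apart), per-peak Bernoulli
presence with log-normal intensities for present cells, and a designated
fraction of group-unique peaks whose presence probability differs between a
home group and the rest. Defaults — 2,000 peaks, 4 groups of 5 samples,
background presence 0.18 (≈ 82% missing cells), half the peaks
formula-assigned — mirror the shape of a typical two-factor soil study at a
reduced peak count that keeps the full test suite and acceptance script in
the tens of seconds. The truth table records each peak's uniqueness, home
group and true presence probabilities for recovery scoring.

What the generator does **not** emulate: mass-dependent peak density and
intensity structure, correlated presence across chemically related peaks,
alignment artifacts, or formula-assignment errors. Passing recovery tests
therefore demonstrate correctness of the bookkeeping and statistics under
the stated presence model, not performance on real soil data.

## Degenerate inputs and tie-breaks

Ratios with zero denominators are missing, never infinite; property cells
for formula-less peaks are missing, never 0. Overlapping class windows
resolve by rule order. Filters on a column with only missing values would
empty the dataset and are rejected. The comparison's verdict set is a
partition: every analyzed peak gets exactly one of the four labels.

## Known limitations

- Upstream processing (peak picking, alignment, formula assignment) is out
  of scope; inputs are always processed peak lists.
- The compound-class windows are literature-typical reconstructions, not a
  canonical standard; classifications near window edges depend on the set.
- Only qualitative (presence/absence) group comparison is provided;
  intensity-based differential abundance is deliberately excluded.
- The G-test p-values inherit the χ²₁ approximation; at ≤ 5 samples per
  group they are anti-conservative (see the calibration discussion above).
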