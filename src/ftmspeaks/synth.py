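"""Synthetic CHONSP peak-list generator with known ground truth.

Emulates the statistical shape of a formula-assigned FT-MS soil/water study:
a peak x sample matrix with group-structured presence/absence, zero-inflated
log-normal intensities, CHONSP formulas with realistic element-ratio ranges,
and observed masses equal to the formula's monoisotopic mass plus a small
ppm-scale measurement jitter.  A fraction of peaks is made group-unique (a
presence-probability gap between a home group and the rest) and recorded in
a truth table, so group-comparison methods can be scored against a known
answer.

The defaults mirror a four-group, five-samples-per-group design with ~80%
of matrix cells absent and about half the peaks formula-assigned, at a
reduced peak count (2,000) that keeps simulations quick.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import MONOISOTOPIC_MASS
from .dataset import PeakDataset, build_dataset
from .formula import ElementCounts, write_formula

__all__ = ["SynthSpec", "generate_synthetic", "synthetic_dataset"]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic study generator.

    Presence model: every peak has a background Bernoulli presence
    probability per sample; a ``unique_fraction`` of peaks instead has
    probability ``unique_presence`` in one home group and
    ``unique_absence`` elsewhere (the gap is the effect size).
    """

    n_peaks: int = 2000
    n_samples: int = 20
    n_groups: int = 4
    #: fraction of peaks with group-structured presence
    unique_fraction: float = 0.1
    #: per-sample presence probability of non-unique peaks (all groups)
    background_presence: float = 0.18
    #: presence probability of unique peaks in their home group
    unique_presence: float = 0.9
    #: presence probability of unique peaks in the other groups
    unique_absence: float = 0.02
    #: fraction of peaks given a formula in the annotation table
    formula_assignment_rate: float = 0.5
    #: fraction of formula-carrying peaks flagged as isotopic
    isotope_fraction: float = 0.0
    #: log-normal intensity parameters for present cells
    intensity_meanlog: float = 14.0
    intensity_sdlog: float = 1.0
    #: standard deviation of the relative mass error (parts per million)
    mass_jitter_ppm: float = 0.5
    seed: int = 17

    def __post_init__(self) -> None:
        if self.n_peaks < 1 or self.n_samples < 1 or self.n_groups < 1:
            raise ValueError("n_peaks, n_samples and n_groups must be >= 1")
        if self.n_samples % self.n_groups:
            raise ValueError("n_samples must divide evenly into n_groups")
        for name in ("unique_fraction", "background_presence", "unique_presence",
                     "unique_absence", "formula_assignment_rate", "isotope_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mass_jitter_ppm < 0 or self.intensity_sdlog < 0:
            raise ValueError("mass_jitter_ppm and intensity_sdlog must be >= 0")


def _random_counts(rng: np.random.Generator) -> ElementCounts:
    """One CHONSP formula with element ratios typical of natural organic matter."""
    C = int(rng.integers(4, 41))
    h_lo = max(1, math.ceil(0.5 * C))
    h_hi = min(2 * C + 2, math.floor(2.2 * C))
    H = int(rng.integers(h_lo, h_hi + 1))
    O = min(C, int(rng.binomial(C, 0.35)))
    N = min(C, int(rng.binomial(4, 0.15)))
    S = min(C, int(rng.binomial(2, 0.08)))
    P = min(C, int(rng.binomial(1, 0.08)))
    return ElementCounts(C=C, H=H, N=N, O=O, S=S, P=P)


def _monoisotopic(c: ElementCounts) -> float:
    return sum(MONOISOTOPIC_MASS[el] * getattr(c, el) for el in MONOISOTOPIC_MASS)


def generate_synthetic(
    spec: SynthSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate ``(e_data, f_data, e_meta, truth)`` tables for a spec.

    Deterministic given ``spec.seed``.  The truth table records, per peak,
    the generated formula, whether the peak is group-unique, its home group
    and its true per-group presence probabilities.
    """
    rng = np.random.default_rng(spec.seed)
    per_group = spec.n_samples // spec.n_groups
    group_labels = [f"G{i + 1}" for i in range(spec.n_groups)]
    sample_ids = [f"S{i + 1:02d}" for i in range(spec.n_samples)]
    sample_group = np.repeat(np.arange(spec.n_groups), per_group)

    counts = [_random_counts(rng) for _ in range(spec.n_peaks)]
    exact = np.array([_monoisotopic(c) for c in counts])
    jitter = rng.normal(0.0, spec.mass_jitter_ppm * 1e-6, size=spec.n_peaks)
    masses = np.round(exact * (1.0 + jitter), 5)
    # peak ids are the observed masses; nudge the rare collision apart
    seen: set[float] = set()
    for i in range(spec.n_peaks):
        while masses[i] in seen:
            masses[i] = round(masses[i] + 1e-5, 5)
        seen.add(masses[i])

    n_unique = int(round(spec.unique_fraction * spec.n_peaks))
    is_unique = np.zeros(spec.n_peaks, dtype=bool)
    unique_idx = rng.choice(spec.n_peaks, size=n_unique, replace=False)
    is_unique[unique_idx] = True
    home = np.full(spec.n_peaks, -1)
    home[unique_idx] = rng.integers(0, spec.n_groups, size=n_unique)

    probs = np.full((spec.n_peaks, spec.n_groups), spec.background_presence)
    probs[unique_idx, :] = spec.unique_absence
    probs[unique_idx, home[unique_idx]] = spec.unique_presence

    cell_probs = probs[:, sample_group]  # (n_peaks, n_samples)
    present = rng.random((spec.n_peaks, spec.n_samples)) < cell_probs
    intensities = np.where(
        present,
        rng.lognormal(spec.intensity_meanlog, spec.intensity_sdlog,
                      size=(spec.n_peaks, spec.n_samples)),
        0.0,
    )

    has_formula = rng.random(spec.n_peaks) < spec.formula_assignment_rate
    isotope = has_formula & (rng.random(spec.n_peaks) < spec.isotope_fraction)
    formulas = [write_formula(c) if f else None for c, f in zip(counts, has_formula)]

    e_data = pd.DataFrame(intensities, columns=sample_ids)
    e_data.insert(0, "peak_id", masses)
    f_data = pd.DataFrame(
        {"sample_id": sample_ids, "Group": [group_labels[g] for g in sample_group]}
    )
    e_meta = pd.DataFrame(
        {
            "peak_id": masses,
            "formula": formulas,
            "isotope": np.where(isotope, "1", "0"),
        }
    )
    truth = pd.DataFrame(
        {
            "peak_id": masses,
            "formula": [write_formula(c) for c in counts],
            "exact_mass": exact,
            "is_unique": is_unique,
            "home_group": [group_labels[h] if h >= 0 else None for h in home],
            **{f"prob_{g}": probs[:, i] for i, g in enumerate(group_labels)},
        }
    )
    return e_data, f_data, e_meta, truth


def synthetic_dataset(spec: SynthSpec) -> tuple[PeakDataset, pd.DataFrame]:
    """Generate, validate and group a synthetic dataset; returns (dataset, truth)."""
    e_data, f_data, e_meta, truth = generate_synthetic(spec)
    ds = build_dataset(
        e_data, f_data, e_meta,
        peak_id="peak_id", sample_id="sample_id", formula="formula",
        isotope="isotope", isotope_symbol="1",
    )
    ds = ds.set_groups(["Group"])
    ds.provenance.append(f"synthetic:seed={spec.seed}")
    return ds, truth
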