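"""Synthetic TXRF-like spectra with known class structure.

Generates labeled spectral datasets whose statistical structure matches
what the classification pipeline assumes about benchtop total-reflection
X-ray fluorescence data on digested tissue:

* element fluorescence lines as Gaussian peaks (two or more lines per
  element, with fixed branching ratios) on a smooth positive scatter
  baseline;
* origin-dependent elemental concentration profiles, with log-normal
  sample-to-sample biological variability;
* a per-sample multiplicative gain emulating matrix/scatter effects on the
  X-ray beam — the nuisance the Savitzky-Golay derivative is meant to
  remove;
* additive counting noise (Poisson by default);
* an internal-standard gallium line at fixed concentration, present for
  realism but carrying no class signal.

The model spectrum of sample *i* is

    gain_i * [ baseline(E) + sum_e conc_{i,e} * sum_lines r_l * G(E; E_l, sigma(E_l)) ] + noise

where ``G`` is an unnormalised Gaussian of unit peak height,
``sigma(E) = sqrt(a + b*E)`` is the detector resolution, ``r_l`` the line
branching ratio, and ``conc_{i,e}`` is log-normal around the class mean.
Because every class-discriminative feature is placed explicitly, the
generator can also report the ground-truth discriminative channels, which
serves as the oracle for validating VIP-based variable selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spectra_io import SpectraSet

__all__ = [
    "ElementLine",
    "SyntheticDesign",
    "default_element_lines",
    "class_mean_table",
    "make_design",
    "default_study_designs",
    "recovery_design",
    "generate_dataset",
    "generate_study",
    "ground_truth_discriminative_channels",
]


@dataclass(frozen=True)
class ElementLine:
    """One fluorescence emission line of an element.

    ``relative_intensity`` is the branching of this line relative to the
    element's primary line (1.0 for the primary itself).
    """

    element: str
    line_energy: float  # keV
    relative_intensity: float = 1.0

    def validate(self, e_max: float) -> None:
        if not 0 < self.line_energy <= e_max:
            raise ValueError(
                f"{self.element} line at {self.line_energy} keV outside (0, {e_max}]"
            )
        if not 0 < self.relative_intensity <= 1:
            raise ValueError(
                f"{self.element} relative intensity {self.relative_intensity} "
                "outside (0, 1]"
            )


# Tabulated K/L emission energies (keV) of the elements prominent in marine
# tissue TXRF spectra, plus the gallium internal standard.  Configurable
# constants, not physical claims at eV accuracy.
_LINE_TABLE: list[tuple[str, float, float]] = [
    ("Na", 1.041, 1.0),
    ("K", 3.314, 1.0),
    ("K", 3.590, 0.12),
    ("Ca", 3.692, 1.0),
    ("Ca", 4.013, 0.13),
    ("Fe", 6.404, 1.0),
    ("Fe", 7.058, 0.14),
    ("Cu", 8.048, 1.0),
    ("Cu", 8.905, 0.14),
    ("Zn", 8.639, 1.0),
    ("Zn", 9.572, 0.14),
    ("Ga", 9.251, 1.0),
    ("Ga", 10.264, 0.15),
    ("Pb", 10.552, 1.0),
    ("Pb", 12.614, 0.85),
    ("Br", 11.924, 1.0),
    ("Br", 13.291, 0.15),
    ("Sr", 14.165, 1.0),
    ("Sr", 15.836, 0.17),
]

INTERNAL_STANDARD = "Ga"

# Baseline element concentrations (expected peak counts) typical of a
# digested muscle sample; arbitrary count units.
_BASE_CONCENTRATIONS: dict[str, float] = {
    "Na": 900.0,
    "K": 2600.0,
    "Ca": 1500.0,
    "Fe": 420.0,
    "Cu": 320.0,
    "Zn": 640.0,
    "Br": 520.0,
    "Sr": 360.0,
    "Pb": 150.0,
    INTERNAL_STANDARD: 1000.0,
}


def default_element_lines() -> list[ElementLine]:
    return [ElementLine(el, e, r) for el, e, r in _LINE_TABLE]


@dataclass
class SyntheticDesign:
    """Generative parameters for one labeled spectral dataset.

    Defaults mirror the sampling layout of a per-species provenance study:
    4-5 origin classes with ~30 replicate individuals each and 3025
    spectral channels.
    """

    n_classes: int = 4
    replicates_per_class: int = 30
    n_channels: int = 3025
    e_max: float = 17.5  # keV; covers the K lines of Na..Sr under Mo excitation
    element_lines: list[ElementLine] = field(default_factory=default_element_lines)
    class_concentration_means: pd.DataFrame | None = None  # k x n_elements, > 0
    concentration_cv: float = 0.2
    baseline_params: tuple[float, float, float, float, float] = (
        60.0,   # constant offset (counts)
        -2.0,   # linear slope per keV
        120.0,  # scatter hump amplitude
        16.2,   # hump centre (keV), near the excitation scatter region
        1.6,    # hump width (keV)
    )
    gain_cv: float = 0.15
    noise_model: str = "poisson"  # or "gaussian"
    gaussian_sigma: float = 5.0  # counts, used when noise_model == "gaussian"
    detector_sigma_params: tuple[float, float] = (0.0012, 0.0005)  # sigma^2 = a + b*E
    seed: int = 0
    replicate_overrides: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.class_concentration_means is None:
            self.class_concentration_means = class_mean_table(self.n_classes)

    # -- derived quantities --------------------------------------------------

    @property
    def elements(self) -> list[str]:
        return list(self.class_concentration_means.columns)

    @property
    def channel_energies(self) -> np.ndarray:
        return np.linspace(0.0, self.e_max, self.n_channels)

    @property
    def class_names(self) -> list[str]:
        return [f"class_{c + 1}" for c in range(self.n_classes)]

    def replicates_for(self, class_index: int) -> int:
        return self.replicate_overrides.get(class_index, self.replicates_per_class)

    @property
    def n_samples(self) -> int:
        return sum(self.replicates_for(c) for c in range(self.n_classes))

    def sigma(self, energy: float | np.ndarray) -> float | np.ndarray:
        a, b = self.detector_sigma_params
        return np.sqrt(a + b * np.asarray(energy, float))

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_channels < 3:
            raise ValueError("need at least 3 channels")
        if any(self.replicates_for(c) < 1 for c in range(self.n_classes)):
            raise ValueError("every class needs at least one replicate")
        if self.concentration_cv < 0 or self.gain_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        means = self.class_concentration_means
        if means.shape[0] != self.n_classes:
            raise ValueError(
                f"concentration table has {means.shape[0]} rows for "
                f"{self.n_classes} classes"
            )
        if (means.to_numpy() <= 0).any():
            raise ValueError("class concentration means must be positive")
        line_elements = {l.element for l in self.element_lines}
        unknown = set(self.elements) - line_elements
        if unknown:
            raise ValueError(f"elements without emission lines: {sorted(unknown)}")
        for line in self.element_lines:
            line.validate(self.e_max)

    # -- deterministic model curve -------------------------------------------

    def baseline(self, energies: np.ndarray) -> np.ndarray:
        c0, c1, amp, centre, width = self.baseline_params
        base = c0 + c1 * energies + amp * np.exp(
            -0.5 * ((energies - centre) / width) ** 2
        )
        return np.clip(base, 0.0, None)

    def peak_profiles(self, energies: np.ndarray) -> pd.DataFrame:
        """Unit-concentration spectral profile of each element (p x n_elements)."""
        profiles = {}
        for element in self.elements:
            profile = np.zeros_like(energies)
            for line in self.element_lines:
                if line.element != element:
                    continue
                sig = float(self.sigma(line.line_energy))
                profile += line.relative_intensity * np.exp(
                    -0.5 * ((energies - line.line_energy) / sig) ** 2
                )
            profiles[element] = profile
        return pd.DataFrame(profiles)

    def model_curve(self, class_index: int) -> np.ndarray:
        """Noise-free, unit-gain expected spectrum of one class."""
        energies = self.channel_energies
        profiles = self.peak_profiles(energies).to_numpy()
        conc = self.class_concentration_means.iloc[class_index].to_numpy()
        return self.baseline(energies) + profiles @ conc


def class_mean_table(
    k: int,
    elements: list[str] | None = None,
    strength: float = 0.5,
    varying: list[str] | None = None,
) -> pd.DataFrame:
    """Origin-dependent concentration means for ``k`` classes.

    Each varying element gets a deterministic per-class fold change between
    ``1 - strength`` and ``1 + strength`` of its baseline concentration,
    phased so that no two classes share a profile.  The internal standard
    never varies.
    """
    if elements is None:
        elements = list(_BASE_CONCENTRATIONS)
    if varying is None:
        varying = [e for e in elements if e != INTERNAL_STANDARD]
    if not 0 <= strength < 1:
        raise ValueError("strength must lie in [0, 1)")
    rows = []
    for c in range(k):
        row = {}
        for j, element in enumerate(elements):
            base = _BASE_CONCENTRATIONS.get(element, 300.0)
            if element in varying and element != INTERNAL_STANDARD:
                # phase-shifted cosine pattern: distinct profile per class
                phase = 2.0 * np.pi * (c / k + j / len(elements))
                row[element] = base * (1.0 + strength * np.cos(phase))
            else:
                row[element] = base
        rows.append(row)
    table = pd.DataFrame(rows, columns=elements)
    table.index = [f"class_{c + 1}" for c in range(k)]
    return table


def make_design(k: int = 4, seed: int = 0, **overrides) -> SyntheticDesign:
    """Convenience constructor with the study-scale defaults."""
    design = SyntheticDesign(n_classes=k, seed=seed, **overrides)
    design.validate()
    return design


def recovery_design(seed: int = 0) -> SyntheticDesign:
    """Study-shaped dataset with strong class-specific elemental signal.

    4 origin classes x 30 replicates x 3025 channels, with pronounced
    fold changes of the elements across classes (strength 0.7, i.e. class
    means spanning +-70% of baseline) against small biological variability
    (8% concentration CV) — a high-SNR regime in which the pipeline is
    expected to recover the origin labels and the discriminative channels
    almost perfectly.  Matrix gain variability and counting noise stay at
    their realistic defaults.
    """
    return make_design(
        k=4,
        seed=seed,
        class_concentration_means=class_mean_table(4, strength=0.7),
        concentration_cv=0.08,
    )


def default_study_designs() -> tuple[list[SyntheticDesign], list[str]]:
    """The five-species study layout: k in {4, 5, 4, 4, 5}, 30 replicates
    per class except one 19-replicate class, for 649 samples in total."""
    ks = [4, 5, 4, 4, 5]
    names = [f"species_{i + 1}" for i in range(5)]
    designs = []
    for i, k in enumerate(ks):
        overrides = {1: 19} if i == 2 else {}
        designs.append(
            SyntheticDesign(
                n_classes=k,
                seed=i,
                class_concentration_means=class_mean_table(k, strength=0.5),
                replicate_overrides=overrides,
            )
        )
    return designs, names


# ---------------------------------------------------------------------------
# generation


def generate_dataset(
    design: SyntheticDesign,
    species: str = "species_1",
    rng: np.random.Generator | None = None,
) -> SpectraSet:
    """Draw one labeled dataset from the generative model.

    Deterministic given ``design.seed`` (or an explicit ``rng``).  Origin
    labels are ``class_1 .. class_k``; sample ids encode species, class and
    replicate.
    """
    design.validate()
    if rng is None:
        rng = np.random.default_rng(design.seed)

    energies = design.channel_energies
    profiles = design.peak_profiles(energies).to_numpy()  # p x n_elem
    baseline = design.baseline(energies)
    means = design.class_concentration_means.to_numpy()  # k x n_elem

    ids, origins, rows = [], [], []
    for c in range(design.n_classes):
        n_rep = design.replicates_for(c)
        conc = _lognormal_around(means[c], design.concentration_cv, (n_rep, means.shape[1]), rng)
        gain = _lognormal_around(np.ones(n_rep), design.gain_cv, (n_rep,), rng)
        clean = gain[:, None] * (baseline[None, :] + conc @ profiles.T)
        if design.noise_model == "poisson":
            noisy = rng.poisson(np.clip(clean, 0.0, None)).astype(float)
        elif design.noise_model == "gaussian":
            noisy = np.clip(clean + rng.normal(0.0, design.gaussian_sigma, clean.shape), 0.0, None)
        else:
            noisy = clean
        for r in range(n_rep):
            ids.append(f"{species}_c{c + 1}_r{r + 1:03d}")
            origins.append(design.class_names[c])
            rows.append(noisy[r])

    meta = pd.DataFrame(
        {"sample_id": ids, "species": species, "origin": origins}
    ).set_index("sample_id")
    return SpectraSet(
        sample_ids=ids,
        channel_energies=energies,
        intensities=np.vstack(rows),
        meta=meta,
        processed=False,
    )


def _lognormal_around(
    mean: np.ndarray, cv: float, shape: tuple, rng: np.random.Generator
) -> np.ndarray:
    """Log-normal draws with the requested mean and coefficient of variation."""
    if cv == 0:
        return np.broadcast_to(np.asarray(mean, float), shape).copy()
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return np.exp(rng.normal(mu, np.sqrt(sigma2), shape))


def generate_study(
    designs: list[SyntheticDesign],
    species_names: list[str],
    seed: int | None = None,
) -> list[SpectraSet]:
    """One dataset per species, with independent random substreams.

    When ``seed`` is given it overrides the per-design seeds through
    spawned substreams of a single seed sequence, so the whole study is
    reproducible from one integer.
    """
    if len(designs) != len(species_names):
        raise ValueError("designs and species_names must have equal length")
    if len(set(species_names)) != len(species_names):
        dupes = sorted({n for n in species_names if species_names.count(n) > 1})
        raise ValueError(f"duplicate species names: {dupes}")
    if seed is not None:
        streams = np.random.SeedSequence(seed).spawn(len(designs))
        rngs = [np.random.default_rng(s) for s in streams]
    else:
        rngs = [None] * len(designs)
    return [
        generate_dataset(design, species=name, rng=rng)
        for design, name, rng in zip(designs, species_names, rngs)
    ]


def ground_truth_discriminative_channels(
    design: SyntheticDesign, min_effect: float = 0.05
) -> set[int]:
    """Channels that genuinely carry class signal, by construction.

    An element is discriminative when the relative range of its class-mean
    concentrations, ``(max - min) / mean``, exceeds ``min_effect``.  The
    returned set contains every channel within 3 detector sigma of any line
    of any discriminative element.  Used as the oracle against which
    VIP-based channel selection is scored.
    """
    design.validate()
    means = design.class_concentration_means
    energies = design.channel_energies
    channels: set[int] = set()
    for element in design.elements:
        col = means[element].to_numpy()
        rel_range = (col.max() - col.min()) / col.mean()
        if rel_range <= min_effect:
            continue
        for line in design.element_lines:
            if line.element != element:
                continue
            sig = float(design.sigma(line.line_energy))
            hit = np.abs(energies - line.line_energy) <= 3.0 * sig
            channels.update(np.flatnonzero(hit).tolist())
    return channels
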