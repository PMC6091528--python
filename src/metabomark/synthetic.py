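"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates the output of an XCMS-style alignment of GC/ToF-MS
runs from a dose-response exposure experiment: a samples x bins table of
strictly positive, log-normally distributed abundances, with a small set of
planted dose-responsive bins, a per-tube shared random offset modelling the
housing of several individuals per exposure tube, and companion spectral and
pathway libraries.  Ground truth (which bins were planted, in which
direction, and which compound each maps to) is recorded so recovery tests
can score the downstream ranking.

Defaults mirror the study design this package targets: exposure levels
{0, 10, 50, 250, 1250} ug/L, five replicate tubes of four individuals per
level (20 samples per group, 100 per species), and roughly 10^4 retention
time x mass-fragment bins per species.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np

from .errors import ConfigurationError
from .feature_table import FeatureTable, bin_meta_from_ids
from .pathways import Pathway, PathwayLibrary
from .spectral import BASE_PEAK, LibraryEntry, SpectralLibrary, Spectrum

#: exposure levels of the emulated design, in ug/L
DEFAULT_CONCENTRATIONS = (0.0, 10.0, 50.0, 250.0, 1250.0)

#: bin counts of the two emulated species-level alignments
N_BINS_TOAD = 11766
N_BINS_TREEFROG = 9723

DOSE_MODELS = ("linear-log", "step")


@dataclass
class SyntheticConfig:
    """Design constants and noise model of one synthetic species dataset.

    ``effect_size`` is the maximum absolute log2 fold change of a planted bin,
    reached at the highest concentration; ``noise_sigma`` and ``tube_sigma``
    are standard deviations on the log2-abundance scale.
    """

    n_bins: int = N_BINS_TOAD
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    tubes_per_group: int = 5
    individuals_per_tube: int = 4
    n_planted: int = 20
    effect_size: float = 2.0
    dose_model: str = "linear-log"
    step_threshold: float | None = None
    noise_sigma: float = 0.5
    tube_sigma: float = 0.1
    species_label: str = "synthetic"
    seed: int = 0

    def validate(self) -> None:
        if self.n_bins <= 0:
            raise ConfigurationError("n_bins must be positive")
        if self.tubes_per_group <= 0:
            raise ConfigurationError("tubes_per_group must be positive")
        if self.individuals_per_tube <= 0:
            raise ConfigurationError("individuals_per_tube must be positive")
        if not (0 <= self.n_planted <= self.n_bins):
            raise ConfigurationError("n_planted must satisfy 0 <= n_planted <= n_bins")
        if any(c < 0 for c in self.concentrations):
            raise ConfigurationError("concentrations must be non-negative")
        if 0.0 not in {float(c) for c in self.concentrations}:
            raise ConfigurationError("concentrations must include 0 (the control)")
        if len(set(self.concentrations)) != len(self.concentrations):
            raise ConfigurationError("concentrations must be distinct")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be non-negative")
        if self.noise_sigma <= 0:
            raise ConfigurationError("noise_sigma must be positive")
        if self.tube_sigma < 0:
            raise ConfigurationError("tube_sigma must be non-negative")
        if self.dose_model not in DOSE_MODELS:
            raise ConfigurationError(f"dose_model must be one of {DOSE_MODELS}")

    @property
    def n_samples(self) -> int:
        return len(self.concentrations) * self.tubes_per_group * self.individuals_per_tube

    def dose_scale(self, concentration: float) -> float:
        """Fraction of the full planted effect applied at a concentration."""
        top = max(self.concentrations)
        if top == 0:
            return 0.0
        if self.dose_model == "linear-log":
            return float(np.log10(concentration + 1.0) / np.log10(top + 1.0))
        threshold = self.step_threshold
        if threshold is None:
            threshold = min(c for c in self.concentrations if c > 0)
        return 1.0 if concentration >= threshold else 0.0


@dataclass
class SyntheticTruth:
    """Ground truth of one generated table, for recovery scoring."""

    planted_bins: list[str]
    per_bin_direction: dict[str, int]
    bin_to_compound: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["per_bin_direction"] = {k: int(v) for k, v in d["per_bin_direction"].items()}
        return cls(**d)


def _unique_bin_ids(n_bins: int, rng: np.random.Generator) -> list[str]:
    ids: dict[str, None] = {}
    while len(ids) < n_bins:
        rts = np.round(rng.uniform(60.0, 1500.0, size=n_bins - len(ids)), 1)
        mzs = rng.integers(50, 651, size=n_bins - len(ids))
        for rt, mz in zip(rts, mzs):
            key = f"RT{rt:.1f}_MZ{int(mz)}"
            if key not in ids:
                ids[key] = None
    return list(ids)


def generate_feature_table(config: SyntheticConfig) -> tuple[FeatureTable, SyntheticTruth]:
    """Draw one samples x bins abundance table plus its ground truth.

    Abundances are ``2 ** (base_bin + planted_effect + tube_offset + noise)``
    with iid Gaussian noise on the log2 scale, so all values are strictly
    positive and right-skewed on the raw scale.  Planted bins shift by
    ``direction * effect_size * dose_scale(concentration)`` log2 units.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    import pandas as pd

    bin_ids = _unique_bin_ids(config.n_bins, rng)
    base = rng.normal(13.0, 2.0, size=config.n_bins)

    planted_idx = np.sort(rng.choice(config.n_bins, size=config.n_planted, replace=False))
    directions = rng.choice([-1, 1], size=config.n_planted)

    sample_ids, species, concs, tube_ids = [], [], [], []
    tube_offsets = []
    for conc in config.concentrations:
        for t in range(1, config.tubes_per_group + 1):
            off = rng.normal(0.0, config.tube_sigma) if config.tube_sigma > 0 else 0.0
            for i in range(1, config.individuals_per_tube + 1):
                sample_ids.append(f"{config.species_label}_c{conc:g}_t{t}_i{i}")
                species.append(config.species_label)
                concs.append(float(conc))
                tube_ids.append(f"c{conc:g}_t{t}")
                tube_offsets.append(off)

    n = len(sample_ids)
    log2a = np.tile(base, (n, 1))
    log2a += np.asarray(tube_offsets)[:, None]
    for j, (b, d) in enumerate(zip(planted_idx, directions)):
        shift = np.array([d * config.effect_size * config.dose_scale(c) for c in concs])
        log2a[:, b] += shift
    log2a += rng.normal(0.0, config.noise_sigma, size=log2a.shape)

    abund = pd.DataFrame(np.exp2(log2a), index=pd.Index(sample_ids, name="sample_id"),
                         columns=bin_ids)
    meta = pd.DataFrame({"species": species, "concentration_ug_per_L": concs,
                         "tube_id": tube_ids},
                        index=pd.Index(sample_ids, name="sample_id"))
    table = FeatureTable(abund, meta, bin_meta_from_ids(bin_ids))
    truth = SyntheticTruth(planted_bins=[bin_ids[b] for b in planted_idx],
                           per_bin_direction={bin_ids[b]: int(d)
                                              for b, d in zip(planted_idx, directions)},
                           seed=config.seed)
    return table, truth


# ---------------------------------------------------------------------------
# companion libraries


def generate_spectral_library(n_compounds: int, peaks_per_spectrum: int,
                              seed: int = 0) -> SpectralLibrary:
    """A synthetic stand-in for a reference EI spectral library.

    Each entry carries a compound name, a retention time in seconds and
    ``peaks_per_spectrum`` unit-m/z peaks with the base peak normalized to 999.
    """
    if n_compounds <= 0:
        raise ConfigurationError("n_compounds must be positive")
    if peaks_per_spectrum <= 0:
        raise ConfigurationError("peaks_per_spectrum must be positive")
    rng = np.random.default_rng(seed)
    # retention times spaced to stay distinguishable at a 0.05 s tolerance
    rts = rng.choice(np.arange(60.0, 1500.0, 0.5), size=n_compounds, replace=False)
    entries = []
    for k in range(n_compounds):
        mz = np.sort(rng.choice(np.arange(50, 651), size=peaks_per_spectrum, replace=False))
        inten = rng.uniform(10.0, 1000.0, size=peaks_per_spectrum)
        inten = inten * (BASE_PEAK / inten.max())
        entries.append(LibraryEntry(
            f"Compound_{k + 1:03d}",
            Spectrum(tuple(float(m) for m in mz), tuple(float(i) for i in inten),
                     float(rts[k]))))
    return SpectralLibrary(entries)


def generate_pathway_library(n_pathways: int, background_size: int,
                             size_range: tuple[int, int], seed: int = 0) -> PathwayLibrary:
    """Random pathway sets over a compound background, each with a connected graph.

    Compound names follow the same ``Compound_###`` convention as
    :func:`generate_spectral_library`, so a spectral library of the same
    background size yields directly mappable annotations.
    """
    lo, hi = size_range
    if n_pathways <= 0 or background_size <= 0:
        raise ConfigurationError("n_pathways and background_size must be positive")
    if not (1 <= lo <= hi <= background_size):
        raise ConfigurationError(
            f"size_range {size_range} infeasible for background_size {background_size}")
    rng = np.random.default_rng(seed)
    background = [f"Compound_{k + 1:03d}" for k in range(background_size)]
    pathways = []
    for p in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = sorted(rng.choice(background, size=size, replace=False))
        order = list(rng.permutation(members))
        g = nx.Graph()
        g.add_nodes_from(members)
        for i in range(1, len(order)):  # random spanning tree keeps the graph connected
            g.add_edge(order[i], order[int(rng.integers(0, i))])
        for _ in range(size // 3):  # a few shortcut edges for non-trivial topology
            u, v = rng.choice(members, size=2, replace=False)
            if u != v:
                g.add_edge(u, v)
        pathways.append(Pathway(f"Pathway_{p + 1:02d}", frozenset(members), g))
    return PathwayLibrary(pathways, background=set(background))


# ---------------------------------------------------------------------------
# bin spectra tied to ground truth


def assign_compounds(truth: SyntheticTruth, library: SpectralLibrary,
                     seed: int = 0, compounds: list[str] | None = None) -> None:
    """Map each planted bin to a distinct library compound (in place).

    When ``compounds`` is given, bins are mapped to those names in order
    (useful to force a known cross-species overlap); otherwise compounds are
    drawn at random from the library.
    """
    rng = np.random.default_rng(seed)
    names = library.names()
    if compounds is None:
        if len(names) < len(truth.planted_bins):
            raise ConfigurationError("library smaller than the number of planted bins")
        compounds = list(rng.choice(names, size=len(truth.planted_bins), replace=False))
    if len(compounds) < len(truth.planted_bins):
        raise ConfigurationError("fewer compounds than planted bins")
    unknown = set(compounds) - set(names)
    if unknown:
        raise ConfigurationError(f"compounds not in library: {sorted(unknown)[:5]}")
    truth.bin_to_compound = dict(zip(truth.planted_bins, compounds))


def generate_bin_spectra(truth: SyntheticTruth, library: SpectralLibrary,
                         seed: int = 0, intensity_jitter: float = 0.05,
                         rt_jitter: float = 0.01) -> dict[str, Spectrum]:
    """Measured spectra for the planted bins, derived from their library entries.

    Each planted bin's spectrum is its assigned compound's library spectrum
    with mild multiplicative intensity noise and a retention-time jitter well
    inside the matching tolerance, so a correct pipeline recovers the
    assignment with a high similarity value.
    """
    rng = np.random.default_rng(seed)
    by_name = {e.name: e.spectrum for e in library}
    out: dict[str, Spectrum] = {}
    for bin_id, comp in truth.bin_to_compound.items():
        ref = by_name[comp]
        inten = np.asarray(ref.intensities) * (1.0 + rng.normal(0.0, intensity_jitter,
                                                                size=len(ref.intensities)))
        inten = np.clip(inten, 1.0, None)
        out[bin_id] = Spectrum(ref.mz, tuple(float(i) for i in inten),
                               ref.retention_time + float(rng.uniform(-rt_jitter, rt_jitter)))
    return out


@dataclass
class SpeciesBundle:
    """One species' full synthetic input set."""

    table: FeatureTable
    truth: SyntheticTruth
    bin_spectra: dict[str, Spectrum]


def generate_species_bundle(config: SyntheticConfig, library: SpectralLibrary,
                            compounds: list[str] | None = None) -> SpeciesBundle:
    """Feature table, ground truth and planted-bin spectra for one species."""
    table, truth = generate_feature_table(config)
    assign_compounds(truth, library, seed=config.seed + 1, compounds=compounds)
    spectra = generate_bin_spectra(truth, library, seed=config.seed + 2)
    return SpeciesBundle(table, truth, spectra)
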