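"""Cross-species biomarker intersection and transfer classification.

Metabolites putatively identified from each species' top-ranked bins are
intersected (case- and spelling-insensitively) into a biomarker subset: the
compounds perturbed by exposure in both species, each carrying its
per-species direction of change.  The subset's value as an exposure
signature is then measured by restricting the feature table to the biomarker
bins and classifying each exposure concentration against the controls with
a freshly tuned SVM under repeated stratified k-fold cross-validation.

The package ships a fixture of 44 metabolites identified from the top-ranked
bins of a two-species amphibian atrazine exposure study, with per-species
presence and direction flags, as a standing regression input for the
intersection (22 of the 44 occur in both species).
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .errors import DataError
from .feature_table import FeatureTable
from .naming import canonical_name
from .svm_rfe import SVMConfig, repeated_cv_accuracy, tune_svm

logger = logging.getLogger(__name__)


@dataclass
class BiomarkerSet:
    """Compounds perturbed in both species, with per-species direction signs."""

    compounds: list[str]
    signs: dict[str, tuple[str, str]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.compounds)) != len(self.compounds):
            raise DataError("biomarker compounds are not unique")
        missing = [c for c in self.compounds if c not in self.signs]
        if missing:
            raise DataError(f"compounds without sign entries: {missing[:5]}")

    def __len__(self) -> int:
        return len(self.compounds)

    def concordant(self) -> list[str]:
        return [c for c in self.compounds if self.signs[c][0] == self.signs[c][1]]

    def discordant(self) -> list[str]:
        return [c for c in self.compounds if self.signs[c][0] != self.signs[c][1]]

    def to_tsv(self, path) -> None:
        a = self.provenance.get("species_a", "species_a")
        b = self.provenance.get("species_b", "species_b")
        pd.DataFrame({"compound": self.compounds,
                      f"sign_{a}": [self.signs[c][0] for c in self.compounds],
                      f"sign_{b}": [self.signs[c][1] for c in self.compounds]}
                     ).to_csv(path, sep="\t", index=False)


def intersect_biomarkers(signs_a: Mapping[str, str], signs_b: Mapping[str, str],
                         provenance: dict | None = None) -> BiomarkerSet:
    """Compounds present in both per-species sign maps, alphabetically ordered.

    Matching is canonical-name based (case, punctuation and a small synonym
    map are ignored); the display spelling of the first input wins.
    """
    canon_a = {canonical_name(c): c for c in signs_a}
    canon_b = {canonical_name(c): c for c in signs_b}
    shared = sorted(set(canon_a) & set(canon_b), key=lambda k: canon_a[k].lower())
    compounds = [canon_a[k] for k in shared]
    signs = {canon_a[k]: (signs_a[canon_a[k]], signs_b[canon_b[k]]) for k in shared}
    return BiomarkerSet(compounds, signs, provenance or {})


# ---------------------------------------------------------------------------
# packaged two-species fixture


def load_cross_species_signs() -> tuple[dict[str, str], dict[str, str]]:
    """Per-species sign maps of the packaged 44-metabolite fixture.

    Returns ``(treefrog_signs, toad_signs)``; a metabolite absent from a
    species' top-ranked bins is simply missing from that species' map.
    """
    ref = importlib.resources.files("metabomark.data") / "metabolite_signs_two_species.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
    tf = {r.metabolite: r.h_versicolor for r in df.itertuples() if r.h_versicolor}
    toad = {r.metabolite: r.a_americanus for r in df.itertuples() if r.a_americanus}
    return tf, toad


# ---------------------------------------------------------------------------
# transfer classification per exposure concentration


@dataclass(frozen=True)
class ConcentrationAccuracy:
    """Mean repeated-CV accuracy of exposure-vs-control at one concentration."""

    concentration: float
    mean_accuracy: float
    sd: float
    repeats: int


def classify_with_biomarkers(table: FeatureTable, biomarkers: BiomarkerSet,
                             bin_map: Mapping[str, list[str]], concentration: float,
                             config: SVMConfig) -> ConcentrationAccuracy:
    """Classify one exposure concentration against controls using only
    biomarker bins.

    ``bin_map`` maps each biomarker compound to the feature-table bins
    annotated to it; every biomarker must map to at least one bin.
    Hyperparameters are re-tuned for each concentration contrast (the class
    geometry changes with dose) and accuracy is estimated by repeated
    stratified k-fold cross-validation.
    """
    canon_map = {canonical_name(c): bins for c, bins in bin_map.items()}
    missing, bins = [], []
    for comp in biomarkers.compounds:
        mapped = canon_map.get(canonical_name(comp))
        if not mapped:
            missing.append(comp)
        else:
            bins.extend(mapped)
    if missing:
        raise DataError(f"biomarkers without mapped bins: {missing}")
    seen: dict[str, None] = {}
    for b in bins:
        seen.setdefault(b)
    sub = table.select_bins(list(seen)).select_concentrations([0.0, float(concentration)])
    labels = (sub.sample_meta["concentration_ug_per_L"].astype(float) > 0).astype(int)
    cost, gamma, _ = tune_svm(sub, labels, config)
    from dataclasses import replace

    result = repeated_cv_accuracy(sub, labels, replace(config, cost=cost, gamma=gamma))
    return ConcentrationAccuracy(float(concentration), result.mean, result.sd,
                                 len(result.per_repeat))


def concentration_accuracies_to_tsv(rows, path) -> None:
    pd.DataFrame([{"concentration_ug_per_L": r.concentration, "mean_accuracy": r.mean_accuracy,
                   "sd_accuracy": r.sd, "repeats": r.repeats} for r in rows]
                 ).to_csv(path, sep="\t", index=False)
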