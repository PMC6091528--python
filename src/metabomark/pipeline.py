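"""End-to-end orchestration of the biomarker-discovery analysis.

``run_full`` executes the whole flow for a two-species experiment:
preprocessing and outlier rejection per species, SVM-RFE ranking of the
control vs. top-dose contrast, the accuracy-vs-k curve, spectral annotation
of the top-ranked bins, per-species direction signs, the cross-species
biomarker intersection, per-concentration transfer classification with the
biomarker bins, and over-representation analysis of each species' identified
compound set plus the biomarker subset.  Every intermediate artifact is
written to the output directory, and a manifest records the configuration,
seeds, package version and a checksum per output so a run is re-derivable
from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .biomarker import (classify_with_biomarkers, concentration_accuracies_to_tsv,
                        intersect_biomarkers)
from .errors import MetabomarkError
from .feature_table import FeatureTable
from .pathways import PathwayLibrary, ora, ora_table, report_pathways
from .preprocess import preprocess
from .spectral import (SpectralLibrary, annotate_bins, annotations_to_tsv,
                       compound_best_sv, compound_signs, read_bin_spectra_msp)
from .svm_rfe import SVMConfig, accuracy_curve, rfe_rank

logger = logging.getLogger(__name__)

STAGES = ["preprocess", "rank", "curve", "annotate", "signs", "biomarkers",
          "classify", "pathways", "manifest"]


class PipelineStageError(MetabomarkError):
    """A stage failed; carries the stage name and its numeric exit code."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.code = 10 + STAGES.index(stage)
        super().__init__(f"stage '{stage}' failed: {cause}")


@dataclass
class PipelineConfig:
    """Paths and constants of one full two-species run."""

    table_a: str
    table_b: str
    library_msp: str
    bin_spectra_a: str
    bin_spectra_b: str
    pathway_gmt: str
    pathway_edges_dir: str | None = None
    species_a: str = "species_a"
    species_b: str = "species_b"
    svm: SVMConfig = field(default_factory=SVMConfig)
    top_k: int = 200
    sv_threshold: int = 700
    rt_tolerance: float = 0.05
    mz_tolerance: float = 0.5
    min_hits: int = 3
    confidence: float = 0.95
    n_components: int = 2
    curve_k_values: tuple[int, ...] = (1, 5, 10, 20, 50, 100, 200)
    out_dir: str = "metabomark_out"
    seed: int = 0

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _species_analysis(tag: str, table: FeatureTable, spectra_path: str,
                      library: SpectralLibrary, config: PipelineConfig,
                      out: Path, manifest: dict) -> dict:
    """Preprocess -> rank -> curve -> annotate -> signs for one species."""
    top_dose = float(table.sample_meta["concentration_ug_per_L"].astype(float).max())

    normalized, scaled, report = preprocess(table, confidence=config.confidence,
                                            n_components=config.n_components)
    report.to_json(out / f"{tag}.preprocess.json")
    manifest["stages_done"].append(f"preprocess:{tag}")

    contrast = scaled.select_concentrations([0.0, top_dose])
    labels = (contrast.sample_meta["concentration_ug_per_L"].astype(float) > 0).astype(int)
    svm = dataclasses.replace(config.svm, seed=config.seed)
    try:
        ranking = rfe_rank(contrast, labels, svm)
    except MetabomarkError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineStageError("rank", exc)
    ranking.to_tsv(out / f"{tag}.ranking.tsv")
    manifest["stages_done"].append(f"rank:{tag}")

    svm_eval = dataclasses.replace(svm, cost=None, gamma=None)
    ks = [k for k in config.curve_k_values if k <= len(ranking.order)]
    if len(ranking.order) not in ks:
        ks.append(len(ranking.order))
    curve = accuracy_curve(contrast, labels, ranking, ks, svm_eval)
    curve.to_tsv(out / f"{tag}.accuracy_curve.tsv")
    manifest["stages_done"].append(f"curve:{tag}")

    bin_spectra = read_bin_spectra_msp(spectra_path)
    top_k = min(config.top_k, len(ranking.order))
    annotations = annotate_bins(ranking, top_k, bin_spectra, library,
                                rt_tolerance=config.rt_tolerance,
                                sv_threshold=config.sv_threshold,
                                mz_tolerance=config.mz_tolerance)
    annotations_to_tsv(annotations, out / f"{tag}.annotations.tsv")
    manifest["stages_done"].append(f"annotate:{tag}")

    signs = compound_signs(normalized, annotations, exposed_level=top_dose)
    with open(out / f"{tag}.signs.json", "w") as fh:
        json.dump(signs, fh, indent=1)
    manifest["stages_done"].append(f"signs:{tag}")

    best = compound_best_sv(annotations)
    bin_map = {comp: [ann.bin_id] for comp, ann in best.items()}
    return {"normalized": normalized, "scaled": scaled, "ranking": ranking,
            "annotations": annotations, "signs": signs, "bin_map": bin_map,
            "top_dose": top_dose}


def run_full(config: PipelineConfig) -> dict:
    """Run the whole analysis; returns a result bundle and writes artifacts.

    Any stage failure raises :class:`PipelineStageError` with a stage-specific
    exit code; artifacts of completed stages are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": config.to_json(), "stages_done": [], "outputs": {}}
    results: dict = {}

    stage = "preprocess"
    try:
        table_a = FeatureTable.from_tsv(config.table_a)
        table_b = FeatureTable.from_tsv(config.table_b)
        library = SpectralLibrary.from_msp(config.library_msp)

        stage = "annotate"  # per-species block reports its own finer stages
        res_a = _species_analysis(config.species_a, table_a, config.bin_spectra_a,
                                  library, config, out, manifest)
        res_b = _species_analysis(config.species_b, table_b, config.bin_spectra_b,
                                  library, config, out, manifest)
        results["species_a"], results["species_b"] = res_a, res_b

        stage = "biomarkers"
        biomarkers = intersect_biomarkers(res_a["signs"], res_b["signs"],
                                          provenance={"species_a": config.species_a,
                                                      "species_b": config.species_b,
                                                      "top_k": config.top_k})
        biomarkers.to_tsv(out / "biomarkers.tsv")
        results["biomarkers"] = biomarkers
        manifest["stages_done"].append("biomarkers")

        stage = "classify"
        svm = dataclasses.replace(config.svm, seed=config.seed, cost=None, gamma=None)
        transfer = {}
        for tag, res, table in ((config.species_a, res_a, table_a),
                                (config.species_b, res_b, table_b)):
            _, scaled_all, _ = preprocess(table, confidence=config.confidence,
                                          n_components=config.n_components)
            concs = sorted(c for c in set(
                scaled_all.sample_meta["concentration_ug_per_L"].astype(float)) if c > 0)
            rows = [classify_with_biomarkers(scaled_all, biomarkers, res["bin_map"],
                                             c, svm) for c in concs] if len(biomarkers) else []
            concentration_accuracies_to_tsv(rows, out / f"{tag}.biomarker_accuracy.tsv")
            transfer[tag] = rows
        results["transfer"] = transfer
        manifest["stages_done"].append("classify")

        stage = "pathways"
        pathway_lib = PathwayLibrary.from_gmt(config.pathway_gmt,
                                              edges_dir=config.pathway_edges_dir)
        queries = {config.species_a: sorted(compound_best_sv(res_a["annotations"])),
                   config.species_b: sorted(compound_best_sv(res_b["annotations"])),
                   "biomarkers": list(biomarkers.compounds)}
        ora_results = {}
        for name, query in queries.items():
            rows = report_pathways(ora(query, pathway_lib), min_hits=config.min_hits) \
                if query else []
            ora_table(rows).to_csv(out / f"{name}.ora.tsv", sep="\t", index=False)
            ora_results[name] = rows
        results["ora"] = ora_results
        manifest["stages_done"].append("pathways")
    except PipelineStageError:
        _write_manifest(manifest, out)
        raise
    except Exception as exc:
        _write_manifest(manifest, out)
        raise PipelineStageError(stage, exc)

    _write_manifest(manifest, out)
    results["manifest"] = manifest
    return results


def _write_manifest(manifest: dict, out: Path) -> None:
    manifest["outputs"] = {p.name: _sha256(p) for p in sorted(out.iterdir())
                           if p.is_file() and p.name != "manifest.json"}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    manifest_stage_count = len(manifest["stages_done"])
    logger.info("manifest written: %d stage records", manifest_stage_count)
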