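"""Putative compound identification by spectral similarity.

Electron-impact GC-MS spectra are compared with library spectra using a
Stein-Scott style weighted cosine: each peak is weighted by
``(m/z)^2 * intensity^0.5``, peaks are paired greedily by nearest m/z within
a tolerance, and the cosine of the weighted vectors is scaled to the familiar
0-999 similarity value (SV) range.  An annotation is accepted as a positive
putative identification when SV exceeds a threshold (999 = identical, the
conventional acceptance cut is SV > 700) and the retention times agree within
a tolerance.

Libraries and per-bin spectra are exchanged in MSP format (``Name:``,
``RT:``, ``Num Peaks:`` followed by ``m/z intensity`` lines); reading goes
through :mod:`matchms`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .errors import ConfigurationError, DataError
from .feature_table import FeatureTable

logger = logging.getLogger(__name__)
logging.getLogger("matchms").setLevel(logging.ERROR)

#: weighting exponents of the match factor: w = mz**MZ_POWER * intensity**INTENSITY_POWER
MZ_POWER = 2.0
INTENSITY_POWER = 0.5

#: conventional base-peak intensity in normalized EI spectra
BASE_PEAK = 999.0


@dataclass(frozen=True)
class Spectrum:
    """A centroided mass spectrum with a retention time in seconds."""

    mz: tuple[float, ...]
    intensities: tuple[float, ...]
    retention_time: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.mz) != len(self.intensities):
            raise DataError("mz and intensity lists differ in length")
        if len(self.mz) == 0:
            raise DataError("spectrum has no peaks")
        if len(set(self.mz)) != len(self.mz):
            raise DataError("m/z values must be unique within a spectrum")
        if any(i < 0 for i in self.intensities):
            raise DataError("negative peak intensity")
        if not any(i > 0 for i in self.intensities):
            raise DataError("spectrum has no peak with positive intensity")

    @classmethod
    def from_peaks(cls, peaks: Iterable[tuple[float, float]],
                   retention_time: float = float("nan")) -> "Spectrum":
        mz, inten = zip(*peaks)
        return cls(tuple(float(m) for m in mz), tuple(float(i) for i in inten),
                   float(retention_time))

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz, self.intensities))

    def scaled_to_base_peak(self, base: float = BASE_PEAK) -> "Spectrum":
        top = max(self.intensities)
        return Spectrum(self.mz, tuple(i * base / top for i in self.intensities),
                        self.retention_time)


@dataclass(frozen=True)
class LibraryEntry:
    name: str
    spectrum: Spectrum


class SpectralLibrary:
    """An ordered collection of named reference spectra with retention times."""

    def __init__(self, entries: Iterable[LibraryEntry]):
        self.entries: list[LibraryEntry] = list(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    # -- MSP I/O -----------------------------------------------------------
    def to_msp(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(f"Name: {e.name}\n")
                rt = e.spectrum.retention_time
                if not math.isnan(rt):
                    fh.write(f"RT: {rt:g}\n")
                fh.write(f"Num Peaks: {len(e.spectrum.mz)}\n")
                for m, i in e.spectrum.peaks:
                    fh.write(f"{m:g} {i:g}\n")
                fh.write("\n")

    @classmethod
    def from_msp(cls, path) -> "SpectralLibrary":
        from matchms.importing import load_from_msp

        logging.getLogger("matchms").setLevel(logging.ERROR)
        entries = []
        for s in load_from_msp(str(path), metadata_harmonization=True):
            name = s.metadata.get("compound_name") or s.metadata.get("name")
            rt = s.metadata.get("retention_time", float("nan"))
            entries.append(LibraryEntry(
                str(name),
                Spectrum(tuple(float(m) for m in s.peaks.mz),
                         tuple(float(i) for i in s.peaks.intensities),
                         float(rt) if rt is not None else float("nan"))))
        return cls(entries)


def write_bin_spectra_msp(bin_spectra: Mapping[str, Spectrum], path) -> None:
    """Serialize per-bin measured spectra as an MSP file keyed by bin id."""
    SpectralLibrary(LibraryEntry(b, s) for b, s in bin_spectra.items()).to_msp(path)


def read_bin_spectra_msp(path) -> dict[str, Spectrum]:
    return {e.name: e.spectrum for e in SpectralLibrary.from_msp(path)}


# ---------------------------------------------------------------------------
# match factor


def _greedy_pairs(mz_a: tuple[float, ...], mz_b: tuple[float, ...],
                  tol: float) -> list[tuple[int, int]]:
    # candidate pairs sorted by a symmetric key so match_factor(a, b) == match_factor(b, a)
    cands = [(abs(ma - mb), min(ma, mb), max(ma, mb), i, j)
             for i, ma in enumerate(mz_a) for j, mb in enumerate(mz_b)
             if abs(ma - mb) <= tol]
    cands.sort(key=lambda c: c[:3])
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, _, _, i, j in cands:
        if i not in used_a and j not in used_b:
            pairs.append((i, j))
            used_a.add(i)
            used_b.add(j)
    return pairs


def match_factor(query: Spectrum, reference: Spectrum, mz_tolerance: float = 0.5) -> int:
    """Similarity value in 0-999 between two spectra.

    Peaks are paired greedily by nearest m/z within ``mz_tolerance``; the
    score is the cosine between the weighted intensity vectors
    (w = mz^2 * intensity^0.5), with unpaired peaks contributing to the norms
    only.  999 is returned iff the paired peak sets are proportional and
    cover both spectra; 0 when no peaks pair.  Symmetric in its arguments and
    invariant to rescaling either spectrum's intensities.
    """
    if mz_tolerance < 0:
        raise ConfigurationError("mz_tolerance must be non-negative")
    wq = np.array([m ** MZ_POWER * i ** INTENSITY_POWER for m, i in query.peaks])
    wr = np.array([m ** MZ_POWER * i ** INTENSITY_POWER for m, i in reference.peaks])
    pairs = _greedy_pairs(query.mz, reference.mz, mz_tolerance)
    dot = sum(wq[i] * wr[j] for i, j in pairs)
    denom = float(np.linalg.norm(wq) * np.linalg.norm(wr))
    if denom == 0.0 or dot == 0.0:
        return 0
    cos = min(1.0, dot / denom)
    # absorb float rounding so exactly proportional spectra score 999
    return int(math.floor(999.0 * cos + 1e-9))


# ---------------------------------------------------------------------------
# annotation of ranked bins


@dataclass(frozen=True)
class Annotation:
    """A putative bin -> compound assignment."""

    bin_id: str
    compound: str
    similarity_value: int
    rt_delta: float
    accepted: bool


def annotate_bins(ranking, top_k: int, bin_spectra: Mapping[str, Spectrum],
                  library: SpectralLibrary, rt_tolerance: float = 0.05,
                  sv_threshold: int = 700, mz_tolerance: float = 0.5) -> list[Annotation]:
    """Assign the best-matching library compound to each of the top-ranked bins.

    For every bin among the ``top_k`` best-ranked that has a measured
    spectrum, library entries whose retention time lies within
    ``rt_tolerance`` seconds are scored by :func:`match_factor`; the highest
    scoring entry is reported (ties broken alphabetically by compound name).
    ``accepted`` is True only for SV strictly greater than ``sv_threshold``.
    Bins without a spectrum, or without any retention-time candidate, are
    skipped with a logged warning.
    """
    order = list(ranking.order) if hasattr(ranking, "order") else list(ranking)
    if top_k > len(order):
        raise ConfigurationError(f"top_k={top_k} exceeds ranking length {len(order)}")
    annotations: list[Annotation] = []
    n_missing = 0
    for bin_id in order[:top_k]:
        spec = bin_spectra.get(bin_id)
        if spec is None:
            n_missing += 1
            continue
        best: Annotation | None = None
        for entry in library:
            delta = spec.retention_time - entry.spectrum.retention_time
            if math.isnan(delta) or abs(delta) > rt_tolerance:
                continue
            sv = match_factor(spec, entry.spectrum, mz_tolerance)
            if best is None or sv > best.similarity_value or (
                    sv == best.similarity_value and entry.name < best.compound):
                best = Annotation(bin_id, entry.name, sv, delta, sv > sv_threshold)
        if best is None:
            logger.warning("bin %s: no library entry within %.3g s retention time",
                           bin_id, rt_tolerance)
            continue
        annotations.append(best)
    if n_missing:
        logger.warning("%d of the top %d bins had no measured spectrum and were skipped",
                       n_missing, top_k)
    return annotations


def compound_best_sv(annotations: Iterable[Annotation],
                     accepted_only: bool = True) -> dict[str, Annotation]:
    """Deduplicate annotations to one record per compound, keeping the max SV."""
    best: dict[str, Annotation] = {}
    for ann in annotations:
        if accepted_only and not ann.accepted:
            continue
        cur = best.get(ann.compound)
        if cur is None or ann.similarity_value > cur.similarity_value:
            best[ann.compound] = ann
    return best


# ---------------------------------------------------------------------------
# direction of the abundance change


def direction_sign(table: FeatureTable, bin_id: str, exposed_level: float,
                   control_level: float = 0.0) -> str:
    """Sign of the mean abundance change of a bin, exposed relative to control.

    Returns "+", "-" or "0" (exact tie, logged).  The table should already be
    normalized so the comparison reflects relative abundance.
    """
    if bin_id not in table.abundances.columns:
        raise DataError(f"unknown bin id: {bin_id}")
    conc = table.sample_meta["concentration_ug_per_L"].astype(float)
    for level in (exposed_level, control_level):
        if float(level) not in set(conc):
            raise DataError(f"concentration level {level} not present in table")
    col = table.abundances[bin_id]
    diff = col[conc == float(exposed_level)].mean() - col[conc == float(control_level)].mean()
    if diff > 0:
        return "+"
    if diff < 0:
        return "-"
    logger.info("bin %s: exact tie between exposed and control means", bin_id)
    return "0"


def compound_signs(table: FeatureTable, annotations: Iterable[Annotation],
                   exposed_level: float, control_level: float = 0.0,
                   accepted_only: bool = True) -> dict[str, str]:
    """Per-compound direction signs, using each compound's maximum-SV bin."""
    best = compound_best_sv(annotations, accepted_only=accepted_only)
    return {comp: direction_sign(table, ann.bin_id, exposed_level, control_level)
            for comp, ann in sorted(best.items())}


def annotations_to_tsv(annotations: Iterable[Annotation], path) -> None:
    import pandas as pd

    pd.DataFrame([vars(a) for a in annotations]).to_csv(path, sep="\t", index=False)
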