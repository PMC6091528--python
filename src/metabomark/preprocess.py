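"""Normalization, scaling and PCA-based multivariate outlier rejection.

The preprocessing contract is: (1) constant-sum normalization of every
sample row, so profiles are comparable despite global intensity differences
between runs; (2) univariate (auto-)scaling of every bin column to mean 0 and
unit sample variance, dropping constant columns; (3) outlier rejection by
Hotelling's T-squared on the first principal-component scores, flagging
samples outside the 95% confidence ellipse of the score plot.  All
treatments are pooled for preprocessing and the outlier pass runs once.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import f as f_dist
from sklearn.decomposition import PCA

from .errors import DataError
from .feature_table import FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class PreprocessReport:
    """What preprocessing did: flags, dropped columns, flagged samples."""

    normalization_applied: bool = False
    scaling_applied: bool = False
    outlier_sample_ids: list[str] = field(default_factory=list)
    t2_threshold: float = float("nan")
    n_components_used: int = 0
    confidence: float = float("nan")
    dropped_bins: list[str] = field(default_factory=list)
    t2_by_sample: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def constant_sum_normalize(table: FeatureTable) -> FeatureTable:
    """Divide each sample row by its total abundance so rows sum to one."""
    totals = table.abundances.sum(axis=1)
    bad = totals[totals <= 0]
    if len(bad):
        raise DataError(f"sample(s) with non-positive total abundance: {list(bad.index)[:5]}")
    return FeatureTable(table.abundances.div(totals, axis=0), table.sample_meta,
                        table.bin_meta)


def univariate_scale(table: FeatureTable) -> FeatureTable:
    """Autoscale each bin column to mean 0, unit sample variance (ddof=1).

    Zero-variance columns carry no contrast and are dropped with a logged
    message.
    """
    if table.n_samples < 2:
        raise DataError("univariate scaling needs at least 2 samples")
    X = table.abundances
    sd = X.std(axis=0, ddof=1)
    constant = list(X.columns[(sd == 0) | sd.isna()])
    if constant:
        logger.info("dropping %d zero-variance bin column(s): %s%s", len(constant),
                    constant[:5], "..." if len(constant) > 5 else "")
        X = X.drop(columns=constant)
        sd = sd.drop(index=constant)
    scaled = (X - X.mean(axis=0)) / sd
    return FeatureTable(scaled, table.sample_meta, table.bin_meta.loc[scaled.columns])


def _deterministic_sign(components: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Fix PCA sign so each component's largest-|loading| entry is positive."""
    for a in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[a])))
        if components[a, j] < 0:
            components[a] *= -1.0
            scores[:, a] *= -1.0
    return scores


def pca_outliers(table: FeatureTable, confidence: float = 0.95,
                 n_components: int = 2) -> PreprocessReport:
    """Flag samples outside the Hotelling T-squared confidence ellipse.

    PCA scores are computed on the (already normalized and scaled) table;
    each sample's T-squared statistic on the first ``n_components`` scores,
    ``sum_a t_ia^2 / var(t_a)``, is compared with the F-based cutoff
    ``A(n-1)/(n-A) * F_{A, n-A}(confidence)``.  ``confidence=1`` flags
    nothing (infinite threshold).  Deterministic: PCA uses a full SVD with a
    fixed component sign convention, and the result is invariant to sample
    order.
    """
    n = table.n_samples
    if n < n_components + 2:
        raise DataError(f"need at least {n_components + 2} samples for "
                        f"{n_components}-component outlier analysis")
    if not (0 < confidence <= 1):
        raise DataError("confidence must be in (0, 1]")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(table.values())
    scores = _deterministic_sign(pca.components_, scores)
    lam = scores.var(axis=0, ddof=1)
    if np.any(lam <= 0):
        raise DataError("degenerate PCA scores: a component has zero variance")
    t2 = ((scores ** 2) / lam).sum(axis=1)
    a = n_components
    if confidence == 1.0:
        threshold = float("inf")
    else:
        threshold = a * (n - 1) / (n - a) * float(f_dist.ppf(confidence, a, n - a))
    flagged = [sid for sid, v in zip(table.sample_ids, t2) if v > threshold]
    if flagged:
        logger.info("flagged %d outlier sample(s) at %.3g confidence: %s",
                    len(flagged), confidence, flagged)
    return PreprocessReport(outlier_sample_ids=flagged, t2_threshold=threshold,
                            n_components_used=n_components, confidence=confidence,
                            t2_by_sample=dict(zip(table.sample_ids, map(float, t2))))


def preprocess(table: FeatureTable, confidence: float = 0.95,
               n_components: int = 2) -> tuple[FeatureTable, FeatureTable, PreprocessReport]:
    """Run the full contract: normalize, scale, flag and drop outliers.

    Returns ``(normalized, scaled_clean, report)`` where ``normalized`` is the
    constant-sum table on all samples (used later for direction signs) and
    ``scaled_clean`` is the autoscaled table with outliers removed and scaling
    recomputed on the retained samples.
    """
    normalized = constant_sum_normalize(table)
    scaled = univariate_scale(normalized)
    report = pca_outliers(scaled, confidence=confidence, n_components=n_components)
    report.normalization_applied = True
    report.scaling_applied = True
    sd = normalized.abundances.std(axis=0, ddof=1)
    report.dropped_bins = list(normalized.abundances.columns[(sd == 0) | sd.isna()])
    if report.outlier_sample_ids:
        clean = normalized.drop_samples(report.outlier_sample_ids)
        scaled_clean = univariate_scale(clean)
    else:
        scaled_clean = scaled
    return normalized, scaled_clean, report
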