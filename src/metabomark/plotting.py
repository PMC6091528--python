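"""Matplotlib helpers for the two standard result figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_accuracy_curve(curve, ax=None, label=None):
    """Mean repeated-CV accuracy (with +/- 1 sd band) vs. bins retained."""
    if ax is None:
        _, ax = plt.subplots()
    ks = [p[0] for p in curve.points]
    means = [p[1] for p in curve.points]
    sds = [p[2] for p in curve.points]
    ax.plot(ks, means, marker="o", label=label)
    ax.fill_between(ks, [m - s for m, s in zip(means, sds)],
                    [m + s for m, s in zip(means, sds)], alpha=0.2)
    ax.set_xscale("log")
    ax.set_xlabel("top-ranked bins included")
    ax.set_ylabel("classification accuracy")
    ax.set_ylim(0, 1.05)
    return ax


def plot_concentration_accuracies(rows, ax=None, label=None):
    """Biomarker-subset accuracy per exposure concentration."""
    if ax is None:
        _, ax = plt.subplots()
    concs = [r.concentration for r in rows]
    means = [100 * r.mean_accuracy for r in rows]
    sds = [100 * r.sd for r in rows]
    ax.errorbar(concs, means, yerr=sds, marker="s", capsize=3, label=label)
    ax.set_xscale("log")
    ax.set_xlabel("exposure concentration (ug/L)")
    ax.set_ylabel("% accuracy vs. control")
    ax.set_ylim(0, 105)
    return ax
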