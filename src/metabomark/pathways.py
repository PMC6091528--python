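"""Pathway over-representation analysis with topology-aware impact scores.

For each pathway the query compound set is tested against a hypergeometric
null: drawing ``q`` mapped query compounds from a background universe of
``N``, the raw p-value is the upper-tail probability of observing at least
the seen number of pathway hits.  P-values are corrected across pathways by
Benjamini-Hochberg (FDR) and Holm.  In addition, a topology "impact" score
weights each pathway compound by its relative betweenness centrality in the
pathway graph (weights normalized to sum to one; uniform when the graph has
no between-node traffic) and sums the weights of the hit compounds, so hits
at topologically central positions count more than peripheral ones.

Pathway sets are exchanged in GMT format and pathway graphs as two-column
tab-separated edge lists, one file per pathway.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DataError
from .naming import canonical_name

logger = logging.getLogger(__name__)

#: Table column order of the serialized ORA report
ORA_COLUMNS = ["pathway", "Total", "Expected", "Hits", "Raw p", "FDR", "Impact",
               "Holm adjusted"]


@dataclass(frozen=True)
class Pathway:
    name: str
    compounds: frozenset[str]
    graph: nx.Graph

    def __post_init__(self) -> None:
        extra = set(self.graph.nodes) - set(self.compounds)
        if extra:
            raise ConfigurationError(
                f"pathway {self.name}: graph nodes outside the compound set: {sorted(extra)[:5]}")


class PathwayLibrary:
    """Named compound sets with per-pathway graphs over a shared background."""

    def __init__(self, pathways: Iterable[Pathway], background: set[str] | None = None):
        self.pathways: list[Pathway] = list(pathways)
        union = set().union(*(p.compounds for p in self.pathways)) if self.pathways else set()
        self.background: set[str] = set(background) if background is not None else union
        stray = union - self.background
        if stray:
            raise ConfigurationError(
                f"pathway compounds outside the background: {sorted(stray)[:5]}")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    # -- GMT + edge-list I/O ----------------------------------------------
    def to_gmt(self, gmt_path, edges_dir=None) -> None:
        with open(gmt_path, "w") as fh:
            for p in self.pathways:
                fh.write("\t".join([p.name, "synthetic"] + sorted(p.compounds)) + "\n")
        if edges_dir is not None:
            edges_dir = Path(edges_dir)
            edges_dir.mkdir(parents=True, exist_ok=True)
            for p in self.pathways:
                with open(edges_dir / f"{_safe_name(p.name)}.edges.tsv", "w") as fh:
                    for u, v in sorted(map(sorted, p.graph.edges())):
                        fh.write(f"{u}\t{v}\n")

    @classmethod
    def from_gmt(cls, gmt_path, edges_dir=None,
                 background: set[str] | None = None) -> "PathwayLibrary":
        import gseapy

        sets = gseapy.read_gmt(str(gmt_path))
        pathways = []
        for name, members in sets.items():
            members = [m for m in members if m]
            g = nx.Graph()
            g.add_nodes_from(members)
            if edges_dir is not None:
                f = Path(edges_dir) / f"{_safe_name(name)}.edges.tsv"
                if f.exists():
                    for line in f.read_text().splitlines():
                        if line.strip():
                            u, v = line.split("\t")
                            g.add_edge(u, v)
            pathways.append(Pathway(name, frozenset(members), g))
        return cls(pathways, background=background)


def _safe_name(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]+", "_", name)


# ---------------------------------------------------------------------------
# multiple-testing adjustments


def _check_pvalues(p: Sequence[float]) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise DataError("p-values must lie in [0, 1]")
    return arr


def adjust_bh(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    arr = _check_pvalues(p)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


def adjust_holm(p: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order."""
    arr = _check_pvalues(p)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="holm")[1]


# ---------------------------------------------------------------------------
# topology impact


def impact(graph: nx.Graph, hit_compounds: Iterable[str]) -> float:
    """Topology impact of a hit set within a pathway graph, in [0, 1].

    Nodes are weighted by betweenness centrality normalized to sum to one
    across the pathway (uniform 1/n when every centrality is zero, e.g. in a
    complete or two-node graph); the impact is the summed weight of the hit
    nodes.  Hits absent from the graph are skipped with a logged warning.
    """
    n = graph.number_of_nodes()
    if n == 0:
        return 0.0
    bc = nx.betweenness_centrality(graph, normalized=True)
    total = sum(bc.values())
    if total > 0:
        weights = {node: c / total for node, c in bc.items()}
    else:
        weights = {node: 1.0 / n for node in graph.nodes}
    score = 0.0
    for comp in set(hit_compounds):
        if comp not in weights:
            logger.warning("hit compound %r absent from the pathway graph; skipped", comp)
            continue
        score += weights[comp]
    return min(1.0, score)


# ---------------------------------------------------------------------------
# over-representation analysis


@dataclass(frozen=True)
class ORARow:
    """One pathway's row of the enrichment report."""

    pathway: str
    total: int
    expected: float
    hits: int
    raw_p: float
    fdr: float
    holm: float
    impact: float

    def to_dict(self) -> dict:
        return {"pathway": self.pathway, "Total": self.total, "Expected": self.expected,
                "Hits": self.hits, "Raw p": self.raw_p, "FDR": self.fdr,
                "Impact": self.impact, "Holm adjusted": self.holm}


def ora(query: Iterable[str], library: PathwayLibrary) -> list[ORARow]:
    """Hypergeometric over-representation of a compound set in each pathway.

    Query compounds are matched to the library background by canonical name;
    unmapped ones are dropped with a logged count.  For a pathway of size K
    in a background of N with q mapped query compounds and h hits, the raw
    p-value is P(X >= h) for X ~ Hypergeometric(N, K, q) and the expected hit
    count is K*q/N.  Rows are sorted by raw p, then pathway name.
    """
    background = sorted(library.background)
    canon_bg = {canonical_name(c): c for c in background}
    mapped: set[str] = set()
    n_unmapped = 0
    for comp in set(query):
        hit = canon_bg.get(canonical_name(comp))
        if hit is None:
            n_unmapped += 1
        else:
            mapped.add(hit)
    if n_unmapped:
        logger.warning("%d query compounds could not be mapped to the background", n_unmapped)
    if not mapped:
        raise DataError("no query compound maps to the pathway background")

    N = len(background)
    q = len(mapped)
    rows = []
    for p in library:
        hits = mapped & p.compounds
        h = len(hits)
        K = len(p.compounds)
        raw_p = float(hypergeom.sf(h - 1, N, K, q))
        rows.append((p, h, K, raw_p, hits))
    raw = [r[3] for r in rows]
    fdr = adjust_bh(raw)
    holm = adjust_holm(raw)
    out = [ORARow(pathway=p.name, total=K, expected=K * q / N, hits=h,
                  raw_p=raw_p, fdr=float(f), holm=float(hl),
                  impact=impact(p.graph, hits))
           for (p, h, K, raw_p, hits), f, hl in zip(rows, fdr, holm)]
    out.sort(key=lambda r: (r.raw_p, r.pathway))
    return out


def report_pathways(rows: Sequence[ORARow], min_hits: int = 3) -> list[ORARow]:
    """Keep pathways with at least ``min_hits`` query hits, preserving order."""
    return [r for r in rows if r.hits >= min_hits]


def ora_table(rows: Sequence[ORARow]) -> pd.DataFrame:
    """Rows as a DataFrame in the canonical report column order."""
    if not rows:
        return pd.DataFrame(columns=ORA_COLUMNS)
    return pd.DataFrame([r.to_dict() for r in rows])[ORA_COLUMNS]
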