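"""Lying functional connectivity networks (LFCNs).

An LFCN for a frequency band is the graph whose edges are the selected
lying connections of that band with a positive guilty-minus-innocent mean
coherence difference in the P300-processing period (Delta3); Delta3 is
the edge weight.  Edges with negative Delta3 are removed (a band whose
every selected connection weakens under deception yields an empty
network).  Edges are ordered by descending weight, ties broken by
canonical pair order, so rankings are deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import CHANNELS, LAYOUT_2D, canonical_pair, channel_index, map_regions
from .stats import DeltaTable, StatMatrixSet


@dataclass
class LFCN:
    """Per-band weighted edge list over the 12-electrode scalp graph."""

    band: str
    edges: list[tuple[tuple[str, str], float]]  # (pair, delta3 weight > 0)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def top_edges(self, k: int) -> list[tuple[tuple[str, str], float]]:
        """First ``k`` edges by descending weight (all edges if k is larger)."""
        if k < 0:
            raise ValueError("k must be >= 0")
        return self.edges[:k]

    def region_summary(self) -> pd.DataFrame:
        """Edges annotated with the scalp regions of both endpoints."""
        rows = []
        for (a, b), w in self.edges:
            rows.append(
                {
                    "pair": f"{a}-{b}",
                    "weight": w,
                    "regions_a": "/".join(map_regions(a)),
                    "regions_b": "/".join(map_regions(b)),
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialise with electrode coordinates for scalp plotting."""
        payload = {
            "format": "lfcnet-network",
            "band": self.band,
            "edges": [
                {"pair": list(pair), "weight": float(w)} for pair, w in self.edges
            ],
            "layout": {c: list(LAYOUT_2D[c]) for c in CHANNELS},
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "LFCN":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        if payload.get("format") != "lfcnet-network":
            raise ValueError("not an lfcnet network file")
        edges = [
            (canonical_pair(*e["pair"]), float(e["weight"])) for e in payload["edges"]
        ]
        return cls(band=payload["band"], edges=edges)


def _edge_sort_key(item: tuple[tuple[str, str], float]):
    (a, b), w = item
    return (-w, channel_index(a), channel_index(b))


def build_network(stat: StatMatrixSet, deltas: DeltaTable, band: str | None = None) -> LFCN:
    """Construct the band's LFCN from its L matrix and Delta3 table.

    Edges are the upper-triangle 1s of L whose Delta3 is strictly positive,
    weighted by Delta3; an empty network is valid output.
    """
    band = band or stat.band
    if deltas.band != stat.band:
        raise ValueError(f"band mismatch: {stat.band} vs {deltas.band}")
    d3 = deltas.table.set_index("pair")["delta3"]
    edges = []
    for a, b in stat.selected_pairs():
        w = float(d3[f"{a}-{b}"])
        if w > 0:
            edges.append(((a, b), w))
    edges.sort(key=_edge_sort_key)
    return LFCN(band=band, edges=edges)


def top_edges(network: LFCN, k: int) -> list[tuple[tuple[str, str], float]]:
    return network.top_edges(k)


def edge_list_text(network: LFCN) -> str:
    """Plain-text edge list export: 'pair<TAB>weight' per line."""
    lines = [f"{a}-{b}\t{w:.6f}" for (a, b), w in network.edges]
    return "\n".join(lines) + ("\n" if lines else "")


def plot_network(network: LFCN, ax=None):
    """Scalp-graph rendering of the network (line width tracks weight)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    wmax = max((w for _, w in network.edges), default=1.0)
    for (a, b), w in network.edges:
        xa, ya = LAYOUT_2D[a]
        xb, yb = LAYOUT_2D[b]
        ax.plot([xa, xb], [ya, yb], "k-", lw=0.5 + 3.0 * w / wmax, alpha=0.8)
    for c in CHANNELS:
        x, y = LAYOUT_2D[c]
        ax.plot(x, y, "o", color="w", mec="k", ms=14, zorder=3)
        ax.text(x, y, c, ha="center", va="center", fontsize=7, zorder=4)
    circle = np.linspace(0, 2 * np.pi, 100)
    ax.plot(1.05 * np.cos(circle), 1.05 * np.sin(circle), color="0.6", lw=1)
    ax.set_title(f"{network.band} LFCN ({network.n_edges} edges)")
    ax.set_aspect("equal")
    ax.axis("off")
    return ax
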