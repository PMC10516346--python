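"""Directed competitive-interaction networks.

Four complete directed graphs summarise the assay, all per pH:

* ``single_control`` / ``svs_control`` — edge width i→j is the ratio of
  species i's mean control growth rate to species j's (so opposing widths
  multiply to 1);
* ``eoc_wins`` — edge width i→j is the percentage of competition plates on
  which plug i's effect-of-competition value exceeded plug j's, exact ties
  counting half to each side (opposing widths sum to 100);
* ``ioa`` — edge width i→j is species i's mean antagonism score against j.

Node size is the sum of a species' outgoing edge widths.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CompetitiveNetwork",
    "build_control_network",
    "build_eoc_network",
    "build_ioa_network",
    "export_network",
    "load_network",
]

METRICS = ("single_control", "svs_control", "eoc_wins", "ioa")


@dataclass
class CompetitiveNetwork:
    metric: str
    ph: float
    nodes: dict                      # species -> size (out-width sum)
    edges: dict                      # (i, j) -> width

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        for (i, j), w in self.edges.items():
            if w < 0:
                raise ValueError(f"negative edge width on {i}->{j}")

    @property
    def species(self) -> list:
        return sorted(self.nodes)

    def to_graph(self):
        """The network as a ``networkx.DiGraph`` (width/size attributes)."""
        import networkx as nx

        g = nx.DiGraph(metric=self.metric, ph=self.ph)
        for s, size in self.nodes.items():
            g.add_node(s, size=size)
        for (i, j), w in self.edges.items():
            g.add_edge(i, j, width=w)
        return g


def _finalize(metric: str, ph: float, edges: dict) -> CompetitiveNetwork:
    nodes: dict = {}
    for (i, j), w in edges.items():
        nodes.setdefault(j, 0.0)
        nodes[i] = nodes.get(i, 0.0) + w
    return CompetitiveNetwork(metric=metric, ph=ph, nodes=nodes, edges=edges)


def build_control_network(fits: pd.DataFrame, ph: float, which: str = "svs") -> CompetitiveNetwork:
    """Control-growth network: width(i→j) = mean rate of i / mean rate of j.

    ``which`` selects the ``"single"`` or ``"svs"`` control treatment; the
    SvS fits table should already have one plug selected per plate.
    """
    treatment = {"single": "single", "svs": "SvS"}[which.lower()]
    sub = fits[(fits["treatment"] == treatment) & (fits["ph"] == ph)]
    means = sub.groupby("focal")["rate"].mean()
    if (means <= 0).any():
        bad = sorted(means.index[means <= 0].tolist())
        raise ValueError(f"non-positive mean control rate at pH {ph}: {bad}")
    species = sorted(means.index)
    edges = {
        (i, j): float(means[i] / means[j])
        for i in species
        for j in species
        if i != j
    }
    metric = "single_control" if treatment == "single" else "svs_control"
    return _finalize(metric, ph, edges)


def build_eoc_network(
    eoc_records: pd.DataFrame, ph: float, pooled: bool = False
) -> CompetitiveNetwork:
    """EoC-wins network: percent of plates where i out-performed j.

    By default the two plugs of each competition plate are compared head to
    head (``pooled=False``); exact ties are split 50/50 so that opposing
    widths always sum to 100.  With ``pooled=True`` every cross-plate
    combination of the pair's EoC values is compared instead.
    """
    sub = eoc_records[eoc_records["ph"] == ph]
    edges: dict = {}
    pairs = {tuple(sorted((f, o))) for f, o in zip(sub["focal"], sub["opponent"])}
    for a, b in sorted(pairs):
        pair_rows = sub[
            ((sub["focal"] == a) & (sub["opponent"] == b))
            | ((sub["focal"] == b) & (sub["opponent"] == a))
        ]
        if pooled:
            va = pair_rows.loc[pair_rows["focal"] == a, "eoc"].to_numpy()
            vb = pair_rows.loc[pair_rows["focal"] == b, "eoc"].to_numpy()
            if va.size == 0 or vb.size == 0:
                warnings.warn(f"no usable plates for pair ({a}, {b}) at pH {ph}; edge omitted")
                continue
            diff = va[:, None] - vb[None, :]
            wins_a = (diff > 0).sum() + 0.5 * (diff == 0).sum()
            total = diff.size
        else:
            wide = pair_rows.pivot_table(index="plate_id", columns="focal", values="eoc")
            if a in wide.columns and b in wide.columns:
                wide = wide.dropna()
            else:
                wide = wide.iloc[0:0]
            if wide.empty:
                warnings.warn(f"no usable plates for pair ({a}, {b}) at pH {ph}; edge omitted")
                continue
            diff = wide[a] - wide[b]
            wins_a = float((diff > 0).sum() + 0.5 * (diff == 0).sum())
            total = len(wide)
        edges[(a, b)] = 100.0 * wins_a / total
        edges[(b, a)] = 100.0 - edges[(a, b)]
    return _finalize("eoc_wins", ph, edges)


def build_ioa_network(ioa_records: pd.DataFrame, ph: float) -> CompetitiveNetwork:
    """Antagonism network: width(i→j) = mean IoA score of i against j."""
    sub = ioa_records[ioa_records["ph"] == ph]
    species = sorted(set(sub["focal"]) | set(sub["opponent"]))
    edges: dict = {}
    for i in species:
        for j in species:
            if i == j:
                continue
            scores = np.concatenate(
                [
                    sub.loc[(sub["focal"] == i) & (sub["opponent"] == j), "focal_score"].to_numpy(float),
                    sub.loc[(sub["focal"] == j) & (sub["opponent"] == i), "opponent_score"].to_numpy(float),
                ]
            )
            if scores.size == 0:
                warnings.warn(f"pairing ({i}, {j}) unscored at pH {ph}; edge omitted")
                continue
            edges[(i, j)] = float(scores.mean())
    return _finalize("ioa", ph, edges)


def export_network(network: CompetitiveNetwork, path, format: str = "json") -> Path:
    """Serialise a network to JSON, edge-list CSV, or a static PNG plot."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "json":
        payload = {
            "metric": network.metric,
            "ph": network.ph,
            "nodes": [{"id": s, "size": network.nodes[s]} for s in network.species],
            "edges": [
                {"from": i, "to": j, "width": w}
                for (i, j), w in sorted(network.edges.items())
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["from", "to", "width"])
            for (i, j), w in sorted(network.edges.items()):
                writer.writerow([i, j, repr(w)])
    elif format == "png":
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        import networkx as nx

        g = network.to_graph()
        pos = nx.circular_layout(g)
        sizes = np.array([network.nodes[s] for s in g.nodes])
        widths = np.array([g.edges[e]["width"] for e in g.edges])
        fig, ax = plt.subplots(figsize=(6, 6))
        nx.draw_networkx(
            g,
            pos,
            ax=ax,
            node_size=300 * sizes / sizes.max(),
            width=2.5 * widths / widths.max(),
            connectionstyle="arc3,rad=0.1",
            font_size=7,
        )
        ax.set_title(f"{network.metric} (pH {network.ph})")
        ax.axis("off")
        fig.savefig(path, dpi=150)
        plt.close(fig)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def load_network(path) -> CompetitiveNetwork:
    """Read back a JSON export (inverse of :func:`export_network`)."""
    payload = json.loads(Path(path).read_text())
    return CompetitiveNetwork(
        metric=payload["metric"],
        ph=payload["ph"],
        nodes={n["id"]: n["size"] for n in payload["nodes"]},
        edges={(e["from"], e["to"]): e["width"] for e in payload["edges"]},
    )
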