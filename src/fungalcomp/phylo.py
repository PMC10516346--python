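"""Phylogeny handling: newick parsing and patristic distance matrices.

The patristic distance between two tips is the sum of branch lengths along
the unique path connecting them.  Branch lengths are used exactly as given
(substitutions per site for an inferred tree, arbitrary units for a
simulated one); no ultrametric transformation is applied.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "DistanceMatrix",
    "NewickError",
    "read_newick",
    "patristic_distances",
]


class NewickError(ValueError):
    """Raised for structurally invalid trees (duplicate tips, bad lengths)."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric species-by-species distance matrix.

    Parameters
    ----------
    labels
        Ordered species identifiers; row/column order of ``values``.
    values
        Symmetric nonnegative matrix with zero diagonal.
    kind
        ``"patristic"`` for tree path lengths, ``"growth_rate"`` or
        ``"colony_size"`` for absolute differences of mean baseline growth
        responses.
    ph
        Medium pH the matrix refers to; growth-based distances are computed
        per pH, patristic distances are pH-independent (``None``).
    """

    labels: tuple[str, ...]
    values: np.ndarray
    kind: str = "patristic"
    ph: float | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.labels), len(self.labels)):
            raise ValueError(
                f"matrix shape {vals.shape} does not match {len(self.labels)} labels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels in distance matrix")
        if not np.allclose(vals, vals.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(vals), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (vals < -1e-12).any():
            raise ValueError("negative distances")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "values", vals)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = pair
        idx = {lab: k for k, lab in enumerate(self.labels)}
        return float(self.values[idx[i], idx[j]])

    def subset(self, labels: list[str] | tuple[str, ...]) -> "DistanceMatrix":
        """Restrict to ``labels``, preserving their order."""
        idx = {lab: k for k, lab in enumerate(self.labels)}
        missing = [lab for lab in labels if lab not in idx]
        if missing:
            raise KeyError(f"labels not in matrix: {missing}")
        sel = [idx[lab] for lab in labels]
        return DistanceMatrix(
            tuple(labels), self.values[np.ix_(sel, sel)], kind=self.kind, ph=self.ph
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="species")

    @classmethod
    def from_csv(cls, path, kind: str = "patristic", ph: float | None = None) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("distance CSV rows and columns disagree")
        return cls(tuple(df.index), df.to_numpy(dtype=float), kind=kind, ph=ph)

    def pair_series(self) -> pd.DataFrame:
        """Long table of unordered pairs (i < j by label order) and distances."""
        rows = []
        for a in range(len(self.labels)):
            for b in range(a + 1, len(self.labels)):
                rows.append(
                    {
                        "species_a": self.labels[a],
                        "species_b": self.labels[b],
                        "distance": self.values[a, b],
                    }
                )
        return pd.DataFrame(rows)


def _validate_tree(tree: dendropy.Tree) -> None:
    labels = [t.label for t in tree.taxon_namespace]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise NewickError(f"duplicate tip labels: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:  # root edge may legitimately lack a length
            continue
        if edge.length is None:
            head = edge.head_node
            name = head.taxon.label if head.taxon else "<internal node>"
            raise NewickError(f"missing branch length on edge above {name!r}")
        if edge.length < 0:
            head = edge.head_node
            name = head.taxon.label if head.taxon else "<internal node>"
            raise NewickError(f"negative branch length on edge above {name!r}")


def read_newick(source) -> dendropy.Tree:
    """Parse a rooted newick tree with branch lengths.

    ``source`` may be a filesystem path or a newick string.  Every non-root
    edge must carry a nonnegative length; duplicate tip labels are rejected.
    """
    text = None
    if isinstance(source, str) and source.lstrip().startswith("("):
        text = source
    elif isinstance(source, io.IOBase):
        text = source.read()
    try:
        if text is not None:
            tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
        else:
            tree = dendropy.Tree.get(path=str(source), schema="newick", preserve_underscores=True)
    except Exception as err:  # dendropy raises reader-specific subclasses
        if "Duplicate" in type(err).__name__ or "uplicate" in str(err):
            raise NewickError(f"duplicate tip labels: {err}") from err
        raise
    _validate_tree(tree)
    return tree


def patristic_distances(tree: dendropy.Tree, labels: list[str] | tuple[str, ...]) -> DistanceMatrix:
    """Patristic (path-length) distance matrix over the requested tips.

    Tips of the tree not listed in ``labels`` (e.g. an outgroup) are simply
    ignored; requesting a label that is not a tip raises ``KeyError`` naming
    every missing label.
    """
    _validate_tree(tree)
    taxa = {t.label: t for t in tree.taxon_namespace}
    missing = [lab for lab in labels if lab not in taxa]
    if missing:
        raise KeyError(f"labels absent from tree: {missing}")
    pdm = tree.phylogenetic_distance_matrix()
    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(tuple(labels), vals, kind="patristic", ph=None)
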