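"""System-comparison analytics over LFER coefficient vectors.

Three complementary views of how close a set of systems are in the
(e, s, a, b, v) coefficient space:

* agglomerative clustering of the D' distance matrix (default UPGMA /
  average linkage), rendered as a dendrogram or Newick string;
* principal component analysis of the centered, *unscaled* coefficient
  rows — covariance-matrix PCA, so the high-variance coefficients
  (a, b, v: hydrogen bonding and hydrophobicity) dominate the leading
  components, which is exactly what discriminates membranes;
* a direct emulation screen: every (biological, PAMPA) pair flagged when
  D' falls at or below a threshold (conventionally 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy

from .lfer_core import (
    COEFFICIENT_AXES,
    DistanceMatrix,
    SystemCoefficients,
    dprime_matrix,
)

__all__ = [
    "DendrogramNode",
    "PcaResult",
    "EmulationEntry",
    "hierarchical_cluster",
    "pca_coefficients",
    "compare_to_biological",
    "radial_plot_data",
]

_LINKAGE_METHODS = {"upgma": "average", "average": "average",
                    "single": "single", "complete": "complete"}


@dataclass
class DendrogramNode:
    """Binary merge tree. Leaves carry a label and height 0."""

    height: float
    label: str | None = None
    children: tuple["DendrogramNode", "DendrogramNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return self.children[0].leaves() + self.children[1].leaves()

    def merges(self) -> list[tuple[frozenset, float]]:
        """(leaf set, height) of every internal node, sorted by height."""
        out: list[tuple[frozenset, float]] = []

        def walk(node: "DendrogramNode") -> None:
            if node.is_leaf:
                return
            out.append((frozenset(node.leaves()), node.height))
            walk(node.children[0])
            walk(node.children[1])

        walk(self)
        return sorted(out, key=lambda kv: kv[1])

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""

        def render(node: "DendrogramNode", parent_height: float) -> str:
            length = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{length:.6g}"
            inner = ",".join(render(ch, node.height) for ch in node.children)
            return f"({inner}):{length:.6g}"

        if self.is_leaf:
            return f"{self.label};"
        inner = ",".join(render(ch, self.height) for ch in self.children)
        return f"({inner});"


@dataclass
class PcaResult:
    """Loadings (unit vectors over e,s,a,b,v), explained variance fractions
    (non-increasing), and per-system scores in component space."""

    loadings: np.ndarray  # (k, 5)
    explained_variance_fraction: np.ndarray  # (k,)
    scores: np.ndarray  # (n_systems, k)
    ids: list[str]
    axes: tuple[str, ...] = COEFFICIENT_AXES


@dataclass
class EmulationEntry:
    biological_id: str
    pampa_id: str
    dprime: float
    emulates: bool


def hierarchical_cluster(
    m: DistanceMatrix, linkage: str = "upgma"
) -> DendrogramNode:
    """Agglomerative clustering of a D' matrix into a merge tree.

    Linkage is 'upgma' (average, the default), 'single' or 'complete'.
    scipy's pairing is deterministic (lowest-index pair on ties).
    """
    if len(m.ids) < 2:
        raise ValueError("need at least 2 systems to cluster")
    try:
        method = _LINKAGE_METHODS[linkage.lower()]
    except KeyError:
        raise ValueError(
            f"unknown linkage {linkage!r}; choose from upgma, single, complete"
        ) from None
    Z = hierarchy.linkage(m.condensed(), method=method)
    tree = hierarchy.to_tree(Z)

    def convert(node) -> DendrogramNode:
        if node.is_leaf():
            return DendrogramNode(height=0.0, label=m.ids[node.id])
        return DendrogramNode(
            height=float(node.dist),
            children=(convert(node.get_left()), convert(node.get_right())),
        )

    return convert(tree)


def pca_coefficients(systems: list[SystemCoefficients], k: int = 2) -> PcaResult:
    """Covariance-matrix PCA of the systems' (e, s, a, b, v) rows.

    Rows are centered but not scaled.  Loadings are the orthonormal
    eigenvectors of the covariance matrix, ordered by decreasing
    eigenvalue; the sign convention makes each component's
    largest-magnitude loading positive.
    """
    if len(systems) < 3:
        raise ValueError(f"need at least 3 systems for PCA, got {len(systems)}")
    if not 1 <= k <= len(COEFFICIENT_AXES):
        raise ValueError(f"k must lie in [1, 5], got {k}")
    if k > len(systems):
        raise ValueError(f"cannot extract {k} components from {len(systems)} systems")
    X = np.stack([s.vector() for s in systems])
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (len(systems) - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(eigvecs.shape[1]):
        pivot = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[pivot, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    total = eigvals.sum()
    fractions = eigvals / total if total > 0 else np.zeros_like(eigvals)
    loadings = eigvecs[:, :k].T
    scores = Xc @ eigvecs[:, :k]
    return PcaResult(
        loadings=loadings,
        explained_variance_fraction=fractions[:k],
        scores=scores,
        ids=[s.system_id for s in systems],
    )


def compare_to_biological(
    pampa: list[SystemCoefficients],
    biological: list[SystemCoefficients],
    threshold: float = 1.0,
) -> list[EmulationEntry]:
    """Screen every (biological, PAMPA) pair for emulation ability.

    A PAMPA system is flagged as able to emulate a biological process when
    their D' is at or below ``threshold``.  Distances come from the same
    ``dprime_matrix`` code path as every other analysis.
    """
    if not pampa or not biological:
        raise ValueError("both system lists must be non-empty")
    m = dprime_matrix(list(pampa) + list(biological))
    entries: list[EmulationEntry] = []
    for bio in biological:
        for pam in pampa:
            d = m.get(bio.system_id, pam.system_id)
            entries.append(
                EmulationEntry(
                    biological_id=bio.system_id,
                    pampa_id=pam.system_id,
                    dprime=d,
                    emulates=d <= threshold,
                )
            )
    entries.sort(key=lambda e: e.dprime)
    return entries


def radial_plot_data(systems: list[SystemCoefficients]):
    """Per-system coefficient polygons on the fixed (e,s,a,b,v) axes.

    Returns a DataFrame (rows = systems, columns = axes) ready for a
    radial/spider plot; rendering itself is left to the caller.
    """
    import pandas as pd

    return pd.DataFrame(
        [s.vector() for s in systems],
        index=[s.system_id for s in systems],
        columns=list(COEFFICIENT_AXES),
    )
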