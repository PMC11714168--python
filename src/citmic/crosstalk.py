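"""Individualized cell-cell crosstalk networks.

For one sample, each cell type C and GO biological-process term G are linked
in a bipartite graph with weight

    W[C, G] = J(C, G) * median{ GEP_x : x in C ∩ G }

where J is the Jaccard coefficient of the two gene sets and GEP_x the
sample's expression of gene x. The one-mode projection

    R[i, j] = sum_k W[C_i, G_k] * W[C_j, G_k]      (diagonal set to 0)

is the cell-cell crosstalk adjacency: two cells are connected exactly when
they share at least one GO term, and more strongly the more terms they share
and the more highly the shared genes are expressed.

Only the median factor varies across samples, so the Jaccard matrix and the
per-pair overlap gene indices are precomputed once per cohort
(:class:`OverlapIndex`) and reused for every sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genesets import GeneSetCollection

__all__ = [
    "jaccard_matrix",
    "median_overlap_expression",
    "bipartite_weights",
    "crosstalk_adjacency",
    "OverlapIndex",
    "crosstalk_edge_list",
]


def jaccard_matrix(cells: GeneSetCollection,
                   gos: GeneSetCollection) -> pd.DataFrame:
    """Jaccard coefficients |C∩G| / |C∪G| between every cell and GO set.

    Sample-independent: computed once per cohort. Both collections must
    already be restricted to a common gene universe. A pair of two empty
    sets gets 0.
    """
    if len(cells) == 0 or len(gos) == 0:
        raise ValueError("both collections must be non-empty")
    J = np.zeros((len(cells), len(gos)))
    for i, c in enumerate(cells):
        for j, g in enumerate(gos):
            inter = len(c.genes & g.genes)
            if inter:
                J[i, j] = inter / len(c.genes | g.genes)
    return pd.DataFrame(J, index=cells.names, columns=gos.names)


@dataclass
class OverlapIndex:
    """Precomputed overlap structure for fast per-sample median computation.

    Groups all (cell, GO) pairs with non-empty overlap by overlap size s, so
    each group's medians are one vectorised ``np.median`` over an
    (n_pairs, s) gather of the sample's expression vector.
    """

    cells: list
    go_terms: list
    genes: list
    # per overlap size s: (row idx array, col idx array, (n_pairs, s) gene idx)
    groups: list = field(default_factory=list)

    @classmethod
    def build(cls, cells: GeneSetCollection, gos: GeneSetCollection,
              genes, min_overlap: int = 1) -> "OverlapIndex":
        """Index overlaps against the gene order ``genes`` (the expression
        row order). Every member gene must be present in ``genes``;
        a missing gene means the universe-restriction step was skipped.
        """
        if min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        genes = list(genes)
        pos = {g: k for k, g in enumerate(genes)}
        missing = (set().union(*(s.genes for s in cells), frozenset())
                   | set().union(*(s.genes for s in gos), frozenset())) - pos.keys()
        if missing:
            raise ValueError(
                f"gene(s) in a set but absent from the expression index "
                f"(restrict collections to the measured universe first): "
                f"{sorted(missing)[:5]}"
            )
        by_size: dict[int, list] = {}
        for i, c in enumerate(cells):
            for j, g in enumerate(gos):
                ov = c.genes & g.genes
                if len(ov) >= min_overlap:
                    idx = sorted(pos[x] for x in ov)
                    by_size.setdefault(len(ov), []).append((i, j, idx))
        groups = []
        for s in sorted(by_size):
            entries = by_size[s]
            rows = np.array([e[0] for e in entries], dtype=np.intp)
            cols = np.array([e[1] for e in entries], dtype=np.intp)
            gidx = np.array([e[2] for e in entries], dtype=np.intp)
            groups.append((rows, cols, gidx))
        return cls(cells=cells.names, go_terms=gos.names, genes=genes,
                   groups=groups)

    def median_matrix(self, expr_column: np.ndarray) -> np.ndarray:
        """Medians of the overlapping genes' expression, per (cell, GO) pair.

        Pairs with empty overlap stay 0. Even-sized overlaps use the
        standard midpoint-average median.
        """
        expr_column = np.asarray(expr_column, dtype=float)
        if expr_column.shape != (len(self.genes),):
            raise ValueError(
                f"expression vector has length {expr_column.shape}, "
                f"expected {len(self.genes)}"
            )
        M = np.zeros((len(self.cells), len(self.go_terms)))
        for rows, cols, gidx in self.groups:
            M[rows, cols] = np.median(expr_column[gidx], axis=1)
        return M


def median_overlap_expression(cells: GeneSetCollection,
                              gos: GeneSetCollection,
                              expr_column: pd.Series) -> pd.DataFrame:
    """Median expression of C∩G per (cell, GO) pair for one sample; 0 when
    the overlap is empty."""
    index = OverlapIndex.build(cells, gos, list(expr_column.index))
    M = index.median_matrix(expr_column.to_numpy())
    return pd.DataFrame(M, index=cells.names, columns=gos.names)


def bipartite_weights(J: pd.DataFrame, M: pd.DataFrame) -> pd.DataFrame:
    """Bipartite edge weights W = J ∘ M (elementwise)."""
    if J.shape != M.shape or list(J.index) != list(M.index) \
            or list(J.columns) != list(M.columns):
        raise ValueError("Jaccard and median matrices must be conformable "
                         "with identical row/column orders")
    return J * M


def crosstalk_adjacency(W: pd.DataFrame) -> pd.DataFrame:
    """Project bipartite weights onto cells: R = W·Wᵀ, diagonal zeroed.

    Symmetric by construction; cells sharing no GO term get weight 0.
    """
    Wv = W.to_numpy()
    R = Wv @ Wv.T
    R = (R + R.T) / 2.0  # enforce exact symmetry against FP ordering
    np.fill_diagonal(R, 0.0)
    return pd.DataFrame(R, index=W.index, columns=W.index)


def crosstalk_edge_list(R: pd.DataFrame,
                        include_zero: bool = False) -> pd.DataFrame:
    """Upper-triangle edge list (cell_i, cell_j, weight) of a crosstalk matrix."""
    cells = list(R.index)
    Rv = R.to_numpy()
    rows = []
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            if include_zero or Rv[i, j] != 0:
                rows.append((cells[i], cells[j], Rv[i, j]))
    return pd.DataFrame(rows, columns=["cell_i", "cell_j", "weight"])
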