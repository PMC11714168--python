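"""The :class:`CITMIC` transformer: bulk expression in, infiltration scores out.

The estimator follows scikit-learn conventions (``fit``/``transform``,
``get_params``/``set_params``, trailing-underscore fitted attributes) so it
composes with pipelines and model selection. Rows are samples and columns
are genes, the scikit-learn orientation; the file formats read and written
by :mod:`citmic.expression` and :mod:`citmic.pipeline` keep the
bioinformatics genes-x-samples orientation and the wrappers transpose.

``fit`` learns everything cohort-level and sample-independent: the measured
gene universe after the prevalence filter, the size-filtered and
universe-restricted gene-set collections, the Jaccard matrix and the
overlap index. ``transform`` then scores each sample independently —
bipartite weights, crosstalk projection, random-walk centrality — so a
sample's raw score never depends on which other samples are in the batch.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from . import genesets as gs
from .centrality import RWRConfig, rwr_stationary
from .crosstalk import OverlapIndex, crosstalk_adjacency, jaccard_matrix
from .expression import filter_genes_by_prevalence, validate_expression

__all__ = ["CITMIC", "log_minmax_normalize"]


def log_minmax_normalize(raw: np.ndarray) -> np.ndarray:
    """Per-column: log10, then min-max to [0, 1].

    The raw random-walk scores follow a heavy-tailed, power-law-like
    distribution; log10 tames the extremes before the per-sample min-max
        InScore = (x - min) / (max - min)
    makes columns comparable across samples. A constant column (including
    the single-cell case, max == min) maps to all 0.5 with a warning
    rather than NaN.
    """
    raw = np.asarray(raw, dtype=float)
    if (raw <= 0).any():
        raise ValueError("raw scores must be strictly positive before log10")
    logv = np.log10(raw)
    lo = logv.min(axis=0)
    hi = logv.max(axis=0)
    span = hi - lo
    const = span == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} sample(s) have constant scores across all "
            "cells; their normalized scores are set to 0.5", RuntimeWarning)
    out = np.full_like(logv, 0.5)
    ok = ~const
    if ok.any():
        out[:, ok] = (logv[:, ok] - lo[ok]) / span[ok]
    return out


class CITMIC(BaseEstimator, TransformerMixin):
    """Cell-infiltration scoring via individualized crosstalk networks.

    For each sample, cell types are linked to GO biological-process terms
    they share genes with (edge weight = Jaccard coefficient x median
    expression of the shared genes), the bipartite graph is projected to a
    cell-cell crosstalk network, and each cell's infiltration score is its
    restarted-random-walk centrality in that network, log10-transformed and
    min-max normalized within the sample.

    Parameters
    ----------
    cell_sets : GeneSetCollection or None
        Cell-type signature sets; None loads the packaged collection.
    go_sets : GeneSetCollection or None
        GO-BP sets; None loads the packaged collection.
    exclude_non_solid : bool
        With packaged signatures, drop cell types absent from solid tumors
        (pro-B cells, hematopoietic stem cells, common lymphoid progenitors).
    min_set_size, max_set_size : int
        GO-set size band; sets outside [15, 350] are excluded by default.
    prevalence_fraction : float or None
        Keep genes expressed in at least this fraction of samples (0.5 by
        default); None disables the filter (caller has already filtered).
    expressed_threshold : float
        A gene counts as expressed in a sample when its value exceeds this.
    restrict_sets_to_universe : bool
        Intersect all gene sets with the measured (post-filter) genes before
        computing Jaccard coefficients and medians, keeping both factors in
        the same universe. Disable only for sensitivity analysis.
    min_overlap : int
        Minimum |C ∩ G| for a cell-GO edge (default 1: any shared gene).
    restart_prob, tol, max_iter, dangling_policy
        Random-walk parameters; see :class:`citmic.centrality.RWRConfig`.
    n_jobs : int
        Parallel workers for per-sample scoring; never changes results.

    Attributes
    ----------
    genes_ : list of str
        The measured gene universe after prevalence filtering.
    cell_sets_, go_sets_ : GeneSetCollection
        The collections actually used (size-filtered, universe-restricted).
    cell_names_ : list of str
        Output column order of :meth:`transform`.
    jaccard_ : ndarray of shape (n_cells, n_go)
        Sample-independent Jaccard factor of the bipartite weights.

    Examples
    --------
    >>> est = CITMIC()                      # packaged default collections
    >>> inscore = est.fit_transform(X)      # X: samples x genes DataFrame
    >>> inscore.loc[sample].idxmax()        # most central cell type
    """

    def __init__(self, cell_sets=None, go_sets=None, *,
                 exclude_non_solid=False,
                 min_set_size=gs.DEFAULT_MIN_SET_SIZE,
                 max_set_size=gs.DEFAULT_MAX_SET_SIZE,
                 prevalence_fraction=0.5,
                 expressed_threshold=0.0,
                 restrict_sets_to_universe=True,
                 min_overlap=1,
                 restart_prob=0.15,
                 tol=1e-10,
                 max_iter=1000,
                 dangling_policy="uniform_redistribute",
                 n_jobs=1):
        self.cell_sets = cell_sets
        self.go_sets = go_sets
        self.exclude_non_solid = exclude_non_solid
        self.min_set_size = min_set_size
        self.max_set_size = max_set_size
        self.prevalence_fraction = prevalence_fraction
        self.expressed_threshold = expressed_threshold
        self.restrict_sets_to_universe = restrict_sets_to_universe
        self.min_overlap = min_overlap
        self.restart_prob = restart_prob
        self.tol = tol
        self.max_iter = max_iter
        self.dangling_policy = dangling_policy
        self.n_jobs = n_jobs

    # -- helpers ----------------------------------------------------------

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError(
                "X must be a pandas DataFrame of shape (n_samples, n_genes) "
                "with gene symbols as column names"
            )
        return X

    def rwr_config(self) -> RWRConfig:
        return RWRConfig(restart_prob=self.restart_prob, tol=self.tol,
                         max_iter=self.max_iter,
                         dangling_policy=self.dangling_policy)

    def _check_fitted(self):
        if not hasattr(self, "genes_"):
            raise NotFittedError(
                "This CITMIC instance is not fitted yet; call fit first.")

    # -- estimator API ----------------------------------------------------

    def fit(self, X, y=None):
        """Learn the gene universe and precompute the cohort-level factors.

        Parameters
        ----------
        X : DataFrame of shape (n_samples, n_genes)
            Non-negative log-scale expression (e.g. log2(TPM+1)).
        y : ignored
        """
        X = self._as_frame(X)
        expr = validate_expression(X.T)  # genes x samples internally
        if self.prevalence_fraction is not None:
            expr = filter_genes_by_prevalence(
                expr, self.prevalence_fraction, self.expressed_threshold)
        genes = list(expr.index)

        cells = self.cell_sets
        if cells is None:
            cells = gs.load_packaged_cell_signatures(
                exclude_non_solid=self.exclude_non_solid)
        elif self.exclude_non_solid:
            drop = set(gs.load_packaged_exclusion_list())
            cells = gs.GeneSetCollection(
                [s for s in cells if s.name not in drop], kind=cells.kind)
        gos = self.go_sets
        if gos is None:
            gos = gs.load_packaged_go_bp(self.min_set_size, self.max_set_size)
        else:
            gos = gs.filter_by_size(gos, self.min_set_size, self.max_set_size)
        if self.restrict_sets_to_universe:
            universe = frozenset(genes)
            cells = gs.restrict_to_universe(cells, universe, drop_empty=False)
            gos = gs.restrict_to_universe(gos, universe, drop_empty=True)
        if len(gos) == 0:
            raise ValueError("no GO set survived size filtering / universe "
                             "restriction")
        if len(cells) == 0:
            raise ValueError("no cell signature set available")

        self.genes_ = genes
        self.cell_sets_ = cells
        self.go_sets_ = gos
        self.cell_names_ = cells.names
        self.jaccard_ = jaccard_matrix(cells, gos).to_numpy()
        self.overlap_ = OverlapIndex.build(cells, gos, genes,
                                           min_overlap=self.min_overlap)
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def _expr_matrix(self, X) -> np.ndarray:
        """Validated (n_genes_, n_samples) array in fitted gene order."""
        X = self._as_frame(X)
        missing = set(self.genes_) - set(X.columns)
        if missing:
            raise ValueError(
                f"X lacks {len(missing)} fitted gene(s), e.g. "
                f"{sorted(missing)[:5]}")
        expr = X[self.genes_].T
        validate_expression(expr)
        return expr.to_numpy(dtype=float)

    def _raw_sample(self, expr_column: np.ndarray) -> np.ndarray:
        """Raw random-walk scores for one sample's expression vector."""
        M = self.overlap_.median_matrix(expr_column)
        W = self.jaccard_ * M
        R = crosstalk_adjacency(pd.DataFrame(W, index=self.cell_names_))
        return rwr_stationary(R, self.rwr_config()).scores

    def raw_scores(self, X) -> pd.DataFrame:
        """Pre-log, pre-normalization stationary scores, samples x cells.

        Each row sums to 1; samples are scored independently.
        """
        self._check_fitted()
        expr = self._expr_matrix(X)
        cols = range(expr.shape[1])
        if self.n_jobs == 1:
            scores = [self._raw_sample(expr[:, j]) for j in cols]
        else:
            scores = Parallel(n_jobs=self.n_jobs)(
                delayed(self._raw_sample)(expr[:, j]) for j in cols)
        return pd.DataFrame(np.asarray(scores), index=self._as_frame(X).index,
                            columns=self.cell_names_)

    def transform(self, X) -> pd.DataFrame:
        """Normalized infiltration scores, samples x cells, each in [0, 1].

        Within each sample the most and least central cell types map to 1
        and 0; scores are designed for within-sample cell comparisons and
        for comparing the same cell across samples.
        """
        raw = self.raw_scores(X)
        norm = log_minmax_normalize(raw.to_numpy().T).T
        return pd.DataFrame(norm, index=raw.index, columns=raw.columns)

    def sample_network(self, X, sample) -> pd.DataFrame:
        """The cells x cells crosstalk adjacency of one sample (zero diagonal)."""
        self._check_fitted()
        expr = self._expr_matrix(X)
        j = list(self._as_frame(X).index).index(sample)
        M = self.overlap_.median_matrix(expr[:, j])
        W = self.jaccard_ * M
        return crosstalk_adjacency(pd.DataFrame(W, index=self.cell_names_))

    def get_feature_names_out(self, input_features=None):
        self._check_fitted()
        return np.asarray(self.cell_names_, dtype=object)
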