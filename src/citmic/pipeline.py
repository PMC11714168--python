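"""Cohort-level pipeline functions and the CT-TME linear risk evaluator.

Thin wrappers over :class:`citmic.estimator.CITMIC` in the bioinformatics
orientation: expression genes x samples in, InScore matrix cells x samples
out. The CT-TME (cell crosstalk tumor-microenvironment) score is the linear
combination ``sum_k beta_k * InScore_k`` of selected cells' scores with
externally fitted survival-model coefficients; fitting the coefficients is
out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .centrality import RWRConfig
from .estimator import CITMIC
from .genesets import GeneSetCollection

__all__ = [
    "compute_inscore_sample",
    "compute_inscore_cohort",
    "CTTMEModel",
    "ct_tme_score",
    "write_inscore",
]


def _estimator(cells, gos, cfg: RWRConfig, min_overlap: int = 1) -> CITMIC:
    # collections are taken as given: no size filter, no prevalence filter
    return CITMIC(cells, gos,
                  min_set_size=1, max_set_size=float("inf"),
                  prevalence_fraction=None,
                  restrict_sets_to_universe=False,
                  min_overlap=min_overlap,
                  restart_prob=cfg.restart_prob, tol=cfg.tol,
                  max_iter=cfg.max_iter, dangling_policy=cfg.dangling_policy)


def compute_inscore_sample(expr_column: pd.Series,
                           cells: GeneSetCollection,
                           gos: GeneSetCollection,
                           cfg: RWRConfig = RWRConfig()) -> pd.Series:
    """Raw (pre-log, pre-normalization) random-walk scores for one sample.

    ``expr_column`` is the sample's expression indexed by gene symbol; the
    collections must already be restricted to that gene universe.
    """
    X = expr_column.to_frame(name=expr_column.name or "sample").T
    est = _estimator(cells, gos, cfg).fit(X)
    return est.raw_scores(X).iloc[0]


def compute_inscore_cohort(expr: pd.DataFrame,
                           cells: GeneSetCollection,
                           gos: GeneSetCollection,
                           cfg: RWRConfig = RWRConfig()) -> pd.DataFrame:
    """Normalized InScore matrix (cells x samples, values in [0, 1]).

    ``expr`` is genes x samples, already prevalence-filtered, with the
    collections restricted to its gene universe. Per sample: raw scores,
    log10, min-max; columns are processed independently, so cohort
    composition never changes a sample's raw scores.
    """
    est = _estimator(cells, gos, cfg).fit(expr.T)
    return est.transform(expr.T).T


@dataclass(frozen=True)
class CTTMEModel:
    """Linear risk model: ordered (cell name, coefficient) terms."""

    terms: tuple

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(
            (str(c), float(b)) for c, b in self.terms))
        names = [c for c, _ in self.terms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate cell names in model terms")
        if not all(np.isfinite(b) for _, b in self.terms):
            raise ValueError("coefficients must be finite")

    @classmethod
    def from_tsv(cls, path) -> "CTTMEModel":
        """Read a two-column TSV (cell name, beta)."""
        terms = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            terms.append((parts[0], float(parts[1])))
        return cls(tuple(terms))


def ct_tme_score(inscores: pd.DataFrame, model: CTTMEModel) -> pd.Series:
    """CT-TME score = sum_k beta_k * InScore_k, per sample.

    ``inscores`` is cells x samples. Every model cell must be present;
    absent names are reported together.
    """
    missing = [c for c, _ in model.terms if c not in inscores.index]
    if missing:
        raise KeyError(f"model cell(s) absent from InScore matrix: {missing}")
    scores = np.zeros(inscores.shape[1])
    for cell, beta in model.terms:
        scores = scores + beta * inscores.loc[cell].to_numpy(dtype=float)
    return pd.Series(scores, index=inscores.columns, name="ct_tme_score")


def write_inscore(inscores: pd.DataFrame, path, delimiter: str = "\t") -> None:
    """Write a cells x samples InScore matrix (rows = cells)."""
    inscores.to_csv(path, sep=delimiter, index_label="cell")
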