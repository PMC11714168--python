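"""Synthetic cohorts with known cell-infiltration ground truth.

The generator emulates the statistical structure the crosstalk model
assumes: a gene universe; cell-type signature sets; GO-like function sets
that share genes with the signatures (so cells become linked through common
functions); and log-scale expression in which chosen cell types'
*exclusive* signature genes (genes in exactly one cell set, so ground truth
is unambiguous) are up-shifted by a known effect size in chosen samples.
Everything is reproducible from the seed and writes/reads the same
GMT/TSV formats as the main pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import validate_expression, write_expression
from .genesets import GeneSet, GeneSetCollection, write_gmt

__all__ = ["SyntheticSpec", "SyntheticCohort", "generate", "write_cohort"]

_CATEGORY_CYCLE = ("lymphoid", "myeloid", "stem", "stromal", "other")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    Parameters
    ----------
    n_genes : int
        Size of the gene universe (symbols ``G000001``...).
    n_cells, n_go : int
        Number of cell signature sets / GO-like sets.
    genes_per_cell, genes_per_go : (int, int)
        Inclusive size range each set's size is drawn from.
    overlap_rate : float in [0, 1]
        Probability that a GO-set member is drawn from the pooled signature
        genes rather than the rest of the universe; 0 decouples cells from
        functions entirely (all Jaccard coefficients 0).
    n_samples : int
    baseline_log_mean, baseline_log_sd : float
        Log-normal baseline expression, emulating log2(TPM+1)-like
        positive skewed values (defaults 1.0, 0.5).
    spike : tuple of (cell name, sample id, delta)
        Additive up-shift delta >= 0 applied to the cell's exclusive
        signature genes in the sample.
    seed : int
    """

    n_genes: int = 1000
    n_cells: int = 10
    n_go: int = 60
    genes_per_cell: tuple = (15, 40)
    genes_per_go: tuple = (15, 50)
    overlap_rate: float = 0.4
    n_samples: int = 5
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 0.5
    spike: tuple = ()
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "n_cells", "n_go", "n_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 <= self.overlap_rate <= 1):
            raise ValueError("overlap_rate must be in [0, 1]")
        for rng_name in ("genes_per_cell", "genes_per_go"):
            lo, hi = getattr(self, rng_name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{rng_name} must satisfy 1 <= lo <= hi")
            if hi > self.n_genes:
                raise ValueError(f"{rng_name} upper bound exceeds n_genes")
        for cell, sample, delta in self.spike:
            if delta < 0:
                raise ValueError(f"spike delta must be >= 0, got {delta}")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth."""

    expression: pd.DataFrame        # genes x samples
    cell_sets: GeneSetCollection
    go_sets: GeneSetCollection
    spike_table: pd.DataFrame       # columns: cell, sample, delta, n_genes_spiked
    exclusive_genes: dict = field(default_factory=dict)  # cell -> sorted list


def _draw_set(rng: np.random.Generator, pool: np.ndarray,
              size_range: tuple) -> frozenset:
    size = int(rng.integers(size_range[0], size_range[1] + 1))
    return frozenset(rng.choice(pool, size=size, replace=False).tolist())


def generate(spec: SyntheticSpec, max_retries: int = 100) -> SyntheticCohort:
    """Generate a cohort; deterministic given ``spec.seed``.

    When ``overlap_rate > 0`` the GO collection is resampled (bounded
    retries) until every cell set shares at least one gene with at least
    one GO set, so no cell is structurally isolated by accident.
    """
    rng = np.random.default_rng(spec.seed)
    universe = np.array([f"G{i:06d}" for i in range(spec.n_genes)])

    cell_names = [f"cell_{i:02d}" for i in range(spec.n_cells)]
    cell_sets = GeneSetCollection(
        [GeneSet(name, _draw_set(rng, universe, spec.genes_per_cell),
                 category=_CATEGORY_CYCLE[i % len(_CATEGORY_CYCLE)])
         for i, name in enumerate(cell_names)],
        kind="cell_signature")

    sig_pool = np.array(sorted(cell_sets.all_genes()))
    nonsig_pool = np.array(sorted(set(universe) - set(sig_pool)))

    def draw_go_collection() -> GeneSetCollection:
        sets = []
        for j in range(spec.n_go):
            size = int(rng.integers(spec.genes_per_go[0],
                                    spec.genes_per_go[1] + 1))
            take_sig = rng.random(size) < spec.overlap_rate
            n_sig = min(int(take_sig.sum()), len(sig_pool))
            n_non = size - n_sig
            genes: set = set()
            if n_sig:
                genes |= set(rng.choice(sig_pool, n_sig, replace=False))
            if n_non and len(nonsig_pool):
                n_non = min(n_non, len(nonsig_pool))
                genes |= set(rng.choice(nonsig_pool, n_non, replace=False))
            sets.append(GeneSet(f"GO_{j:04d}", frozenset(genes),
                                category="go_bp"))
        return GeneSetCollection(sets, kind="go_bp")

    go_sets = draw_go_collection()
    if spec.overlap_rate > 0:
        go_union = go_sets.all_genes()
        for _ in range(max_retries):
            if all(s.genes & go_union for s in cell_sets):
                break
            go_sets = draw_go_collection()
            go_union = go_sets.all_genes()
        else:
            raise RuntimeError(
                "could not generate a GO collection covering every cell set; "
                "raise overlap_rate or n_go")

    # baseline expression: log-normal, positive, log2(TPM+1)-like scale
    sample_ids = [f"S{j:03d}" for j in range(spec.n_samples)]
    values = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd,
                           size=(spec.n_genes, spec.n_samples))
    expr = pd.DataFrame(values, index=universe, columns=sample_ids)

    # exclusive signature genes: members of exactly one cell set
    counts: dict[str, int] = {}
    for s in cell_sets:
        for g in s.genes:
            counts[g] = counts.get(g, 0) + 1
    exclusive = {s.name: sorted(g for g in s.genes if counts[g] == 1)
                 for s in cell_sets}

    spikes = []
    for cell, sample, delta in spec.spike:
        if cell not in cell_sets:
            raise ValueError(f"spike names unknown cell {cell!r}")
        if sample not in expr.columns:
            raise ValueError(f"spike names unknown sample {sample!r}")
        genes = exclusive[cell]
        expr.loc[genes, sample] += float(delta)
        spikes.append((cell, sample, float(delta), len(genes)))
    spike_table = pd.DataFrame(
        spikes, columns=["cell", "sample", "delta", "n_genes_spiked"])

    validate_expression(expr)
    return SyntheticCohort(expression=expr, cell_sets=cell_sets,
                           go_sets=go_sets, spike_table=spike_table,
                           exclusive_genes=exclusive)


def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Write expression.tsv, cell_sets.gmt, go_sets.gmt, spike_table.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "cell_gmt": outdir / "cell_sets.gmt",
        "go_gmt": outdir / "go_sets.gmt",
        "spike_table": outdir / "spike_table.tsv",
    }
    write_expression(cohort.expression, paths["expression"])
    write_gmt(cohort.cell_sets, paths["cell_gmt"])
    write_gmt(cohort.go_sets, paths["go_gmt"])
    cohort.spike_table.to_csv(paths["spike_table"], sep="\t", index=False)
    return paths
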