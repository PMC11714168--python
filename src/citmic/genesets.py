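"""Gene-set collections: GMT I/O, validation, size filtering, universe restriction.

Two kinds of collections are used throughout the package: cell-type
signature sets (each annotated with a coarse lineage category) and GO
biological-process sets. Both are plain named sets of gene symbols; symbols
are matched exactly (no alias resolution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "CATEGORIES",
    "GeneSet",
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "read_category_table",
    "filter_by_size",
    "restrict_to_universe",
    "load_packaged_cell_signatures",
    "load_packaged_go_bp",
    "load_packaged_exclusion_list",
    "DEFAULT_MIN_SET_SIZE",
    "DEFAULT_MAX_SET_SIZE",
]

#: GO-BP sets with fewer than 15 or more than 350 genes are excluded by default.
DEFAULT_MIN_SET_SIZE = 15
DEFAULT_MAX_SET_SIZE = 350

CATEGORIES = ("lymphoid", "myeloid", "stem", "stromal", "other", "go_bp")


class GmtParseError(ValueError):
    """A GMT line could not be parsed; the message names the line number."""


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols with an optional category label.

    Parameters
    ----------
    name : str
        Unique identifier within a collection.
    genes : frozenset of str
        Non-empty set of gene symbols.
    category : str
        One of ``lymphoid, myeloid, stem, stromal, other, go_bp``.
    """

    name: str
    genes: frozenset = field(default_factory=frozenset)
    category: str = "other"

    def __post_init__(self):
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        object.__setattr__(self, "genes", frozenset(self.genes))
        # Emptiness is rejected at parse time (read_gmt); an empty GeneSet is
        # representable so universe restriction can keep placeholder rows.
        if self.category not in CATEGORIES:
            raise ValueError(
                f"gene set {self.name!r}: unknown category {self.category!r}"
            )

    def __len__(self) -> int:
        return len(self.genes)


class GeneSetCollection:
    """An ordered collection of uniquely named :class:`GeneSet` objects.

    Iteration order is the input order and is deterministic; the order fixes
    row/column order of every downstream matrix.
    """

    def __init__(self, sets: Iterable[GeneSet], kind: str = "cell_signature"):
        if kind not in ("cell_signature", "go_bp"):
            raise ValueError(f"unknown collection kind {kind!r}")
        self.sets = list(sets)
        self.kind = kind
        seen = set()
        for s in self.sets:
            if s.name in seen:
                raise ValueError(f"duplicate gene set name {s.name!r}")
            seen.add(s.name)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, key):
        if isinstance(key, str):
            for s in self.sets:
                if s.name == key:
                    return s
            raise KeyError(key)
        return self.sets[key]

    def __contains__(self, name: str) -> bool:
        return any(s.name == name for s in self.sets)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def all_genes(self) -> frozenset:
        """Union of all member genes."""
        out: set = set()
        for s in self.sets:
            out |= s.genes
        return frozenset(out)

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        wanted = set(names)
        missing = wanted - set(self.names)
        if missing:
            raise KeyError(f"unknown set names: {sorted(missing)}")
        return GeneSetCollection(
            [s for s in self.sets if s.name in wanted], kind=self.kind
        )

    def __repr__(self) -> str:
        return f"GeneSetCollection(kind={self.kind!r}, n_sets={len(self)})"


def read_gmt(path, kind: str = "cell_signature",
             categories: dict[str, str] | None = None) -> GeneSetCollection:
    """Read a GMT file (tab-separated: name, description, gene symbols...).

    Duplicate gene symbols within a line are deduplicated and empty gene
    fields dropped. Lines with fewer than three fields raise
    :class:`GmtParseError` naming the line number; duplicate set names raise
    ``ValueError``.

    Parameters
    ----------
    path : path-like
    kind : {"cell_signature", "go_bp"}
    categories : dict, optional
        Maps set name to category label; sets default to ``go_bp`` for GO
        collections and ``other`` for signatures when absent.
    """
    default_cat = "go_bp" if kind == "go_bp" else "other"
    categories = categories or {}
    sets = []
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise GmtParseError(
                f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                f"got {len(fields)}"
            )
        name = fields[0]
        genes = [g.strip() for g in fields[2:]]
        genes = [g for g in genes if g]
        if not genes:
            raise GmtParseError(f"{path}: line {lineno}: set {name!r} has no genes")
        sets.append(GeneSet(name, frozenset(genes),
                            categories.get(name, default_cat)))
    return GeneSetCollection(sets, kind=kind)


def write_gmt(coll: GeneSetCollection, path) -> None:
    """Write a collection in GMT format (description column = category)."""
    with open(path, "w") as fh:
        for s in coll:
            fh.write("\t".join([s.name, s.category, *sorted(s.genes)]) + "\n")


def read_category_table(path) -> dict[str, str]:
    """Read a two-column TSV (set name, category) into a dict."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}: line {lineno}: expected 2 columns")
        out[parts[0]] = parts[1]
    return out


def filter_by_size(coll: GeneSetCollection,
                   min_size: int = DEFAULT_MIN_SET_SIZE,
                   max_size: float = DEFAULT_MAX_SET_SIZE) -> GeneSetCollection:
    """Retain sets with ``min_size <= |genes| <= max_size``, preserving order.

    Defaults implement the standard GO-BP size filter (15..350 genes):
    very small sets are statistically unstable, very large ones uninformative.
    Idempotent.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if max_size < min_size:
        raise ValueError("max_size must be >= min_size")
    if not math.isinf(max_size):
        max_size = int(max_size)
    return GeneSetCollection(
        [s for s in coll if min_size <= len(s) <= max_size], kind=coll.kind
    )


def restrict_to_universe(coll: GeneSetCollection, universe: Iterable[str],
                         drop_empty: bool = True) -> GeneSetCollection:
    """Intersect every set with a gene universe (e.g. the measured genes).

    Jaccard coefficients and median expressions are only consistent when
    both cell and GO sets live in the same measured-gene universe, so this
    is applied to both collections before any weight computation.

    Parameters
    ----------
    drop_empty : bool
        Remove sets whose intersection with the universe is empty.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    sets = []
    for s in coll:
        genes = s.genes & universe
        if genes or not drop_empty:
            sets.append(replace(s, genes=genes))
    return GeneSetCollection(sets, kind=coll.kind)


# ---------------------------------------------------------------------------
# Packaged default collections.
#
# The shipped cell-signature and GO-BP files are SYNTHETIC stand-ins: they
# reproduce the documented structure of the reference collection (86 cell
# types: 40 lymphoid, 15 myeloid, 11 stem, 11 stromal, 9 other; GO-BP sets
# within the 15..350 size band sharing genes with the signatures) with
# realistic cell-type names but generated gene symbols. They exercise every
# code path and serve as runnable defaults; real analyses should supply
# curated GMTs via the same loaders.
# ---------------------------------------------------------------------------

_DATA_PKG = "citmic.data"
_SIG_GMT = "cell_signatures_synthetic.gmt"
_SIG_CATS = "cell_categories_synthetic.tsv"
_GO_GMT = "go_bp_synthetic.gmt"
_EXCLUDE_TXT = "non_solid_tumor_cells.txt"


def _data_path(name: str) -> Path:
    path = resources.files(_DATA_PKG).joinpath(name)
    if not path.is_file():
        raise FileNotFoundError(
            f"packaged resource {name!r} is missing or corrupt; supply your "
            "own GMT via read_gmt() — all algorithms accept arbitrary "
            "collections"
        )
    return Path(str(path))


def load_packaged_exclusion_list() -> list[str]:
    """Cell types absent from solid tumor tissue (pro-B cells, hematopoietic
    stem cells, common lymphoid progenitors).

    The reference list is open-ended ("etc."); only the explicitly named
    types are packaged, and users can extend the exclusion at call sites.
    """
    text = _data_path(_EXCLUDE_TXT).read_text()
    return [l.strip() for l in text.splitlines()
            if l.strip() and not l.startswith("#")]


def load_packaged_cell_signatures(
        exclude_non_solid: bool = False,
        extra_exclusions: Iterable[str] = ()) -> GeneSetCollection:
    """Load the packaged 86-cell-type signature collection (synthetic stand-in).

    Parameters
    ----------
    exclude_non_solid : bool
        Drop cell types not present in solid tumor tissue (see
        :func:`load_packaged_exclusion_list`), for tumor-biopsy cohorts.
    extra_exclusions : iterable of str
        Additional set names to drop.
    """
    cats = read_category_table(_data_path(_SIG_CATS))
    coll = read_gmt(_data_path(_SIG_GMT), kind="cell_signature", categories=cats)
    if exclude_non_solid:
        drop = set(load_packaged_exclusion_list()) | set(extra_exclusions)
        coll = GeneSetCollection(
            [s for s in coll if s.name not in drop], kind="cell_signature"
        )
    elif extra_exclusions:
        drop = set(extra_exclusions)
        coll = GeneSetCollection(
            [s for s in coll if s.name not in drop], kind="cell_signature"
        )
    return coll


def load_packaged_go_bp(min_size: int = DEFAULT_MIN_SET_SIZE,
                        max_size: int = DEFAULT_MAX_SET_SIZE) -> GeneSetCollection:
    """Load the packaged GO-BP-like collection (synthetic stand-in), size-filtered."""
    coll = read_gmt(_data_path(_GO_GMT), kind="go_bp")
    return filter_by_size(coll, min_size, max_size)
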