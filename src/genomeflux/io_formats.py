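"""Readers, writers and basic containers for the pipeline's file formats.

Trees are Newick with mandatory branch lengths; tabular data are
tab-separated UTF-8 with a single header line and ``#``-prefixed comment
lines. Genome and family identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("genomeflux")

__all__ = [
    "ValidationError",
    "SpeciesTree",
    "CountMatrix",
    "FamilyAnnotation",
    "DEFENSE_CLASSES",
    "NON_DEFENSE",
    "CLASS_VOCABULARY",
    "RATIO_COLUMNS",
    "read_tree",
    "parse_tree",
    "write_tree",
    "midpoint_root",
    "read_count_matrix",
    "write_count_matrix",
    "read_annotation",
    "write_annotation",
    "read_relative_rate_table",
    "write_relative_rate_table",
    "load_table1_fixture",
]


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


# --------------------------------------------------------------------------
# Species trees
# --------------------------------------------------------------------------

class SpeciesTree:
    """A rooted species tree with branch lengths over genome identifiers.

    Thin validated wrapper around a :class:`dendropy.Tree`. The wrapped
    tree is indexed once into flat arrays (postorder node order, parent
    pointers, branch lengths) so that likelihood code can run fully
    vectorized. Edges are identified by their child node.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._index()
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises assorted error types
            raise ValidationError(f"Newick parse failure: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_path(cls, path: str | Path) -> "SpeciesTree":
        text = Path(path).read_text(encoding="utf-8")
        return cls.from_newick(text)

    # -- indexing ---------------------------------------------------------

    def _index(self) -> None:
        nodes = list(self._tree.postorder_node_iter())
        self._nodes = nodes
        pos = {id(n): i for i, n in enumerate(nodes)}
        n = len(nodes)
        self.parent = np.full(n, -1, dtype=int)
        self.branch_lengths = np.zeros(n, dtype=float)
        self.is_leaf = np.zeros(n, dtype=bool)
        labels: list[str | None] = [None] * n
        for i, node in enumerate(nodes):
            if node.parent_node is not None:
                self.parent[i] = pos[id(node.parent_node)]
                self.branch_lengths[i] = (
                    np.nan if node.edge.length is None else float(node.edge.length)
                )
            if node.is_leaf():
                self.is_leaf[i] = True
                labels[i] = node.taxon.label if node.taxon else None
        self.node_labels = labels
        self.root_index = n - 1  # postorder places the root last
        self.leaf_indices = np.flatnonzero(self.is_leaf)
        self.edge_child_indices = np.array(
            [i for i in range(n) if self.parent[i] >= 0], dtype=int
        )
        # stable names for edges/internal nodes: leaf label or N<postorder>
        self.node_names = [
            labels[i] if labels[i] is not None else f"N{i}" for i in range(n)
        ]

    def _validate(self) -> None:
        root = self._tree.seed_node
        if root is None or len(root.child_nodes()) < 2:
            raise ValidationError("tree root must have at least 2 children")
        leaves = [self.node_labels[i] for i in self.leaf_indices]
        if len(leaves) < 2:
            raise ValidationError("tree must have at least 2 leaves")
        if any(l is None for l in leaves):
            raise ValidationError("every leaf must carry a label")
        if len(set(leaves)) != len(leaves):
            raise ValidationError("duplicate leaf labels")
        lengths = self.branch_lengths[self.edge_child_indices]
        if np.isnan(lengths).any():
            raise ValidationError("every non-root edge needs a branch length")
        if (lengths < 0).any() or not np.isfinite(lengths).all():
            raise ValidationError("branch lengths must be finite and >= 0")

    # -- accessors --------------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> list[str]:
        return [self.node_labels[i] for i in self.leaf_indices]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_indices)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edge_child_indices)

    @property
    def edge_names(self) -> list[str]:
        return [self.node_names[i] for i in self.edge_child_indices]

    def children(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.parent == i)

    def leaf_index_map(self) -> dict[str, int]:
        """Leaf label -> postorder node index."""
        return {self.node_labels[i]: i for i in self.leaf_indices}

    def total_tree_length(self) -> float:
        return float(self.branch_lengths[self.edge_child_indices].sum())

    def leaf_distance_matrix(self) -> pd.DataFrame:
        """All leaf-to-leaf path lengths (via the phylogenetic distance matrix)."""
        pdm = self._tree.phylogenetic_distance_matrix()
        labels = self.leaf_labels
        taxa = {t.label: t for t in self._tree.taxon_namespace}
        out = pd.DataFrame(0.0, index=labels, columns=labels)
        for a in labels:
            for b in labels:
                if a != b:
                    out.loc[a, b] = pdm.patristic_distance(taxa[a], taxa[b])
        return out

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def __repr__(self) -> str:  # pragma: no cover
        return f"SpeciesTree(n_leaves={self.n_leaves}, n_edges={self.n_edges})"


def parse_tree(newick: str) -> SpeciesTree:
    """Parse a Newick string into a validated :class:`SpeciesTree`."""
    return SpeciesTree.from_newick(newick)


def read_tree(path: str | Path) -> SpeciesTree:
    """Read a rooted Newick tree with branch lengths from *path*."""
    return SpeciesTree.from_path(path)


def write_tree(tree: SpeciesTree, path: str | Path) -> None:
    Path(path).write_text(tree.as_newick() + "\n", encoding="utf-8")


def midpoint_root(tree: SpeciesTree) -> SpeciesTree:
    """Re-root a tree at the midpoint of its longest leaf-to-leaf path.

    Tip-to-tip path lengths are preserved. A tree whose branch lengths are
    all zero has no defined midpoint and is rejected as degenerate.
    """
    if tree.total_tree_length() <= 0.0:
        raise ValidationError("all-zero branch lengths: midpoint undefined")
    clone = dendropy.Tree(tree.dendropy_tree)
    clone.reroot_at_midpoint(update_bipartitions=False)
    # the new root may carry a stale edge length; clear it
    clone.seed_node.edge.length = None
    return SpeciesTree(clone)


# --------------------------------------------------------------------------
# Gene-family count matrices
# --------------------------------------------------------------------------

class CountMatrix:
    """Families x genomes matrix of non-negative integer gene counts."""

    def __init__(self, frame: pd.DataFrame):
        if frame.index.duplicated().any():
            raise ValidationError("duplicate family IDs")
        if frame.columns.duplicated().any():
            raise ValidationError("duplicate genome IDs")
        values = frame.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if not np.isfinite(values).all():
            raise ValidationError("counts must be finite")
        if (values < 0).any():
            raise ValidationError("counts must be >= 0")
        if not np.array_equal(values, np.round(values)):
            raise ValidationError("counts must be integers")
        self._frame = frame.astype(int)
        self._frame.index.name = None  # IDs are opaque; name is layout only
        self._frame.columns.name = None

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def family_ids(self) -> list[str]:
        return list(self._frame.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self._frame.columns)

    @property
    def n_families(self) -> int:
        return self._frame.shape[0]

    @property
    def n_genomes(self) -> int:
        return self._frame.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self._frame.to_numpy()

    def subset(self, family_ids: Iterable[str]) -> "CountMatrix":
        ids = list(family_ids)
        missing = set(ids) - set(self._frame.index)
        if missing:
            raise ValidationError(f"unknown family IDs: {sorted(missing)[:5]}")
        return CountMatrix(self._frame.loc[ids])

    def aligned_to(self, tree: SpeciesTree) -> "CountMatrix":
        """Reorder genome columns to the tree's leaves; labels must match."""
        leaves = tree.leaf_labels
        if set(leaves) != set(self._frame.columns):
            raise ValidationError("genome IDs do not match tree leaf labels")
        return CountMatrix(self._frame[leaves])

    def max_count(self) -> int:
        return int(self._frame.to_numpy().max(initial=0))

    def drop_all_zero(self) -> "CountMatrix":
        mask = self._frame.sum(axis=1) > 0
        n_dropped = int((~mask).sum())
        if n_dropped:
            logger.warning("dropping %d all-zero family rows", n_dropped)
        return CountMatrix(self._frame.loc[mask])

    def __repr__(self) -> str:  # pragma: no cover
        return f"CountMatrix({self.n_families} families x {self.n_genomes} genomes)"


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a TSV count matrix: header = genome IDs, first column = family ID."""
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    if frame.empty:
        raise ValidationError(f"empty count matrix: {path}")
    try:
        numeric = frame.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return CountMatrix(numeric)


def write_count_matrix(matrix: CountMatrix, path: str | Path,
                       header_comment: str | None = None) -> None:
    _write_tsv(matrix.frame, path, header_comment, index_label="family_id")


# --------------------------------------------------------------------------
# Family annotations
# --------------------------------------------------------------------------

DEFENSE_CLASSES = ("RM", "TA", "CRISPR-Cas", "Abi", "other-defense")
NON_DEFENSE = "non-defense"
CLASS_VOCABULARY = DEFENSE_CLASSES + (NON_DEFENSE,)


class FamilyAnnotation:
    """Mapping family ID -> defense class label (closed vocabulary)."""

    def __init__(self, mapping: Mapping[str, str]):
        bad = {c for c in mapping.values() if c not in CLASS_VOCABULARY}
        if bad:
            raise ValidationError(
                f"unknown class labels {sorted(bad)}; allowed: {CLASS_VOCABULARY}"
            )
        self._mapping = dict(mapping)

    @property
    def mapping(self) -> dict[str, str]:
        return dict(self._mapping)

    def class_of(self, family_id: str) -> str:
        return self._mapping.get(family_id, NON_DEFENSE)

    def is_defense(self, family_id: str) -> bool:
        return self.class_of(family_id) != NON_DEFENSE

    @property
    def defense_families(self) -> list[str]:
        return [f for f, c in self._mapping.items() if c != NON_DEFENSE]

    def families_of_class(self, klass: str) -> list[str]:
        return [f for f, c in self._mapping.items() if c == klass]

    def __len__(self) -> int:
        return len(self._mapping)


def read_annotation(path: str | Path) -> FamilyAnnotation:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(frame.columns[:2]) != ["family_id", "class"]:
        raise ValidationError("annotation TSV needs columns: family_id, class")
    if frame["family_id"].duplicated().any():
        raise ValidationError("duplicate family IDs in annotation")
    return FamilyAnnotation(dict(zip(frame["family_id"], frame["class"])))


def write_annotation(annotation: FamilyAnnotation, path: str | Path,
                     header_comment: str | None = None) -> None:
    frame = pd.DataFrame(
        sorted(annotation.mapping.items()), columns=["family_id", "class"]
    )
    _write_tsv(frame, path, header_comment, index=False)


# --------------------------------------------------------------------------
# Relative-rate tables (Table 1 layout)
# --------------------------------------------------------------------------

RATIO_COLUMNS = (
    "gain_ratio", "loss_ratio", "expansion_ratio", "reduction_ratio",
    "all_gde_ratio",
)


def _validate_rate_table(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("genus",) + RATIO_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"relative-rate table missing columns: {missing}")
    if frame.index.duplicated().any():
        raise ValidationError("duplicate ATGC row keys")
    vals = frame[list(RATIO_COLUMNS)].to_numpy(dtype=float)
    if np.nanmin(vals, initial=0.0) < 0:
        raise ValidationError("ratios must be >= 0")
    return frame


def read_relative_rate_table(path: str | Path) -> pd.DataFrame:
    """Read a Table 1-style relative-rate table (index: ATGC ID)."""
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    frame.index = frame.index.astype(str)
    return _validate_rate_table(frame)


def write_relative_rate_table(frame: pd.DataFrame, path: str | Path,
                              header_comment: str | None = None) -> None:
    _validate_rate_table(frame)
    _write_tsv(frame, path, header_comment, index_label="atgc")


def load_table1_fixture() -> pd.DataFrame:
    """The packaged 36-ATGC defense-vs-all relative-rate table.

    Values are stored at the printed precision (2 decimals). Columns:
    genus plus the five ratio columns; index: ATGC identifier.
    """
    ref = resources.files("genomeflux").joinpath(
        "data/table1_defense_relative_rates.tsv"
    )
    with resources.as_file(ref) as p:
        return read_relative_rate_table(p)


# --------------------------------------------------------------------------
# Shared TSV writer
# --------------------------------------------------------------------------

def _write_tsv(frame: pd.DataFrame, path: str | Path,
               header_comment: str | None = None, *,
               index: bool = True, index_label: str | None = None) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=index, index_label=index_label)
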