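"""Phylogenies, diet-count tables, and their merger.

The analyses in this package start from two inputs: a rooted, time-calibrated
(ultrametric) phylogeny and a species-by-prey-category table of observed prey
counts.  This module reads and validates both, maps raw prey taxon records
into a fixed category scheme, and prunes/merges them into a matched pair
(tree restricted to sampled species, table ordered like the tree's tips).

Trees are parsed with dendropy and converted into a light array-based
:class:`Phylogeny` (parent pointers, branch lengths, pre/postorder) that the
samplers and flux code operate on directly.

Species name matching is exact after whitespace/underscore normalization:
leading/trailing whitespace is stripped and internal runs of whitespace are
replaced by a single underscore.
"""
from __future__ import annotations

import io
import logging
import os
import re
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("trophoshift")

#: relative tip-depth spread (fraction of tree height) above which a tree is
#: flagged as non-ultrametric; published time trees carry rounding noise below this
ULTRAMETRIC_WARN = 1e-6
#: relative tip-depth spread above which age-based analyses refuse the tree
ULTRAMETRIC_FAIL = 1e-3

#: Default 22 prey-group header.  The analysis scheme groups prey by higher
#: taxonomy; this list covers the groups commonly distinguished in the snake
#: natural-history literature.  It is a default only -- the category scheme and
#: the taxon->category mapping are user-editable inputs.
DEFAULT_PREY_GROUPS = [
    "annelids", "amphisbaenians", "amphibian_eggs", "amphibian_larvae",
    "birds", "bird_eggs", "caecilians", "centipedes", "crocodilians",
    "crustaceans", "fishes", "frogs", "insects", "lizards", "mammals",
    "salamanders", "scorpions", "slugs", "snails", "snakes", "spiders",
    "squamate_eggs",
]


def normalize_name(name: str) -> str:
    """Whitespace/underscore normalization used for species-name matching."""
    return re.sub(r"\s+", "_", str(name).strip())


class NonUltrametricError(ValueError):
    """Raised when a tree's tip depths spread more than the hard tolerance."""


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

@dataclass
class Phylogeny:
    """Rooted tree as flat arrays.

    Node indices: tips are ``0..n_tips-1`` (order of :attr:`tip_labels`),
    internal nodes follow.  ``parent[root] == -1`` and ``blen[root] == 0``.
    Polytomies are allowed and treated as hard.
    """

    parent: np.ndarray
    blen: np.ndarray
    tip_labels: list[str]
    root: int

    children: list[list[int]] = field(init=False, repr=False)
    postorder: np.ndarray = field(init=False, repr=False)
    preorder: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.blen = np.asarray(self.blen, dtype=float)
        n = self.parent.size
        if self.blen.size != n:
            raise ValueError("parent and blen must have equal length")
        if np.any(self.blen < 0):
            raise ValueError("negative branch length")
        if (self.parent == -1).sum() != 1 or self.parent[self.root] != -1:
            raise ValueError("tree must have exactly one root")
        labels = [normalize_name(x) for x in self.tip_labels]
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels are not unique")
        self.tip_labels = labels
        self.children = [[] for _ in range(n)]
        for i in range(n):
            if i != self.root:
                self.children[self.parent[i]].append(i)
        for i in range(self.n_tips):
            if self.children[i]:
                raise ValueError("tips must be leaves")
        # iterative preorder/postorder
        pre: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            pre.append(v)
            stack.extend(reversed(self.children[v]))
        self.preorder = np.array(pre, dtype=int)
        self.postorder = self.preorder[::-1].copy()

    # -- basic properties ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def is_tip(self, v: int) -> bool:
        return v < self.n_tips

    @property
    def total_length(self) -> float:
        """Sum of all branch lengths."""
        return float(self.blen.sum())

    # -- depths and ages ----------------------------------------------------
    def depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        d = np.zeros(self.n_nodes)
        for v in self.preorder:
            if v != self.root:
                d[v] = d[self.parent[v]] + self.blen[v]
        return d

    def ultrametric_deviation(self) -> float:
        """Relative spread of root-to-tip path lengths (fraction of height)."""
        d = self.depths()[: self.n_tips]
        h = d.max()
        if h == 0:
            return 0.0
        return float((d.max() - d.min()) / h)

    def node_ages(self, tol: float = ULTRAMETRIC_FAIL) -> np.ndarray:
        """Age (time before present) of every node; tips are at age 0.

        Requires an ultrametric tree: raises :class:`NonUltrametricError` if
        the relative tip-depth spread exceeds ``tol``.
        """
        dev = self.ultrametric_deviation()
        if dev > tol:
            raise NonUltrametricError(
                f"tip depths spread {dev:.3g} of tree height (tol {tol:g})")
        d = self.depths()
        ages = d[: self.n_tips].max() - d
        ages[: self.n_tips] = 0.0
        return ages

    def subtree_nodes(self, v: int) -> np.ndarray:
        """All nodes in the clade rooted at ``v`` (including ``v``)."""
        out = []
        stack = [v]
        while stack:
            u = stack.pop()
            out.append(u)
            stack.extend(self.children[u])
        return np.array(out, dtype=int)

    def path_to_root(self, v: int) -> list[int]:
        """Nodes from ``v``'s parent up to and including the root."""
        out = []
        u = self.parent[v]
        while u != -1:
            out.append(u)
            u = self.parent[u]
        return out

    def patristic_matrix(self) -> np.ndarray:
        """Pairwise tip-to-tip path-length distances, shape (n_tips, n_tips)."""
        n = self.n_tips
        d = self.depths()
        dist = np.zeros((n, n))
        below: dict[int, np.ndarray] = {i: np.array([i]) for i in range(n)}
        for v in self.postorder:
            if self.is_tip(v):
                continue
            groups = [below.pop(c) for c in self.children[v]]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    ii = groups[a][:, None]
                    jj = groups[b][None, :]
                    val = d[ii] + d[jj] - 2.0 * d[v]
                    dist[ii, jj] = val
                    dist[jj.T, ii.T] = val.T
            below[v] = np.concatenate(groups)
        return dist

    # -- dendropy interop ---------------------------------------------------
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Phylogeny":
        leaves = [lf for lf in dtree.leaf_node_iter()]
        internals = [nd for nd in dtree.preorder_node_iter() if not nd.is_leaf()]
        index = {}
        for i, nd in enumerate(leaves):
            index[id(nd)] = i
        for j, nd in enumerate(internals):
            index[id(nd)] = len(leaves) + j
        n = len(leaves) + len(internals)
        parent = np.full(n, -1, dtype=int)
        blen = np.zeros(n)
        for nd in dtree.preorder_node_iter():
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                blen[i] = nd.edge.length if nd.edge.length is not None else 0.0
        labels = [lf.taxon.label if lf.taxon is not None else f"tip{i}"
                  for i, lf in enumerate(leaves)]
        root = index[id(dtree.seed_node)]
        return cls(parent=parent, blen=blen, tip_labels=labels, root=root)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace(self.tip_labels)
        nodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for i in range(self.n_tips):
            nodes[i].taxon = taxa.get_taxon(self.tip_labels[i])
        for i in range(self.n_nodes):
            if i != self.root:
                nodes[self.parent[i]].add_child(nodes[i])
                nodes[i].edge.length = float(self.blen[i])
        tree = dendropy.Tree(taxon_namespace=taxa)
        tree.seed_node = nodes[self.root]
        return tree

    def write_newick(self, path: str) -> None:
        self.to_dendropy().write(path=path, schema="newick",
                                 suppress_rooting=True)


def read_tree(source: str, strict_ultrametric: bool = False) -> Phylogeny:
    """Read a newick tree from a file path or a newick string.

    Warns if root-to-tip depths spread more than ``ULTRAMETRIC_WARN`` of tree
    height; with ``strict_ultrametric`` a spread beyond ``ULTRAMETRIC_FAIL``
    raises instead.
    """
    if os.path.exists(source):
        dtree = dendropy.Tree.get(path=source, schema="newick")
    else:
        try:
            dtree = dendropy.Tree.get(data=source, schema="newick")
        except Exception as exc:  # unparseable newick
            raise ValueError(f"could not parse newick input: {exc}") from exc
    tree = Phylogeny.from_dendropy(dtree)
    dev = tree.ultrametric_deviation()
    if dev > ULTRAMETRIC_WARN:
        msg = (f"tree is not ultrametric: tip depths spread {dev:.3g} "
               f"of tree height")
        if strict_ultrametric and dev > ULTRAMETRIC_FAIL:
            raise NonUltrametricError(msg)
        warnings.warn(msg, stacklevel=2)
    return tree


# ---------------------------------------------------------------------------
# Prey categories and count tables
# ---------------------------------------------------------------------------

@dataclass
class PreyCategories:
    """Ordered prey-category scheme with an optional taxon->category mapping.

    ``colors`` (if given) is a (J, 3) array of RGB triples in [0, 1] used for
    additive color mixing of diet states.
    """

    names: list[str]
    colors: np.ndarray | None = None
    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.names) < 2:
            raise ValueError("need at least 2 prey categories")
        if len(set(self.names)) != len(self.names):
            raise ValueError("category names must be unique")
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=float)
            if self.colors.shape != (len(self.names), 3):
                raise ValueError("colors must be (J, 3)")
            if self.colors.min() < 0 or self.colors.max() > 1:
                raise ValueError("color channels must lie in [0, 1]")
        for taxon, cat in self.mapping.items():
            if cat not in self.names:
                raise ValueError(f"mapping target {cat!r} is not a category")
        self.index = {name: j for j, name in enumerate(self.names)}

    @property
    def J(self) -> int:
        return len(self.names)

    @classmethod
    def default(cls) -> "PreyCategories":
        return cls(names=list(DEFAULT_PREY_GROUPS))

    @classmethod
    def from_table(cls, path: str, names: list[str] | None = None) -> "PreyCategories":
        """Load a two-column (taxon, category) mapping table (CSV/TSV)."""
        df = pd.read_csv(path, sep=None, engine="python")
        if df.shape[1] < 2:
            raise ValueError("mapping table needs (taxon, category) columns")
        mapping = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
        if names is None:
            names = sorted(set(mapping.values()))
        return cls(names=names, mapping=mapping)


@dataclass
class DietCountTable:
    """Species x category matrix of non-negative integer prey counts."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("count table must be numeric")
        if np.any(arr < 0):
            raise ValueError("negative count")
        if np.any(arr != np.round(arr)):
            raise ValueError("non-integer count")
        self.counts = df.astype(np.int64)
        self.counts.index = [normalize_name(s) for s in df.index]

    @property
    def species(self) -> list[str]:
        return list(self.counts.index)

    @property
    def categories(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def J(self) -> int:
        return self.counts.shape[1]

    @property
    def totals(self) -> pd.Series:
        """Per-species total number of observed prey records (N_i)."""
        return self.counts.sum(axis=1)

    def to_array(self, species_order: list[str] | None = None) -> np.ndarray:
        if species_order is None:
            return self.counts.to_numpy()
        return self.counts.loc[species_order].to_numpy()


def read_diet_counts(path_or_buf, categories: PreyCategories | None = None,
                     ) -> DietCountTable:
    """Read a delimited species x category count table.

    The first column holds species names.  Rows sharing a species name are
    aggregated by summation (the analysis uses one composite diet per
    species).  All-zero species are dropped with a log notice.
    """
    df = pd.read_csv(path_or_buf, sep=None, engine="python", index_col=0)
    if categories is not None:
        cols = list(df.columns)
        unknown = [c for c in cols if c not in categories.index]
        if unknown:
            raise ValueError(f"unknown category column(s): {unknown}")
        df = df.reindex(columns=categories.names, fill_value=0)
    df = df.groupby(level=0, sort=False).sum()
    table = DietCountTable(df)
    empty = table.totals == 0
    if empty.any():
        dropped = list(table.counts.index[empty])
        logger.info("dropping %d species with no observations: %s",
                    len(dropped), dropped)
        table = DietCountTable(table.counts.loc[~empty.to_numpy()])
    return table


def map_prey_categories(raw_records, categories: PreyCategories,
                        ) -> tuple[DietCountTable, list[tuple[str, str, int]]]:
    """Bin raw (species, prey-taxon, count) records into categories.

    Returns the aggregated count table and the list of unmappable records
    (reported, not silently dropped).
    """
    rows: dict[str, np.ndarray] = {}
    unmapped: list[tuple[str, str, int]] = []
    for species, taxon, count in raw_records:
        count = int(count)
        if count < 0:
            raise ValueError("negative record count")
        cat = categories.mapping.get(str(taxon))
        if cat is None:
            unmapped.append((str(species), str(taxon), count))
            continue
        sp = normalize_name(species)
        row = rows.setdefault(sp, np.zeros(categories.J, dtype=np.int64))
        row[categories.index[cat]] += count
    if unmapped:
        logger.warning("%d record(s) with unmappable prey taxa: %s",
                       len(unmapped), sorted({t for _, t, _ in unmapped}))
    df = pd.DataFrame.from_dict(rows, orient="index", columns=categories.names)
    return DietCountTable(df), unmapped


def merge_and_prune(tree: Phylogeny, table: DietCountTable,
                    ) -> tuple[Phylogeny, DietCountTable]:
    """Restrict tree and table to their common, observed species.

    The returned tree keeps only tips with at least one observation; internal
    degree-2 nodes created by pruning are suppressed with branch lengths
    summed, so patristic distances among retained tips are preserved.  The
    returned table rows follow the returned tree's tip order.
    """
    observed = set(table.counts.index[table.totals.to_numpy() > 0])
    keep = [lb for lb in tree.tip_labels if lb in observed]
    if not keep:
        raise ValueError("no species shared between tree and count table")
    extra = sorted(observed - set(tree.tip_labels))
    if extra:
        logger.info("dropping %d species absent from the tree", len(extra))
    if len(keep) == tree.n_tips:
        pruned = tree
    else:
        dtree = tree.to_dendropy()
        dtree.retain_taxa_with_labels(keep)
        pruned = Phylogeny.from_dendropy(dtree)
    out = DietCountTable(table.counts.loc[pruned.tip_labels])
    return pruned, out
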