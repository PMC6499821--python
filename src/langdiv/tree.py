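"""Language trees from tabular taxonomies.

The world's languages have no accepted global phylogeny, but language
atlases classify every language into a nested taxonomy (family, then
progressively finer subgroups).  This module turns such a taxonomy into a
rooted tree whose tips are languages, whose internal nodes are taxonomy
groups, and whose base is an unresolved star joining all families: the
taxonomy says nothing about between-family relationships, so any two
languages from different families sit at the maximum patristic distance
from each other.

Branch lengths are assigned by ultrametric depth-normalisation: every
root-to-tip path has total length 1.0, internal taxonomy edges get equal
shares of the deepest chain, and the pendant (tip) edge absorbs the
remainder.  This guarantees the maximum-distance property above and makes
downstream branch-length-based similarity measures scale-free.  A
``unit_branch_lengths`` switch is available for sensitivity analysis.

Language isolates are their own families: a classification path equal to
``[language_id]`` attaches the tip directly under the root with length 1.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TaxonomyError",
    "NewickParseError",
    "LanguageTree",
    "build_tree",
    "read_taxonomy_csv",
    "write_taxonomy_csv",
]


class TaxonomyError(ValueError):
    """Raised for an inconsistent taxonomy table.

    Parameters
    ----------
    message : str
        Description of the problem.
    language_id : str, optional
        The offending language, when one can be named.
    """

    def __init__(self, message: str, language_id: str | None = None):
        self.language_id = language_id
        if language_id is not None:
            message = f"{message} (language_id={language_id!r})"
        super().__init__(message)


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


def _normalize_taxonomy(
    taxonomy: pd.DataFrame | Mapping[str, Sequence[str]] | Iterable,
) -> list[tuple[str, tuple[str, ...]]]:
    """Coerce the accepted taxonomy representations to sorted (id, path) rows.

    Accepts a DataFrame with a ``language_id`` column plus ragged
    ``level_*`` columns (empty cells allowed), a mapping ``id -> path``, or
    an iterable of ``(id, path)`` pairs.  Rows are sorted by id so that the
    built tree is independent of input row order.
    """
    rows: list[tuple[str, tuple[str, ...]]] = []
    if isinstance(taxonomy, pd.DataFrame):
        if "language_id" not in taxonomy.columns:
            raise TaxonomyError("taxonomy table needs a 'language_id' column")
        level_cols = [c for c in taxonomy.columns if c.startswith("level_")]
        level_cols.sort(key=lambda c: int(c.split("_", 1)[1]))
        for _, r in taxonomy.iterrows():
            path = tuple(
                str(r[c]).strip()
                for c in level_cols
                if not pd.isna(r[c]) and str(r[c]).strip() != ""
            )
            rows.append((str(r["language_id"]), path))
    elif isinstance(taxonomy, Mapping):
        rows = [(str(k), tuple(str(p) for p in v)) for k, v in taxonomy.items()]
    else:
        rows = [(str(k), tuple(str(p) for p in v)) for k, v in taxonomy]
    rows.sort(key=lambda r: r[0])
    return rows


class LanguageTree:
    """A rooted language tree wrapping a :class:`dendropy.Tree`.

    Tips are languages (dendropy taxa); internal nodes are taxonomy groups
    (node labels).  The root is a star over families.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._edge_cache: tuple[np.ndarray, np.ndarray, dict[str, int]] | None = None

    # -- basic accessors ---------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return tuple(sorted(t.label for t in self._tree.taxon_namespace))

    @property
    def n_tips(self) -> int:
        return len(self._tree.taxon_namespace)

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length for every tip."""
        depths: dict[str, float] = {}
        for leaf in self._tree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            depths[leaf.taxon.label] = d
        return depths

    # -- patristic distances ----------------------------------------------

    def patristic_matrix(
        self, labels: Sequence[str] | None = None
    ) -> tuple[list[str], np.ndarray]:
        """Pairwise patristic distance matrix over tips.

        Returns the label order used and the symmetric distance matrix.
        """
        if labels is None:
            labels = list(self.tip_labels)
        else:
            labels = list(labels)
        pdm = self._tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self._tree.taxon_namespace}
        missing = [lab for lab in labels if lab not in taxa]
        if missing:
            raise TaxonomyError("tip not in tree", language_id=missing[0])
        n = len(labels)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
                D[i, j] = D[j, i] = d
        return labels, D

    # -- edge bookkeeping for branch-length similarity ---------------------

    def edge_tip_incidence(self) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
        """Edge lengths and the edge-by-tip descendant incidence matrix.

        Returns ``(lengths, incidence, tip_index)`` where ``incidence[e, t]``
        is True iff tip ``t`` descends through edge ``e``.  An edge belongs
        to the rooted spanning subtree of a tip set S iff its descendant set
        intersects S, so this is the whole bookkeeping branch-length
        beta-diversity needs.  The (lengthless) root edge is excluded.
        """
        if self._edge_cache is not None:
            return self._edge_cache
        labels = self.tip_labels
        tip_index = {lab: i for i, lab in enumerate(labels)}
        lengths: list[float] = []
        rows: list[np.ndarray] = []
        below: dict[int, np.ndarray] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                mask = np.zeros(len(labels), dtype=bool)
                mask[tip_index[node.taxon.label]] = True
            else:
                mask = np.zeros(len(labels), dtype=bool)
                for ch in node.child_nodes():
                    mask |= below[id(ch)]
            below[id(node)] = mask
            if node.parent_node is not None:
                if node.edge.length is None:
                    raise TaxonomyError("tree has an edge with no length")
                lengths.append(float(node.edge.length))
                rows.append(mask)
        cache = (np.asarray(lengths), np.vstack(rows), tip_index)
        self._edge_cache = cache
        return cache

    # -- serialization -----------------------------------------------------

    def write_newick(self) -> str:
        """Serialize to Newick with branch lengths at full precision."""
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".17g",
        )
        return s.strip()

    @classmethod
    def from_newick(cls, text: str) -> "LanguageTree":
        """Parse a Newick string into a :class:`LanguageTree`.

        Raises
        ------
        NewickParseError
            If the string is empty or malformed; the message carries
            dendropy's position information where available.
        """
        if not text or not text.strip():
            raise NewickParseError("empty Newick string")
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several error classes
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        if tree is None or next(tree.leaf_node_iter(), None) is None:
            raise NewickParseError("Newick string contains no tree")
        return cls(tree)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<LanguageTree with {self.n_tips} tips>"


def _validate(rows: list[tuple[str, tuple[str, ...]]]) -> None:
    seen: set[str] = set()
    for lid, path in rows:
        if lid in seen:
            raise TaxonomyError("duplicate language_id", language_id=lid)
        seen.add(lid)
        if len(path) == 0:
            raise TaxonomyError("empty classification path", language_id=lid)
    # a language id may not double as a taxonomy group of another language
    group_names: set[str] = set()
    for lid, path in rows:
        if len(path) == 1 and path[0] == lid:
            continue  # isolate: path is the id itself
        group_names.update(path)
    for lid, _ in rows:
        if lid in group_names:
            raise TaxonomyError(
                "language_id also appears as a taxonomy group", language_id=lid
            )


def build_tree(
    taxonomy: pd.DataFrame | Mapping[str, Sequence[str]] | Iterable,
    *,
    unit_branch_lengths: bool = False,
) -> LanguageTree:
    """Build the global language tree from a taxonomy table.

    Paths sharing a prefix are merged into shared internal nodes; the root
    is a star over families (outermost path entries).  With the default
    depth-normalised branch lengths every tip sits at depth 1.0, so the
    patristic distance between any two languages from different families is
    exactly 2.0 — the maximum over all pairs.

    Parameters
    ----------
    taxonomy
        DataFrame (``language_id`` + ragged ``level_*`` columns), mapping
        ``id -> path``, or iterable of ``(id, path)``.
    unit_branch_lengths
        If True, give every edge length 1 instead (sensitivity switch; the
        maximum-distance property then only holds for equal-depth chains).
    """
    rows = _normalize_taxonomy(taxonomy)
    if not rows:
        raise TaxonomyError("empty taxonomy")
    _validate(rows)

    # chain length in edges from root to tip
    def chain_len(lid: str, path: tuple[str, ...]) -> int:
        if len(path) == 1 and path[0] == lid:
            return 1  # isolate: tip directly under root
        return len(path) + 1

    K = max(chain_len(lid, path) for lid, path in rows)

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    groups: dict[tuple[str, ...], dendropy.Node] = {}

    internal_len = 1.0  # unit lengths
    for lid, path in rows:
        isolate = len(path) == 1 and path[0] == lid
        parent = root
        level = 0
        if not isolate:
            prefix: tuple[str, ...] = ()
            for name in path:
                prefix = prefix + (name,)
                level += 1
                node = groups.get(prefix)
                if node is None:
                    node = dendropy.Node(label=name)
                    parent.add_child(node)
                    node.edge.length = (
                        internal_len if unit_branch_lengths else 1.0 / K
                    )
                    groups[prefix] = node
                node = groups[prefix]
                parent = node
        tip = dendropy.Node(taxon=tns.new_taxon(label=lid))
        parent.add_child(tip)
        if unit_branch_lengths:
            tip.edge.length = 1.0
        else:
            tip.edge.length = 1.0 - level / K
    # deterministic serialization: children sorted lexicographically
    for node in tree.preorder_node_iter():
        node._child_nodes.sort(
            key=lambda c: c.taxon.label if c.taxon is not None else (c.label or "")
        )
    return LanguageTree(tree)


def read_taxonomy_csv(path) -> pd.DataFrame:
    """Read a taxonomy CSV (columns ``language_id, level_1..level_k``)."""
    df = pd.read_csv(path, dtype=str)
    if "language_id" not in df.columns:
        raise TaxonomyError("taxonomy CSV needs a 'language_id' column")
    return df


def write_taxonomy_csv(rows: Mapping[str, Sequence[str]] | Iterable, path) -> None:
    """Write a taxonomy (mapping or (id, path) rows) as a ragged-level CSV."""
    norm = _normalize_taxonomy(rows)
    k = max(len(p) for _, p in norm)
    records = []
    for lid, path_ in norm:
        rec = {"language_id": lid}
        for i in range(k):
            rec[f"level_{i + 1}"] = path_[i] if i < len(path_) else ""
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, index=False)
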