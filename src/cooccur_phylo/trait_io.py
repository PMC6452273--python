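"""Reading, writing and reconciling trees and binary trait tables.

Trees are handled as :class:`dendropy.Tree` objects (rooted, tip labels
unique, branch lengths non-negative).  Trait tables are tab-delimited text
with a header row of trait ids, a second ``#group:`` row assigning each
trait to one of the groups ``system`` / ``cas`` / ``control``, and one row
per genome; they are held in memory as a :class:`TraitMatrix`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_GROUPS = ("system", "cas", "control")

GROUP_ROW_PREFIX = "#group:"


class TraitTableError(ValueError):
    """Raised when a trait table violates the format contract."""


class TreeError(ValueError):
    """Raised when a tree violates the format contract."""


@dataclass
class TraitMatrix:
    """Binary genomes x traits matrix with a group label per trait.

    Attributes
    ----------
    values : pandas.DataFrame
        0/1 integer matrix, index = genome ids, columns = trait ids.
    groups : pandas.Series
        Group label per trait id, each one of ``system``, ``cas``,
        ``control``.
    """

    values: pd.DataFrame
    groups: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if self.groups is None:
            self.groups = pd.Series("system", index=self.values.columns)
        self.groups = self.groups.reindex(self.values.columns)
        self.validate()

    def validate(self) -> None:
        df = self.values
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise TraitTableError(f"duplicated genome id: {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise TraitTableError(f"duplicated trait id: {dup!r}")
        arr = df.to_numpy()
        if arr.size and not np.isin(arr, (0, 1)).all():
            bad = np.argwhere(~np.isin(arr, (0, 1)))[0]
            raise TraitTableError(
                f"non-binary cell at genome {df.index[bad[0]]!r}, "
                f"trait {df.columns[bad[1]]!r}: {arr[tuple(bad)]!r}"
            )
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()][0]
            raise TraitTableError(f"trait {missing!r} has no group label")
        bad_groups = set(self.groups) - set(VALID_GROUPS)
        if bad_groups:
            raise TraitTableError(
                f"unknown trait group(s) {sorted(bad_groups)}; "
                f"expected one of {VALID_GROUPS}"
            )

    @property
    def genome_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def trait_ids(self) -> list[str]:
        return list(self.values.columns)

    def traits_in_group(self, group: str) -> list[str]:
        if group not in VALID_GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return list(self.groups.index[self.groups == group])

    def frequency(self, trait: str) -> float:
        """Presence frequency of ``trait`` across genomes."""
        if trait not in self.values.columns:
            raise KeyError(f"unknown trait id {trait!r}")
        return float(self.values[trait].mean())

    def frequencies(self) -> pd.Series:
        return self.values.mean(axis=0)

    def subset_genomes(self, genome_ids) -> "TraitMatrix":
        missing = set(genome_ids) - set(self.values.index)
        if missing:
            raise KeyError(f"unknown genome ids: {sorted(missing)[:5]}")
        return TraitMatrix(self.values.loc[list(genome_ids)], self.groups.copy())

    def subset_traits(self, trait_ids) -> "TraitMatrix":
        missing = set(trait_ids) - set(self.values.columns)
        if missing:
            raise KeyError(f"unknown trait ids: {sorted(missing)[:5]}")
        return TraitMatrix(
            self.values[list(trait_ids)], self.groups[list(trait_ids)]
        )

    @staticmethod
    def concat(matrices: list["TraitMatrix"]) -> "TraitMatrix":
        """Column-wise concatenation; genome id sets must match."""
        base = matrices[0].values.index
        for m in matrices[1:]:
            if not base.equals(m.values.index):
                raise TraitTableError("genome ids differ between matrices")
        values = pd.concat([m.values for m in matrices], axis=1)
        groups = pd.concat([m.groups for m in matrices])
        return TraitMatrix(values, groups)


def _validate_tree(tree: dendropy.Tree, source: str = "<tree>") -> dendropy.Tree:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    seen = set()
    for lab in labels:
        if lab in seen:
            raise TreeError(f"{source}: duplicate tip label {lab!r}")
        seen.add(lab)
    defaulted = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 0.0
            defaulted += 1
        elif edge.length < 0:
            raise TreeError(f"{source}: negative branch length {edge.length}")
    if defaulted:
        warnings.warn(
            f"{source}: {defaulted} branch(es) had no length; set to 0",
            stacklevel=3,
        )
    # Root an unrooted basal trifurcation explicitly: likelihood under the
    # reversible models used downstream is invariant to root placement.
    if len(tree.seed_node.child_nodes()) > 2:
        warnings.warn(
            f"{source}: basal multifurcation treated as root "
            "(likelihood is root-invariant under reversible models)",
            stacklevel=3,
        )
    tree.is_rooted = True
    return tree


def _parse_newick(data: str, source: str) -> dendropy.Tree:
    if data.count("(") != data.count(")"):
        raise TreeError(f"{source}: unbalanced parentheses in Newick string")
    try:
        tree = dendropy.Tree.get(
            data=data,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"{source}: malformed Newick: {exc}") from exc
    return _validate_tree(tree, source)


def read_newick(path) -> dendropy.Tree:
    """Read a single rooted tree from a Newick file.

    Missing branch lengths default to 0 (with a warning); duplicate tip
    labels or malformed syntax raise :class:`TreeError`.
    """
    with open(path) as fh:
        data = fh.read().strip()
    if not data.endswith(";"):
        raise TreeError(f"{path}: Newick string must end with ';'")
    return _parse_newick(data, str(path))


def read_newick_list(path) -> list[dendropy.Tree]:
    """Read a multi-tree Newick file, one tree per line."""
    trees = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            trees.append(_parse_newick(line, f"{path}:line {i + 1}"))
    if not trees:
        raise TreeError(f"{path}: no trees found")
    return trees


def _newick_string(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".12g",
    ).strip()


def write_newick(trees, path) -> None:
    """Write one tree or a list of trees, one Newick string per line."""
    if isinstance(trees, dendropy.Tree):
        trees = [trees]
    with open(path, "w") as fh:
        for tree in trees:
            fh.write(_newick_string(tree) + "\n")


def read_trait_table(path, sep: str = "\t") -> TraitMatrix:
    """Read a delimited trait table with a ``#group:`` annotation row."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)
        group_line = fh.readline().rstrip("\n").split(sep)
        if not group_line or group_line[0] != GROUP_ROW_PREFIX:
            raise TraitTableError(
                f"{path}: second row must start with {GROUP_ROW_PREFIX!r}"
            )
        body = pd.read_csv(fh, sep=sep, header=None, index_col=0, dtype=str)
    trait_ids = header[1:]
    if len(group_line) - 1 != len(trait_ids):
        raise TraitTableError(f"{path}: group row length does not match header")
    if body.shape[1] != len(trait_ids):
        raise TraitTableError(f"{path}: data row length does not match header")
    body.columns = trait_ids
    body.index = body.index.astype(str)
    body.index.name = None
    try:
        values = body.astype(int)
    except ValueError:
        mask = ~body.isin(["0", "1"])
        loc = np.argwhere(mask.to_numpy())[0]
        raise TraitTableError(
            f"{path}: non-binary cell at genome {body.index[loc[0]]!r}, "
            f"trait {trait_ids[loc[1]]!r}: {body.iloc[loc[0], loc[1]]!r}"
        ) from None
    groups = pd.Series(group_line[1:], index=trait_ids)
    return TraitMatrix(values, groups)


def write_trait_table(m: TraitMatrix, path, sep: str = "\t") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(sep.join(["genome_id", *m.trait_ids]) + "\n")
        fh.write(sep.join([GROUP_ROW_PREFIX, *m.groups.tolist()]) + "\n")
        for gid, row in m.values.iterrows():
            fh.write(sep.join([str(gid), *map(str, row.tolist())]) + "\n")


def prune_to_taxa(tree: dendropy.Tree, labels) -> dendropy.Tree:
    """Return a copy of ``tree`` restricted to the given tip labels.

    Degree-2 internal nodes created by pruning are collapsed with branch
    lengths summed, so patristic distances among retained tips are exact.
    """
    pruned = tree.clone(depth=1)
    keep = set(labels)
    taxa = [t for t in pruned.taxon_namespace if t.label in keep]
    if len(taxa) != len(keep):
        found = {t.label for t in taxa}
        raise TreeError(f"labels not in tree: {sorted(keep - found)[:5]}")
    pruned.retain_taxa(taxa, suppress_unifurcations=True)
    pruned.purge_taxon_namespace()
    return pruned


def reconcile(
    tree: dendropy.Tree, m: TraitMatrix, policy: str = "strict"
) -> tuple[dendropy.Tree, TraitMatrix]:
    """Reconcile a tree's tip set with a trait matrix's genome set.

    ``strict`` requires the two id sets to be equal; ``intersect`` restricts
    both objects to the shared ids (pruning the tree, preserving patristic
    distances among retained tips).
    """
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    genomes = set(m.genome_ids)
    if policy == "strict":
        if tips != genomes:
            only_tree = sorted(tips - genomes)[:5]
            only_table = sorted(genomes - tips)[:5]
            raise TreeError(
                "strict reconcile failed: tip set != genome set "
                f"(tree-only: {only_tree}, table-only: {only_table})"
            )
        return tree, m
    if policy == "intersect":
        shared = tips & genomes
        if not shared:
            raise TreeError("tree tips and table genomes are disjoint")
        logger.info("reconcile: %d shared ids retained", len(shared))
        if shared == tips and shared == genomes:
            return tree, m
        new_tree = tree if shared == tips else prune_to_taxa(tree, shared)
        order = [g for g in m.genome_ids if g in shared]
        return new_tree, m.subset_genomes(order)
    raise ValueError(f"unknown policy {policy!r}; use 'strict' or 'intersect'")


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]
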