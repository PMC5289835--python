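"""Felsenstein's phylogenetically independent contrasts and their regression.

Comparative data from related species are not independent draws; under a
Brownian-motion model of trait change, the standardized differences between
sister lineages are. At each internal node joining children with values
x1, x2 on (pruned) branch lengths v1, v2:

    contrast  C = (x1 - x2) / sqrt(v1 + v2)
    ancestor  x = (x1/v1 + x2/v2) / (1/v1 + 1/v2)
    parent edge lengthened by v1*v2 / (v1 + v2)

Contrast signs are fixed by a deterministic child ordering (alphabetical by
smallest descendant tip name). Regressions between contrast sets are forced
through the origin, as the method requires, with R^2 measured about zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .statskit import OLSResult, ols


@dataclass
class _Node:
    name: str                      # tip name, or smallest descendant tip
    length: float                  # branch length to parent
    children: list["_Node"] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children


@dataclass
class TraitTree:
    """Rooted tree with branch lengths plus per-tip trait values."""

    root: _Node
    traits: dict[str, dict[str, float]]  # species_id -> trait_name -> value

    @classmethod
    def from_dendropy(
        cls, tree: dendropy.Tree, traits: dict[str, dict[str, float]],
    ) -> "TraitTree":
        root = _convert(tree.seed_node)
        tt = cls(root, traits)
        for tip in tt.tip_names():
            if tip not in traits:
                raise ValueError(f"tip {tip!r} has no trait values")
        return tt

    @classmethod
    def from_newick(
        cls, newick: str | Path, traits: dict[str, dict[str, float]],
    ) -> "TraitTree":
        s = str(newick)
        is_path = "(" not in s and len(s) < 4096
        text = Path(s).read_text() if is_path and Path(s).exists() else s
        tree = dendropy.Tree.get(data=text, schema="newick")
        return cls.from_dendropy(tree, traits)

    def tip_names(self) -> list[str]:
        out: list[str] = []

        def walk(node: _Node) -> None:
            if node.is_tip:
                out.append(node.name)
            for ch in node.children:
                walk(ch)

        walk(self.root)
        return sorted(out)


def _convert(dnode: dendropy.Node) -> _Node:
    """dendropy node -> internal node, resolving polytomies deterministically.

    A polytomy is resolved to a ladder of zero-length bifurcations, joining
    children in order of their smallest descendant tip name.
    """
    length = dnode.edge.length or 0.0
    kids = dnode.child_nodes()
    if not kids:
        name = dnode.taxon.label if dnode.taxon else (dnode.label or "")
        if not name:
            raise ValueError("unnamed tip in tree")
        return _Node(name.replace(" ", "_"), float(length))
    children = sorted((_convert(k) for k in kids), key=lambda n: n.name)
    while len(children) > 2:
        a = children.pop(0)
        b = children.pop(0)
        merged = _Node(min(a.name, b.name), 0.0, [a, b])
        children.append(merged)
        children.sort(key=lambda n: n.name)
    if len(children) == 1:          # unifurcation: collapse into the child
        child = children[0]
        child.length += float(length)
        return child
    return _Node(children[0].name, float(length), children)


@dataclass
class ContrastSet:
    node_ids: list[str]
    contrasts: list[float]

    @property
    def n(self) -> int:
        return len(self.contrasts)


def independent_contrasts(tree: TraitTree, trait: str) -> ContrastSet:
    """One standardized contrast per internal node, in deterministic order."""
    node_ids: list[str] = []
    values: list[float] = []

    def prune(node: _Node) -> tuple[float, float]:
        """Return (trait value, adjusted branch length) for this subtree."""
        if node.is_tip:
            try:
                x = tree.traits[node.name][trait]
            except KeyError:
                raise ValueError(f"tip {node.name!r} missing trait {trait!r}")
            return float(x), node.length
        (x1, v1), (x2, v2) = (prune(ch) for ch in node.children)
        if v1 + v2 <= 0:
            raise ValueError(
                f"zero-length sibling pair at node above {node.name!r}")
        node_ids.append(node.name)
        values.append((x1 - x2) / math.sqrt(v1 + v2))
        anc = (x1 / v1 + x2 / v2) / (1.0 / v1 + 1.0 / v2) if v1 > 0 and v2 > 0 \
            else (x1 if v1 == 0 else x2)
        return anc, node.length + v1 * v2 / (v1 + v2)

    prune(tree.root)
    return ContrastSet(node_ids, values)


def contrast_regression(cs_x: ContrastSet, cs_y: ContrastSet) -> OLSResult:
    """Through-origin least squares of one contrast set on another."""
    if cs_x.node_ids != cs_y.node_ids:
        raise ValueError("contrast sets come from different trees or orderings")
    return ols(cs_x.contrasts, cs_y.contrasts, through_origin=True)


def contrast_correlation(cs_x: ContrastSet, cs_y: ContrastSet) -> float:
    """Through-origin correlation sum(xy)/sqrt(sum x^2 sum y^2)."""
    x = np.asarray(cs_x.contrasts)
    y = np.asarray(cs_y.contrasts)
    denom = math.sqrt(float(x @ x) * float(y @ y))
    if denom == 0:
        return float("nan")
    return float(x @ y) / denom


def batch_contrasts(
    trees: list[TraitTree], x: str, y: str,
) -> dict:
    """Contrast regressions of trait y on trait x over a collection of trees.

    Returns per-tree (slope, r_squared, p) plus a summary with the median,
    minimum and maximum of R^2 and p across trees.
    """
    if not trees:
        raise ValueError("empty tree list")
    tips0 = trees[0].tip_names()
    results: list[OLSResult] = []
    for i, tree in enumerate(trees):
        tips = tree.tip_names()
        if tips != tips0:
            raise ValueError(f"tree {i} has a different tip set")
        cs_x = independent_contrasts(tree, x)
        cs_y = independent_contrasts(tree, y)
        results.append(contrast_regression(cs_x, cs_y))
    r2 = np.array([r.r_squared for r in results])
    p = np.array([r.p_value for r in results])
    return {
        "per_tree": results,
        "summary": {
            "r_squared": {"median": float(np.median(r2)),
                          "min": float(r2.min()), "max": float(r2.max())},
            "p_value": {"median": float(np.median(p)),
                        "min": float(p.min()), "max": float(p.max())},
        },
    }


def read_trait_table(path: str | Path) -> dict[str, dict[str, float]]:
    """TSV with columns species_id, trait_name, value -> nested dict."""
    traits: dict[str, dict[str, float]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["species_id", "trait_name", "value"]:
            raise ValueError("trait table must have columns species_id, trait_name, value")
        for line in fh:
            if not line.strip():
                continue
            sp, name, value = line.rstrip("\n").split("\t")[:3]
            traits.setdefault(sp, {})[name] = float(value)
    return traits
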