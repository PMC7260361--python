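"""Rooted binary time tree: node ages in units of 100 My, leaves at age 0.

Newick parsing goes through dendropy; the in-memory representation is a
small arrayed structure suited to the MCMC inner loop.  Annotated output
(posterior mean ages and HPD bounds encoded in internal-node labels as
``name|age=..|hpd=lo,hi``) round-trips through :meth:`TimeTree.from_newick`.
"""

from __future__ import annotations

import io

import dendropy
import numpy as np


class TimeTree:
    """Rooted tree with per-node ages; children strictly younger than parents."""

    def __init__(self, labels: list[str], parent: list[int], ages: list[float]):
        self.labels = list(labels)
        self.parent = np.asarray(parent, dtype=int)       # -1 for the root
        self.ages = np.asarray(ages, dtype=float)
        self.index = {lab: i for i, lab in enumerate(self.labels)}
        n = len(self.labels)
        self.children: list[list[int]] = [[] for _ in range(n)]
        roots = []
        for i, p in enumerate(self.parent):
            if p < 0:
                roots.append(i)
            else:
                self.children[p].append(i)
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")
        self.root = roots[0]
        self._validate()

    def _validate(self) -> None:
        for i, p in enumerate(self.parent):
            if p >= 0 and not self.ages[p] > self.ages[i]:
                raise ValueError(
                    f"node {self.labels[i]!r} (age {self.ages[i]}) not younger "
                    f"than parent {self.labels[p]!r} (age {self.ages[p]})")
        if not self.ages[self.root] > 0:
            raise ValueError("root age must be > 0")
        for i, kids in enumerate(self.children):
            if kids and self.ages[i] < 0:
                raise ValueError("negative node age")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_children(cls, root: str, children: dict[str, list[str]],
                      ages: dict[str, float]) -> "TimeTree":
        labels: list[str] = []
        parent_of: dict[str, str | None] = {root: None}

        def walk(lab: str) -> None:
            labels.append(lab)
            for kid in children.get(lab, []):
                parent_of[kid] = lab
                walk(kid)

        walk(root)
        idx = {lab: i for i, lab in enumerate(labels)}
        parent = [idx[parent_of[lab]] if parent_of[lab] is not None else -1
                  for lab in labels]
        return cls(labels, parent, [ages[lab] for lab in labels])

    @classmethod
    def from_newick(cls, newick: str) -> "TimeTree":
        """Read a rooted Newick tree; node ages come from branch lengths
        (leaves at 0) unless ``|age=..`` annotations are present."""
        dt = dendropy.Tree.get(data=newick, schema="newick",
                               suppress_internal_node_taxa=False)
        labels, parent, ages = [], [], []
        idx: dict[int, int] = {}
        annotated_ages: dict[int, float] = {}
        auto = 0
        for node in dt.preorder_node_iter():
            raw = None
            if node.taxon is not None:
                raw = node.taxon.label
            elif node.label:
                raw = node.label
            if raw is None:
                auto += 1
                raw = f"node{auto}"
            name = raw
            if "|" in raw:
                name = raw.split("|", 1)[0]
                for part in raw.split("|")[1:]:
                    if part.startswith("age="):
                        annotated_ages[id(node)] = float(part[4:])
            idx[id(node)] = len(labels)
            labels.append(name)
            parent.append(idx[id(node.parent_node)] if node.parent_node else -1)
            ages.append(0.0)

        # depth from root via branch lengths, then age = max depth - depth
        depth = [0.0] * len(labels)
        for node in dt.preorder_node_iter():
            i = idx[id(node)]
            if node.parent_node is not None:
                depth[i] = depth[idx[id(node.parent_node)]] + (node.edge.length or 0.0)
        maxd = max(depth)
        ages = [maxd - d for d in depth]
        for node in dt.preorder_node_iter():
            if id(node) in annotated_ages:
                ages[idx[id(node)]] = annotated_ages[id(node)]
        # leaves are extant: snap tiny numeric residue to 0
        for node in dt.leaf_node_iter():
            i = idx[id(node)]
            if abs(ages[i]) < 1e-9:
                ages[i] = 0.0
        return cls(labels, parent, ages)

    # -- queries -------------------------------------------------------------

    def age(self, label: str) -> float:
        return float(self.ages[self.index[label]])

    def parent_label(self, label: str) -> str:
        p = self.parent[self.index[label]]
        if p < 0:
            raise ValueError(f"{label!r} is the root")
        return self.labels[p]

    @property
    def root_label(self) -> str:
        return self.labels[self.root]

    @property
    def n_tips(self) -> int:
        return sum(1 for kids in self.children if not kids)

    def internal_labels(self) -> list[str]:
        return [self.labels[i] for i, kids in enumerate(self.children) if kids]

    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i, kids in enumerate(self.children) if not kids]

    def branch_labels(self) -> list[str]:
        """Branches identified by their child node, preorder, root excluded."""
        return [lab for lab in self.labels if lab != self.root_label]

    def branch_durations(self) -> dict[str, float]:
        return {lab: self.age(self.parent_label(lab)) - self.age(lab)
                for lab in self.branch_labels()}

    def root_to_tip_times(self) -> dict[str, float]:
        root_age = self.ages[self.root]
        return {lab: float(root_age - self.age(lab)) for lab in self.tip_labels()}

    # -- output --------------------------------------------------------------

    def to_newick(self, annotations: dict[str, tuple[float, float]] | None = None,
                  digits: int = 6) -> str:
        """Serialize with branch lengths = time durations.

        ``annotations`` maps node label -> (hpd_low, hpd_high); annotated
        internal nodes are written as ``name|age=..|hpd=lo,hi``.
        """
        def fmt(i: int) -> str:
            lab = self.labels[i]
            if annotations is not None and lab in annotations:
                lo, hi = annotations[lab]
                lab = (f"'{lab}|age={self.ages[i]:.{digits}g}"
                       f"|hpd={lo:.{digits}g},{hi:.{digits}g}'")
            if self.children[i]:
                inner = ",".join(fmt(c) for c in self.children[i])
                node = f"({inner}){lab}"
            else:
                node = lab
            p = self.parent[i]
            if p >= 0:
                node += f":{self.ages[p] - self.ages[i]:.{digits}g}"
            return node

        return fmt(self.root) + ";"

    def with_ages(self, new_ages: dict[str, float]) -> "TimeTree":
        ages = self.ages.copy()
        for lab, a in new_ages.items():
            ages[self.index[lab]] = a
        return TimeTree(self.labels, self.parent.tolist(), ages.tolist())
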