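"""Phylogenies, branch regime paintings, and phylogenetic covariance matrices.

Trees are rooted, binary (polytomies are resolved at ingestion), with branch
lengths in arbitrary time units.  A :class:`RegimePainting` assigns every
instant along every branch to a discrete regime (e.g. ``continent`` /
``Socotra`` / ``AbdAlKuri``), the representation produced by stochastic
character mapping and consumed by multi-rate Brownian models.

Newick I/O goes through dendropy.  Paintings are serialized in a bracketed
annotation placed after each branch length::

    (A:1.0[&regimes=continent:1.0],B:1.0[&regimes=continent:0.4|Socotra:0.6]);

Segments run from the parent end of the branch to the child end.  Because the
annotation is a Newick comment, painted files remain readable by any standard
Newick parser (the painting is simply ignored).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "RegimePainting",
    "NewickError",
    "PaintingError",
    "read_newick",
    "read_newick_list",
    "write_newick",
    "read_painting",
    "write_painting",
    "vcv",
    "regime_vcv",
    "node_heights",
    "is_ultrametric",
]

DURATION_RTOL = 1e-9


class NewickError(ValueError):
    """Malformed Newick input."""


class PaintingError(ValueError):
    """Invalid or inconsistent regime painting."""


class Phylogeny:
    """Rooted binary tree with branch lengths.

    Nodes are integer ids ``0 .. n_nodes-1``.  Tips occupy ids
    ``0 .. n_tips-1`` in order of first appearance; internal ids follow.
    The root has parent ``-1`` and branch length 0.

    Instances are treated as immutable after construction; derived
    quantities (heights, covariance) are memoized.
    """

    def __init__(self, parent, branch_length, tip_labels, *, children=None,
                 validate=True):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.branch_length = np.asarray(branch_length, dtype=np.float64)
        self.tip_labels = list(tip_labels)
        self.n_nodes = len(self.parent)
        self.n_tips = len(self.tip_labels)
        root = -1
        if children is not None:
            # explicit child order (e.g. Newick appearance order)
            self._children = [list(c) for c in children]
            for i, p in enumerate(self.parent):
                if p < 0:
                    root = i
                elif i not in self._children[p]:
                    raise NewickError("children list inconsistent with parents")
        else:
            self._children = [[] for _ in range(self.n_nodes)]
            for i, p in enumerate(self.parent):
                if p < 0:
                    root = i
                else:
                    self._children[p].append(i)
        self.root = root
        self._cache: dict[str, object] = {}
        if validate:
            self._validate()

    # -- construction checks ------------------------------------------------

    def _validate(self):
        if self.root < 0:
            raise NewickError("tree has no root")
        if np.sum(self.parent < 0) != 1:
            raise NewickError("tree must have exactly one root")
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise NewickError(f"duplicate tip labels: {dup}")
        if any(not l for l in labels):
            raise NewickError("empty tip label")
        for i in range(self.n_nodes):
            kids = self._children[i]
            if i < self.n_tips:
                if kids:
                    raise NewickError(f"tip {labels[i]!r} has children")
            elif len(kids) != 2:
                raise NewickError(
                    f"internal node {i} has {len(kids)} children; trees must "
                    "be binary after ingestion"
                )
        nonroot = np.arange(self.n_nodes) != self.root
        if np.any(self.branch_length[nonroot] < 0):
            raise NewickError("negative branch length")
        if np.any(~np.isfinite(self.branch_length[nonroot])):
            raise NewickError("missing or non-finite branch length")
        # reject cycles / disconnected parts: every node must reach the root
        order = self.postorder()
        if len(order) != self.n_nodes:
            raise NewickError("tree is not connected")

    # -- structure ----------------------------------------------------------

    def children(self, node: int) -> list[int]:
        return self._children[node]

    def is_tip(self, node: int) -> bool:
        return node < self.n_tips

    def postorder(self) -> np.ndarray:
        """Node ids with every child before its parent."""
        if "postorder" not in self._cache:
            order, stack = [], [self.root]
            while stack:
                v = stack.pop()
                order.append(v)
                stack.extend(self._children[v])
            self._cache["postorder"] = np.array(order[::-1], dtype=np.int64)
        return self._cache["postorder"]

    def preorder(self) -> np.ndarray:
        return self.postorder()[::-1]

    @property
    def label_index(self) -> dict[str, int]:
        if "label_index" not in self._cache:
            self._cache["label_index"] = {l: i for i, l in enumerate(self.tip_labels)}
        return self._cache["label_index"]

    @property
    def total_length(self) -> float:
        nonroot = np.arange(self.n_nodes) != self.root
        return float(self.branch_length[nonroot].sum())

    def heights(self) -> np.ndarray:
        """Time from the root to each node."""
        if "heights" not in self._cache:
            h = np.zeros(self.n_nodes)
            for v in self.preorder():
                if v != self.root:
                    h[v] = h[self.parent[v]] + self.branch_length[v]
            self._cache["heights"] = h
        return self._cache["heights"]

    @property
    def depth(self) -> float:
        return float(self.heights()[: self.n_tips].max())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        th = self.heights()[: self.n_tips]
        d = th.max()
        return bool(d == 0 or (th.max() - th.min()) <= rel_tol * d)

    def mrca_heights(self) -> np.ndarray:
        """(n_nodes, n_tips) matrix of MRCA heights between nodes and tips."""
        if "mrca_heights" not in self._cache:
            h = self.heights()
            # descendant tip sets, then shared height = height of deepest
            # common ancestor; computed by propagating tip memberships up.
            n, ntip = self.n_nodes, self.n_tips
            out = np.zeros((n, ntip))
            below = [None] * n
            for v in self.postorder():
                if self.is_tip(v):
                    below[v] = {v}
                else:
                    s = set()
                    for c in self._children[v]:
                        s |= below[c]
                    below[v] = s
            # For node v and tip i: MRCA is the first ancestor of v whose
            # descendant set contains i; walk up from v once per node.
            anc_chain: list[list[int]] = [[] for _ in range(n)]
            for v in self.preorder():
                if v == self.root:
                    anc_chain[v] = [v]
                else:
                    anc_chain[v] = anc_chain[self.parent[v]] + [v]
            for v in range(n):
                chain = anc_chain[v]
                for i in range(ntip):
                    # deepest ancestor containing tip i
                    hv = 0.0
                    for a in chain:
                        if i in below[a]:
                            hv = h[a]
                        else:
                            break
                    out[v, i] = hv
            self._cache["mrca_heights"] = out
        return self._cache["mrca_heights"]

    # -- serialization ------------------------------------------------------

    def newick(self, *, annotations: dict[int, str] | None = None) -> str:
        """Newick string; ``annotations`` maps node id -> comment body."""
        parts = []

        def emit(v: int) -> str:
            if self.is_tip(v):
                s = _quote_label(self.tip_labels[v])
            else:
                a, b = self._children[v]
                s = f"({emit(a)},{emit(b)})"
            if v != self.root:
                s += f":{self.branch_length[v]:.12g}"
                if annotations and v in annotations:
                    s += f"[&{annotations[v]}]"
            return s

        return emit(self.root) + ";"

    def __repr__(self):
        return f"<Phylogeny {self.n_tips} tips, depth {self.depth:.4g}>"


def _quote_label(label: str) -> str:
    if re.search(r"[\s()\[\]:;,'\"]", label):
        return "'" + label.replace("'", "''") + "'"
    return label


@dataclass
class RegimePainting:
    """Per-branch regime history.

    ``segments[child_id]`` is the ordered list of ``(regime, duration)``
    pairs from the parent end to the child end of the branch leading to
    ``child_id``.  Durations are strictly positive and sum to the branch
    length.
    """

    segments: dict[int, list[tuple[str, float]]]
    alphabet: tuple[str, ...]
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def validate(self, tree: Phylogeny) -> None:
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            if v not in self.segments:
                raise PaintingError(f"branch to node {v} is not painted")
            segs = self.segments[v]
            bl = tree.branch_length[v]
            tot = sum(d for _, d in segs)
            if abs(tot - bl) > DURATION_RTOL * max(bl, 1.0):
                raise PaintingError(
                    f"branch to node {v}: painted duration {tot!r} != branch "
                    f"length {bl!r}"
                )
            # zero-length branches (resolved polytomies) carry a single
            # zero-duration segment recording their state
            zero_ok = bl == 0.0 and len(segs) == 1
            for s, d in segs:
                if s not in self.alphabet:
                    raise PaintingError(
                        f"branch to node {v}: regime {s!r} not in alphabet "
                        f"{self.alphabet}"
                    )
                if d < 0 or (d == 0 and not zero_ok):
                    raise PaintingError(f"branch to node {v}: non-positive duration")

    def child_state(self, node: int) -> str:
        return self.segments[node][-1][0]

    def parent_state(self, node: int) -> str:
        return self.segments[node][0][0]

    def dwell_times(self) -> dict[str, float]:
        out = {s: 0.0 for s in self.alphabet}
        for segs in self.segments.values():
            for s, d in segs:
                out[s] += d
        return out

    def transition_counts(self) -> pd.DataFrame:
        k = len(self.alphabet)
        idx = {s: i for i, s in enumerate(self.alphabet)}
        m = np.zeros((k, k))
        for segs in self.segments.values():
            for (s1, _), (s2, _) in zip(segs, segs[1:]):
                m[idx[s1], idx[s2]] += 1
        return pd.DataFrame(m, index=self.alphabet, columns=self.alphabet)

    def n_transitions(self) -> int:
        return int(self.transition_counts().to_numpy().sum())


def _merge_segments(segs: list[tuple[str, float]]) -> list[tuple[str, float]]:
    out: list[tuple[str, float]] = []
    for s, d in segs:
        if out and out[-1][0] == s:
            out[-1] = (s, out[-1][1] + d)
        else:
            out.append((s, d))
    return out


# ---------------------------------------------------------------------------
# Newick I/O (dendropy-backed)
# ---------------------------------------------------------------------------


def _from_dendropy(dtree: dendropy.Tree) -> tuple[Phylogeny, dict[int, object]]:
    """Convert, resolving polytomies into zero-length binary branches.

    Returns the tree plus a map node-id -> dendropy annotation dict (used by
    the painting reader).
    """
    dtree = dtree.clone(depth=1)
    _resolve_polytomies(dtree)

    tips: list[dendropy.Node] = []
    internals: list[dendropy.Node] = []
    for nd in dtree.preorder_node_iter():
        if nd.is_leaf():
            tips.append(nd)
        else:
            internals.append(nd)
    if not tips:
        raise NewickError("tree has no tips")
    for nd in tips:
        if nd.taxon is None or not nd.taxon.label:
            raise NewickError("unlabelled tip")
    ids: dict[dendropy.Node, int] = {}
    for i, nd in enumerate(tips):
        ids[nd] = i
    for j, nd in enumerate(internals):
        ids[nd] = len(tips) + j

    n = len(tips) + len(internals)
    parent = np.full(n, -1, dtype=np.int64)
    blen = np.zeros(n)
    children: list[list[int]] = [[] for _ in range(n)]
    meta: dict[int, object] = {}
    for nd in dtree.preorder_node_iter():
        i = ids[nd]
        children[i] = [ids[c] for c in nd.child_nodes()]
        if nd.parent_node is not None:
            parent[i] = ids[nd.parent_node]
            if nd.edge.length is None:
                who = nd.taxon.label if nd.taxon else f"internal node {i}"
                raise NewickError(f"missing branch length on edge to {who}")
            blen[i] = nd.edge.length
        meta[i] = dict(nd.annotations.values_as_dict())
    labels = [nd.taxon.label for nd in tips]
    return Phylogeny(parent, blen, labels, children=children), meta


def _resolve_polytomies(dtree: dendropy.Tree) -> None:
    """Deterministic binary resolution: children ordered by smallest
    descendant tip label, combined left-to-right with zero-length edges."""
    for nd in list(dtree.postorder_internal_node_iter()):
        kids = nd.child_nodes()
        if len(kids) <= 2:
            continue
        def key(c):
            if c.is_leaf():
                return c.taxon.label
            return min(l.taxon.label for l in c.leaf_iter())
        kids = sorted(kids, key=key)
        for c in kids:
            nd.remove_child(c)
        left = kids[0]
        for c in kids[1:-1]:
            joint = dendropy.Node(edge_length=0.0)
            joint.add_child(left)
            joint.add_child(c)
            left = joint
        nd.add_child(left)
        nd.add_child(kids[-1])


def _parse_dendropy(text: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            extract_comment_metadata=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise NewickError(f"Newick parse failure: {exc}") from exc


def read_newick(text: str) -> Phylogeny:
    """Parse a single Newick tree (branch lengths required on all edges)."""
    tree, _ = _from_dendropy(_parse_dendropy(text))
    return tree


def read_newick_list(text: str) -> list[Phylogeny]:
    """Parse a multi-tree file: one Newick string per non-empty line."""
    return [read_newick(line) for line in text.splitlines() if line.strip()]


def write_newick(tree: Phylogeny) -> str:
    return tree.newick()


def read_painting(text: str, alphabet) -> tuple[Phylogeny, RegimePainting]:
    """Parse painted Newick: each branch carries ``[&regimes=s1:d1|s2:d2]``."""
    alphabet = tuple(alphabet)
    tree, meta = _from_dendropy(_parse_dendropy(text))
    segments: dict[int, list[tuple[str, float]]] = {}
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        ann = meta.get(v, {})
        if "regimes" not in ann:
            who = tree.tip_labels[v] if tree.is_tip(v) else f"internal node {v}"
            raise PaintingError(f"branch to {who} lacks a [&regimes=...] annotation")
        raw = str(ann["regimes"])
        segs = []
        for tok in raw.split("|"):
            try:
                s, d = tok.rsplit(":", 1)
                segs.append((s, float(d)))
            except ValueError as exc:
                raise PaintingError(f"bad segment token {tok!r}") from exc
        segments[v] = _merge_segments(segs)
    painting = RegimePainting(segments=segments, alphabet=alphabet)
    painting.validate(tree)
    return tree, painting


def write_painting(tree: Phylogeny, painting: RegimePainting) -> str:
    painting.validate(tree)
    ann = {
        v: "regimes=" + "|".join(f"{s}:{d:.12g}" for s, d in segs)
        for v, segs in painting.segments.items()
    }
    return tree.newick(annotations=ann)


# ---------------------------------------------------------------------------
# Covariance machinery
# ---------------------------------------------------------------------------


def vcv(tree: Phylogeny) -> pd.DataFrame:
    """Brownian-motion covariance structure: C[i, j] = height of MRCA(i, j).

    Indexed by tip labels; the diagonal holds tip depths.
    """
    return pd.DataFrame(
        vcv_array(tree), index=tree.tip_labels, columns=tree.tip_labels
    )


def vcv_array(tree: Phylogeny) -> np.ndarray:
    """ndarray form of :func:`vcv`, memoized on the tree."""
    if "vcv" not in tree._cache:
        m = tree.mrca_heights()[: tree.n_tips, :]
        tree._cache["vcv"] = np.ascontiguousarray((m + m.T) / 2.0)
        # mrca_heights is symmetric over tips already; the averaging is a
        # cheap guard against asymmetric float accumulation.
    return tree._cache["vcv"]


def regime_vcv(tree: Phylogeny, painting: RegimePainting) -> dict[str, pd.DataFrame]:
    """Per-regime shared-time matrices.

    Entry (i, j) of matrix r is the time painted r on the shared root-to-MRCA
    path of tips i and j; the matrices sum elementwise to :func:`vcv`.
    """
    arrs = regime_vcv_arrays(tree, painting)
    return {
        r: pd.DataFrame(a, index=tree.tip_labels, columns=tree.tip_labels)
        for r, a in arrs.items()
    }


def regime_vcv_arrays(tree: Phylogeny, painting: RegimePainting) -> dict[str, np.ndarray]:
    key = ("regime_vcv", id(tree))
    if key not in painting._cache:
        painting.validate(tree)
        ntip = tree.n_tips
        k = len(painting.alphabet)
        idx = {s: i for i, s in enumerate(painting.alphabet)}
        # per-branch painted duration by regime
        dur = np.zeros((tree.n_nodes, k))
        for v, segs in painting.segments.items():
            for s, d in segs:
                dur[v, idx[s]] += d
        # tips below each node
        below = np.zeros((tree.n_nodes, ntip), dtype=bool)
        for v in tree.postorder():
            if tree.is_tip(v):
                below[v, v] = True
            else:
                for c in tree.children(v):
                    below[v] |= below[c]
        out = np.zeros((k, ntip, ntip))
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            mask = below[v]
            block = np.outer(mask, mask)
            for r in range(k):
                if dur[v, r]:
                    out[r][block] += dur[v, r]
        painting._cache[key] = {s: out[idx[s]] for s in painting.alphabet}
    return painting._cache[key]


def node_heights(tree: Phylogeny) -> dict[int, float]:
    """Time from the root to every node, keyed by node id."""
    h = tree.heights()
    return {v: float(h[v]) for v in range(tree.n_nodes)}


def is_ultrametric(tree: Phylogeny, rel_tol: float = 1e-6) -> bool:
    return tree.is_ultrametric(rel_tol)
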