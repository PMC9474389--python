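"""Forward-in-time simulation of species trees with general waiting times.

Each lineage independently carries a pending time to speciation and,
optionally, a pending time to extinction, drawn from a configurable waiting
time model (Coxian phase-type, exponential, or Weibull); whichever fires
first determines the lineage's fate.  This is a Bellman-Harris branching
process: with one-phase (exponential) waiting times it collapses to the
constant-rate birth-death process, and with pure birth to the Yule-Harding
model.

Two speciation modes are supported.  Under *symmetric* speciation both
daughters are new species of age 0 with fresh waiting-time draws.  Under
*asymmetric* (budding) speciation the parent persists: it keeps its pending
extinction time and only the single new daughter resets to age 0 (the parent
draws a fresh time to its next speciation, since the previous one just
fired).

A simulation ends once the number of simultaneously extant lineages first
reaches ``n_tips``: the present is placed at the instant before the next
event would have fired, and every extant lineage is truncated there.
Placing the present inside the final inter-event interval (rather than at
the ``n_tips``-th speciation itself) preserves the waiting-time law of the
last internode interval, which node-timing statistics such as gamma rely
on.  The *reconstructed* tree — what one infers from extant species — is
obtained by pruning extinct subtrees and suppressing the resulting unary
nodes.
"""

from __future__ import annotations

import heapq
import io
import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import dendropy
import numpy as np

from .phasetype import CoxianPH, build_coxian, ph_dec, ph_inc

__all__ = [
    "TreeNode",
    "SimTree",
    "WaitingTimeModel",
    "BranchData",
    "simulate_tree",
    "simulate_trees",
    "reconstruct",
    "classify_branches",
    "write_newick",
    "read_newick",
    "read_newick_file",
    "write_newick_file",
]

_ULTRAMETRIC_RTOL = 1e-9


@dataclass
class TreeNode:
    """Node of a rooted binary tree; ``length`` is the edge above the node."""

    length: float = 0.0
    name: str | None = None
    extinct: bool = False
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class SimTree:
    """Rooted, edge-weighted binary tree.

    ``root.length`` holds the root (origin) edge when one is present, else
    0.  ``provenance`` records how the tree was produced (model, mode, seed,
    restart count) for simulator output.
    """

    root: TreeNode
    provenance: dict = field(default_factory=dict)

    # -- traversal helpers -------------------------------------------------

    def preorder(self) -> Iterable[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def n_tips(self) -> int:
        return sum(1 for n in self.preorder() if n.is_leaf)

    @property
    def n_extant(self) -> int:
        return sum(1 for n in self.preorder() if n.is_leaf and not n.extinct)

    def depths(self) -> dict[int, float]:
        """Map ``id(node) -> distance from the top of the root edge``."""
        out = {}
        stack = [(self.root, self.root.length)]
        while stack:
            node, d = stack.pop()
            out[id(node)] = d
            for ch in node.children:
                stack.append((ch, d + ch.length))
        return out

    @property
    def age(self) -> float:
        """Tree age: maximum root-edge-to-tip depth."""
        depths = self.depths()
        return max(depths[id(n)] for n in self.leaves())

    def is_ultrametric(self, rtol: float = _ULTRAMETRIC_RTOL) -> bool:
        depths = self.depths()
        tip_d = [depths[id(n)] for n in self.leaves()]
        span = max(tip_d) - min(tip_d)
        return span <= rtol * max(max(tip_d), 1.0)

    def n_edges(self, include_root_edge: bool = False) -> int:
        total = sum(1 for n in self.preorder()) - 1  # every non-root node
        return total + (1 if include_root_edge and self.root.length > 0 else 0)

    def copy(self) -> "SimTree":
        def clone(node: TreeNode) -> TreeNode:
            return TreeNode(
                length=node.length,
                name=node.name,
                extinct=node.extinct,
                children=[clone(c) for c in node.children],
            )

        return SimTree(root=clone(self.root), provenance=dict(self.provenance))


# ---------------------------------------------------------------------------
# waiting-time models


@dataclass(frozen=True)
class WaitingTimeModel:
    """Waiting-time distributions for speciation and (optional) extinction.

    Each side is given as ``(family, params)`` where family is one of
    ``coxian`` (params: lambdas, ps), ``ph_dec`` / ``ph_inc`` (x, y, z),
    ``exponential`` (rate) or ``weibull`` (psi=shape, phi=scale).
    """

    speciation: tuple[str, dict]
    extinction: tuple[str, dict] | None = None

    def speciation_sampler(self) -> Callable[[np.random.Generator], float]:
        return _make_sampler(*self.speciation)

    def extinction_sampler(self) -> Callable[[np.random.Generator], float] | None:
        if self.extinction is None:
            return None
        return _make_sampler(*self.extinction)


def _make_sampler(family: str, params: dict) -> Callable[[np.random.Generator], float]:
    if family in ("coxian", "ph_dec", "ph_inc"):
        if family == "coxian":
            dist = build_coxian(params["lambdas"], params["ps"])
        elif family == "ph_dec":
            dist = ph_dec(params["x"], params["y"], params["z"])
        else:
            dist = ph_inc(params["x"], params["y"], params["z"])
        return lambda rng: float(dist.sample(rng, 1)[0])
    if family in ("exponential", "exp"):
        rate = float(params["rate"] if isinstance(params, dict) else params)
        if rate <= 0:
            raise ValueError("exponential rate must be > 0")
        return lambda rng: float(rng.exponential(1.0 / rate))
    if family == "weibull":
        psi, phi = float(params["psi"]), float(params["phi"])
        if psi <= 0 or phi <= 0:
            raise ValueError("weibull parameters must be > 0")
        return lambda rng: float(phi * rng.weibull(psi))
    raise ValueError(f"unknown waiting-time family: {family!r}")


# ---------------------------------------------------------------------------
# simulation


class _Lineage:
    __slots__ = ("node", "start", "spec_at", "ext_at")

    def __init__(self, node, start, spec_at, ext_at):
        self.node = node
        self.start = start
        self.spec_at = spec_at
        self.ext_at = ext_at


def simulate_tree(
    model: WaitingTimeModel,
    n_tips: int,
    rng: np.random.Generator,
    mode: str = "symmetric",
    max_retries: int = 1000,
    keep_root_edge: bool = False,
) -> SimTree:
    """Simulate one original (complete) tree with ``n_tips`` extant lineages.

    The process starts from a single lineage at time 0 (the origin / root
    edge) and runs until the extant count first reaches ``n_tips``.  If the
    whole tree dies first the simulation restarts with fresh randomness, up
    to ``max_retries`` times.

    Returns the *original* tree, extinct tips included.  By default the
    origin edge is dropped (``root.length = 0``); pass ``keep_root_edge`` to
    retain it.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if mode not in ("symmetric", "asymmetric"):
        raise ValueError(f"mode must be 'symmetric' or 'asymmetric', got {mode!r}")
    draw_spec = model.speciation_sampler()
    draw_ext = model.extinction_sampler()

    for attempt in range(max_retries + 1):
        tree = _simulate_once(draw_spec, draw_ext, n_tips, mode, rng)
        if tree is not None:
            if not keep_root_edge:
                tree.root.length = 0.0
            tree.provenance = {
                "model": {
                    "speciation": list(model.speciation),
                    "extinction": list(model.extinction) if model.extinction else None,
                },
                "mode": mode,
                "n_tips": n_tips,
                "restarts": attempt,
            }
            _name_tips(tree)
            return tree
    raise RuntimeError(
        f"tree went fully extinct in all {max_retries + 1} attempts"
    )


def _simulate_once(draw_spec, draw_ext, n_tips, mode, rng):
    counter = itertools.count()  # heap tie-break, keeps determinism
    root = TreeNode()

    def fresh(node, now):
        spec = now + draw_spec(rng)
        ext = now + draw_ext(rng) if draw_ext else math.inf
        return _Lineage(node, now, spec, ext)

    heap = []

    def push(lin):
        heapq.heappush(heap, (min(lin.spec_at, lin.ext_at), next(counter), lin))

    push(fresh(root, 0.0))
    n_alive = 1
    alive = {id(root)}  # nodes of currently extant lineages

    while heap:
        when, _, lin = heapq.heappop(heap)
        if id(lin.node) not in alive:
            continue
        alive.discard(id(lin.node))
        if lin.ext_at <= lin.spec_at:  # extinction fires
            lin.node.length = when - lin.start
            lin.node.extinct = True
            n_alive -= 1
            if n_alive == 0:
                return None
            continue
        # speciation
        lin.node.length = when - lin.start
        left, right = TreeNode(), TreeNode()
        lin.node.children = [left, right]
        if mode == "symmetric":
            l_lin, r_lin = fresh(left, when), fresh(right, when)
        else:
            # parent persists as `left`: keeps its pending extinction time,
            # redraws the next speciation wait; `right` is the new daughter
            l_lin = _Lineage(left, when, when + draw_spec(rng), lin.ext_at)
            r_lin = fresh(right, when)
        n_alive += 1
        for new_lin in (l_lin, r_lin):
            alive.add(id(new_lin.node))
            push(new_lin)
        if n_alive == n_tips:
            # the present is the instant before the next event would fire:
            # every open lineage is truncated there, so the final internode
            # interval keeps its full waiting-time distribution
            stop = min(
                min(lin.spec_at, lin.ext_at)
                for _, _, lin in heap
                if id(lin.node) in alive
            )
            for _, _, open_lin in heap:
                if id(open_lin.node) in alive:
                    open_lin.node.length = stop - open_lin.start
            return SimTree(root=root)
    raise AssertionError("event queue exhausted before termination")


def _name_tips(tree: SimTree) -> None:
    i = itertools.count(1)
    for node in tree.preorder():
        if node.is_leaf and node.name is None:
            node.name = f"t{next(i)}"


def simulate_trees(
    model: WaitingTimeModel,
    n_tips: int,
    n_trees: int,
    rng: np.random.Generator,
    mode: str = "symmetric",
    reconstructed: bool = True,
    keep_root_edge: bool = False,
) -> list[SimTree]:
    """Simulate ``n_trees`` independent trees; reconstructed view by default."""
    out = []
    for _ in range(n_trees):
        t = simulate_tree(model, n_tips, rng, mode=mode, keep_root_edge=keep_root_edge)
        out.append(reconstruct(t) if reconstructed else t)
    return out


# ---------------------------------------------------------------------------
# reconstruction and branch classification


def reconstruct(tree: SimTree) -> SimTree:
    """Prune extinct lineages and suppress unary nodes.

    Root-to-tip path lengths of surviving tips are preserved exactly; the
    result is the reconstructed tree an observer of extant species would
    infer.  Requires at least two extant tips.
    """
    if tree.n_extant < 2:
        raise ValueError("reconstruction needs at least 2 extant tips")

    def prune(node: TreeNode) -> TreeNode | None:
        if node.is_leaf:
            return None if node.extinct else TreeNode(
                length=node.length, name=node.name
            )
        kept = [c for c in (prune(ch) for ch in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:  # unary: splice child onto this edge
            kept[0].length += node.length
            return kept[0]
        return TreeNode(length=node.length, children=kept)

    new_root = prune(tree.root)
    assert new_root is not None
    # a chain of pruned-away splits above the first surviving one collapses
    # into a root (stem) edge; it is kept so root-to-tip depths are preserved,
    # and excluded from branch counts unless explicitly requested
    prov = dict(tree.provenance)
    prov["reconstructed"] = True
    return SimTree(root=new_root, provenance=prov)


@dataclass
class BranchData:
    """Branch lengths of a reconstructed tree, split by class.

    ``internal`` holds the ``k`` internal branch lengths ``b_i`` (the root
    edge counts as internal when present and requested, giving
    ``k = n_tips - 1``; otherwise ``k = n_tips - 2``); ``pendant`` holds the
    ``n_tips`` tip-adjacent lengths.  ``x`` records, per internal branch, the
    elapsed time from its lower end to the present, ``age`` the total tree
    age, and ``x2`` the elapsed time from the origin of the root's two
    daughter branches to the present (the quantity the survival-conditioned
    birth-death likelihood needs).
    """

    internal: np.ndarray
    pendant: np.ndarray
    x: np.ndarray
    age: float
    x2: float

    @property
    def k(self) -> int:
        return self.internal.size

    @property
    def n_tips(self) -> int:
        return self.pendant.size


def classify_branches(tree: SimTree, include_root_edge: bool = False) -> BranchData:
    """Split a reconstructed tree's edges into internal and pendant lengths."""
    for node in tree.preorder():
        if node.children and len(node.children) != 2:
            raise ValueError("classify_branches requires a binary tree")
    depths = tree.depths()
    age = tree.age
    internal, pendant, xs = [], [], []
    for node in tree.preorder():
        if node is tree.root:
            continue
        if node.is_leaf:
            pendant.append(node.length)
        else:
            internal.append(node.length)
            xs.append(age - depths[id(node)])
    if include_root_edge and tree.root.length > 0:
        internal.append(tree.root.length)
        xs.append(age - depths[id(tree.root)])
    x2 = age - depths[id(tree.root)]
    return BranchData(
        internal=np.asarray(internal, dtype=float),
        pendant=np.asarray(pendant, dtype=float),
        x=np.asarray(xs, dtype=float),
        age=age,
        x2=x2,
    )


# ---------------------------------------------------------------------------
# Newick input/output


def write_newick(tree: SimTree) -> str:
    """Serialize to a Newick string; the root edge appears as the root's
    length field when present."""

    def fmt(node: TreeNode) -> str:
        label = node.name or ""
        if node.children:
            inner = ",".join(fmt(c) for c in node.children)
            label = f"({inner}){label}"
        return f"{label}:{node.length:.12g}"

    body = fmt(tree.root)
    if tree.root.length == 0.0:
        # drop the redundant ":0" on the root for conventional output
        body = body.rsplit(":", 1)[0]
    return body + ";"


def read_newick(newick: str) -> SimTree:
    """Parse a Newick string into a :class:`SimTree`.

    Branch lengths are required on all non-root edges; a length on the root
    is kept as the root (origin) edge.
    """
    try:
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> TreeNode:
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        name = dnode.taxon.label if dnode.taxon is not None else None
        return TreeNode(
            length=float(length),
            name=name,
            children=[convert(c) for c in dnode.child_nodes()],
        )

    return SimTree(root=convert(dtree.seed_node))


def write_newick_file(trees: Sequence[SimTree], path) -> None:
    """One Newick string per line."""
    with open(path, "w") as fh:
        for t in trees:
            fh.write(write_newick(t) + "\n")


def read_newick_file(path) -> list[SimTree]:
    with open(path) as fh:
        return [read_newick(line) for line in fh if line.strip()]
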