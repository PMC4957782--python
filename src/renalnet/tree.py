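"""Generation of asymmetric bifurcating renal arterial trees.

Two variants are built from the same morphometric laws:

* ABT -- a recursively bifurcating tree in which afferent arterioles occur
  only where bifurcation daughters fall below the stop diameter, i.e. at the
  terminals of the tree.
* KSABT -- the kidney-specific variant: before a vessel bifurcates it is
  segmented, with afferent arterioles branching off its side at
  exponentially distributed spacings; each side branch reduces the
  continuing diameter by Murray's law, and the vessel finally bifurcates
  from the reduced diameter.

Murray's law (parent cube = sum of daughter cubes) holds exactly at every
branching and segmentation event, which makes it a checkable invariant of
every generated or loaded tree.

Trees are topological: vessels carry diameter, length and connectivity, but
no 3D embedding.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .morphometry import (
    MorphometricDistributions,
    sample_aa_diameter,
    sample_aa_spacing,
    sample_daughter_diameter,
    sample_vessel_length,
)

__all__ = [
    "Vessel",
    "VascularTree",
    "TreeError",
    "murray_second_daughter",
    "build_abt",
    "build_ksabt",
    "segment_vessel",
    "strahler_orders",
    "tree_summary",
    "save_tree",
    "load_tree",
]

MURRAY_RTOL = 1e-9
#: shortest segment materialized during segmentation; spacing draws of
#: (near-)zero produce a positive-length stub so the strict length>0
#: invariant holds while the geometry is unchanged to numerical precision
MIN_SEGMENT_LENGTH = 1e-6

ROOT = "root"
ARTERY = "artery"
AFFERENT = "afferent_arteriole"


class TreeError(ValueError):
    """Invalid tree construction input or a violated tree invariant."""


@dataclass
class Vessel:
    id: int
    parent_node: int
    child_node: int
    diameter: float        # um
    length: float          # um
    kind: str              # "root" | "artery" | "afferent_arteriole"
    origin_offset: float = 0.0  # um along the pre-segmentation vessel; >0
                                # only for side-branching arterioles
    branch_index: int = 0  # 0 = first daughter / continuing segment, 1 = second

    @property
    def is_arteriole(self) -> bool:
        return self.kind == AFFERENT


@dataclass
class VascularTree:
    """Connectivity structure of vessel segments and afferent arterioles."""

    vessels: list = field(default_factory=list)
    n_nodes: int = 1
    meta: dict = field(default_factory=dict)

    # -- construction helpers ---------------------------------------------

    def _new_node(self) -> int:
        self.n_nodes += 1
        return self.n_nodes - 1

    def _add_vessel(self, parent_node, diameter, length, kind,
                    branch_index=0, origin_offset=0.0) -> "Vessel":
        v = Vessel(id=len(self.vessels), parent_node=parent_node,
                   child_node=self._new_node(), diameter=float(diameter),
                   length=float(length), kind=kind,
                   origin_offset=float(origin_offset),
                   branch_index=int(branch_index))
        self.vessels.append(v)
        return v

    # -- topology ----------------------------------------------------------

    def children_map(self):
        """node id -> list of outgoing vessels, in creation order."""
        out = {}
        for v in self.vessels:
            out.setdefault(v.parent_node, []).append(v)
        return out

    def inbound_map(self):
        """node id -> the vessel ending at that node."""
        return {v.child_node: v for v in self.vessels}

    @property
    def root_vessel(self) -> "Vessel":
        roots = [v for v in self.vessels if v.kind == ROOT]
        if len(roots) != 1:
            raise TreeError(f"tree must have exactly one root vessel, found {len(roots)}")
        return roots[0]

    def arterioles(self):
        return [v for v in self.vessels if v.is_arteriole]

    def arteries(self):
        return [v for v in self.vessels if not v.is_arteriole]

    # -- invariants ---------------------------------------------------------

    def validate(self):
        """Check all structural invariants; raise ``TreeError`` on violation."""
        if not self.vessels:
            raise TreeError("empty tree")
        self.root_vessel  # uniqueness
        children = self.children_map()
        inbound = self.inbound_map()
        for v in self.vessels:
            if v.diameter <= 0 or v.length <= 0:
                raise TreeError(f"vessel {v.id}: non-positive geometry")
            if v.is_arteriole and children.get(v.child_node):
                raise TreeError(f"arteriole {v.id} has children")
            if v.kind != ROOT and v.child_node in inbound and \
                    inbound[v.child_node] is not v:
                raise TreeError(f"node {v.child_node} has two inbound vessels")
        # connectivity / acyclicity: every vessel reachable from the root node
        seen = set()
        stack = [self.root_vessel.parent_node]
        visited_nodes = set()
        while stack:
            n = stack.pop()
            if n in visited_nodes:
                raise TreeError("cycle detected")
            visited_nodes.add(n)
            for v in children.get(n, []):
                seen.add(v.id)
                stack.append(v.child_node)
        if len(seen) != len(self.vessels):
            raise TreeError("tree is not connected")
        # Murray conservation at every internal node
        for v in self.vessels:
            kids = children.get(v.child_node, [])
            if not kids:
                continue
            cube_in = v.diameter ** 3
            cube_out = sum(k.diameter ** 3 for k in kids)
            if abs(cube_in - cube_out) > MURRAY_RTOL * cube_in:
                raise TreeError(
                    f"Murray's law violated at node {v.child_node}: "
                    f"{cube_in:.6g} != {cube_out:.6g}")
        return self


# ---------------------------------------------------------------------------
# Murray's law

def murray_second_daughter(parent_diam: float, first_daughter_diam: float) -> float:
    """Second daughter diameter from Murray's law: (Dp^3 - Dd1^3)^(1/3)."""
    if first_daughter_diam <= 0 or parent_diam <= 0:
        raise TreeError("diameters must be > 0")
    if first_daughter_diam >= parent_diam:
        raise TreeError(
            f"first daughter ({first_daughter_diam:g} um) must be smaller "
            f"than parent ({parent_diam:g} um)")
    return float(np.cbrt(parent_diam ** 3 - first_daughter_diam ** 3))


def _murray_reduce(diam: float, branch_diam: float) -> float:
    """Continuing diameter after a side branch leaves the main vessel."""
    return float(np.cbrt(diam ** 3 - branch_diam ** 3))


# ---------------------------------------------------------------------------
# segmentation walk (KSABT)

def segment_vessel(diameter, length, incoming_shift, dists, rng, d_stop):
    """Walk arteriole attachment sites along one vessel.

    ``incoming_shift`` is the remaining distance to the next arteriole site,
    carried over from the upstream walk (the exponential spacing process is
    memoryless, so a fresh draw is an equivalent restart).

    Returns ``(events, outgoing_shift, final_diameter)`` where ``events`` is
    a list of ``(position_um, aa_diameter, aa_length, diameter_after)``.
    Each attachment reduces the continuing diameter by Murray's law; the
    walk stops early, without attaching, if an attachment would push the
    continuing diameter to or below ``d_stop``.
    """
    events = []
    d = float(diameter)
    pos = 0.0
    s = float(incoming_shift)
    while True:
        x = pos + s
        if x > length:
            return events, x - length, d
        d_aff = sample_aa_diameter(dists, rng, feeding_diam=d)
        d_next = _murray_reduce(d, d_aff)
        if d_next <= d_stop:
            # attaching would exhaust the vessel: stop branching of this
            # vessel, leave the remainder unsegmented
            return events, max(length - x, 0.0) + sample_aa_spacing(dists, rng), d
        aa_len = sample_vessel_length(d_aff, dists, rng)
        events.append((x, d_aff, aa_len, d_next))
        d = d_next
        pos = x
        s = sample_aa_spacing(dists, rng)


# ---------------------------------------------------------------------------
# builders

def _build(variant, d_initial, d_stop, dists, rng, max_depth, seed=None):
    if d_initial <= d_stop:
        raise TreeError("D_initial must exceed D_stop")
    if d_stop <= 0:
        raise TreeError("D_stop must be > 0")
    tree = VascularTree(meta={
        "variant": variant, "d_initial": float(d_initial),
        "d_stop": float(d_stop), "seed": seed, "profile": dists.name,
        "max_depth": int(max_depth),
    })
    root = tree._add_vessel(0, d_initial, sample_vessel_length(d_initial, dists, rng),
                            ROOT)
    segment = variant == "ksabt"
    clamped = 0
    # LIFO stack of vessels to realize: (start node, diameter, branch index,
    # incoming shift or None, depth). Second daughter pushed first so the
    # first daughter's subtree is processed first (depth-first).
    stack = []

    def bifurcate(node, diam, depth, carry_shift):
        d1 = sample_daughter_diameter(diam, dists, rng)
        if d1 > 0.99 * diam:
            nonlocal clamped
            clamped += 1
            d1 = 0.99 * diam
        d2 = murray_second_daughter(diam, d1)
        stack.append((node, d2, 1, None, depth + 1))
        stack.append((node, d1, 0, carry_shift, depth + 1))

    bifurcate(root.child_node, d_initial, 0, None)
    while stack:
        node, diam, branch, s_in, depth = stack.pop()
        if diam <= d_stop:
            tree._add_vessel(node, diam, sample_vessel_length(diam, dists, rng),
                             AFFERENT, branch_index=branch)
            continue
        length = sample_vessel_length(diam, dists, rng)
        carry = None
        if segment:
            if s_in is None:
                s_in = sample_aa_spacing(dists, rng)
            events, carry, d_end = segment_vessel(diam, length, s_in, dists,
                                                  rng, d_stop)
            pos = 0.0
            cur_d = diam
            cur_branch = branch
            for (x, d_aff, aa_len, d_after) in events:
                seg_len = max(x - pos, MIN_SEGMENT_LENGTH)
                seg = tree._add_vessel(node, cur_d, seg_len, ARTERY,
                                       branch_index=cur_branch)
                node = seg.child_node
                tree._add_vessel(node, d_aff, aa_len, AFFERENT,
                                 origin_offset=x)
                cur_d = d_after
                pos = x
                cur_branch = 0
            tail = tree._add_vessel(node, cur_d,
                                    max(length - pos, MIN_SEGMENT_LENGTH),
                                    ARTERY, branch_index=cur_branch)
            node, diam = tail.child_node, cur_d
        else:
            v = tree._add_vessel(node, diam, length, ARTERY, branch_index=branch)
            node = v.child_node
        if depth >= max_depth:
            warnings.warn(f"recursion depth cap {max_depth} reached; vessel "
                          "left terminal", stacklevel=2)
            continue
        bifurcate(node, diam, depth, carry)
    if clamped:
        warnings.warn(f"{clamped} daughter draws clamped to 0.99*parent "
                      "diameter", stacklevel=2)
    return tree


def build_abt(d_initial, d_stop, dists, rng, max_depth=60, seed=None):
    """Build an asymmetric bifurcating tree with terminal arterioles only."""
    return _build("abt", d_initial, d_stop, dists, rng, max_depth, seed)


def build_ksabt(d_initial, d_stop, dists, rng, max_depth=60, seed=None):
    """Build the kidney-specific tree with side-branching arterioles.

    The root vessel (renal artery) is never segmented; every other artery is
    segmented before it bifurcates, and bifurcates from its Murray-reduced
    diameter. The spacing walk's carry-over shift propagates from a vessel
    to its first processed daughter; second daughters restart the walk.
    """
    return _build("ksabt", d_initial, d_stop, dists, rng, max_depth, seed)


# ---------------------------------------------------------------------------
# analysis

def strahler_orders(tree: VascularTree) -> dict:
    """Bottom-up stream ordering: leaves are 1; a parent joining children
    whose maximal order is attained at least twice increments it."""
    children = tree.children_map()
    order = {}
    # iterative postorder over vessels
    stack = [(v, False) for v in reversed(children.get(tree.root_vessel.parent_node, []))]
    while stack:
        v, expanded = stack.pop()
        kids = children.get(v.child_node, [])
        if not kids:
            order[v.id] = 1
            continue
        if not expanded:
            stack.append((v, True))
            stack.extend((k, False) for k in kids)
            continue
        kid_orders = [order[k.id] for k in kids]
        top = max(kid_orders)
        order[v.id] = top + 1 if kid_orders.count(top) >= 2 else top
    return order


def _walk_chain_distances(tree: VascularTree):
    """Along-vessel distances between consecutive side-branch arterioles in
    segmentation walk order.

    Chains follow the shift carry-over: they run through first daughters and
    restart at second daughters and at the daughters of the root vessel.
    """
    children = tree.children_map()
    root = tree.root_vessel
    starts = []
    root_kids = {v.id for v in children.get(root.child_node, [])}
    for v in tree.vessels:
        if v.is_arteriole or v.kind == ROOT:
            continue
        if v.branch_index == 1 or v.id in root_kids:
            starts.append(v)
    distances = []
    for start in starts:
        v = start
        dist = 0.0
        last = None
        while v is not None:
            dist += v.length
            nxt = None
            for k in children.get(v.child_node, []):
                if k.is_arteriole:
                    if k.origin_offset > 0:  # side branch
                        if last is not None:
                            distances.append(dist - last)
                        last = dist
                elif k.branch_index == 0:
                    nxt = k
            v = nxt
    return np.asarray(distances)


def tree_summary(tree: VascularTree) -> dict:
    """Aggregate morphometric statistics of a generated tree."""
    aas = tree.arterioles()
    arteries = tree.arteries()
    aa_d = np.array([v.diameter for v in aas])
    inbound = tree.inbound_map()
    children = tree.children_map()
    feed = np.array([inbound[v.parent_node].diameter for v in aas
                     if v.parent_node in inbound])
    # daughter-vs-parent diameter pairs at bifurcation nodes (two outgoing
    # arteries); arteriole daughters included for the ABT, where terminal
    # arterioles are the bifurcation daughters, excluded for the KSABT
    include_aa = tree.meta.get("variant") != "ksabt"
    pairs = []
    for v in tree.vessels:
        kids = children.get(v.child_node, [])
        art_kids = [k for k in kids if not k.is_arteriole]
        if len(art_kids) + sum(k.is_arteriole and k.origin_offset == 0 for k in kids) < 2:
            continue  # segmentation or terminal-chain node, not a bifurcation
        for k in kids:
            if k.is_arteriole and (k.origin_offset > 0 or not include_aa):
                continue
            pairs.append((v.diameter, k.diameter))
    art_d = np.array([v.diameter for v in arteries])
    art_l = np.array([v.length for v in arteries])
    return {
        "variant": tree.meta.get("variant"),
        "n_vessels": len(tree.vessels),
        "n_nodes": tree.n_nodes,
        "n_arterioles": len(aas),
        "aa_diam_mean": float(aa_d.mean()) if len(aas) else float("nan"),
        "aa_diam_sd": float(aa_d.std(ddof=1)) if len(aas) > 1 else float("nan"),
        "aa_feed_diam_mean": float(feed.mean()) if feed.size else float("nan"),
        "artery_diameters": art_d,
        "artery_lengths": art_l,
        "daughter_parent_pairs": np.asarray(pairs),
        "inter_aa_distances": _walk_chain_distances(tree),
    }


# ---------------------------------------------------------------------------
# serialization

def save_tree(tree: VascularTree, path):
    """Write a tree to JSON (lossless, including generation metadata)."""
    payload = {
        "meta": tree.meta,
        "n_nodes": tree.n_nodes,
        "vessels": [
            {"id": v.id, "parent_node": v.parent_node, "child_node": v.child_node,
             "diameter_um": v.diameter, "length_um": v.length, "kind": v.kind,
             "origin_offset_um": v.origin_offset, "branch_index": v.branch_index}
            for v in tree.vessels
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_tree(path) -> VascularTree:
    """Read a tree from JSON and validate all structural invariants."""
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as e:
            raise TreeError(f"malformed tree file {path}: {e}") from e
    try:
        vessels = [
            Vessel(id=d["id"], parent_node=d["parent_node"],
                   child_node=d["child_node"], diameter=d["diameter_um"],
                   length=d["length_um"], kind=d["kind"],
                   origin_offset=d.get("origin_offset_um", 0.0),
                   branch_index=d.get("branch_index", 0))
            for d in payload["vessels"]
        ]
        tree = VascularTree(vessels=vessels, n_nodes=payload["n_nodes"],
                            meta=payload.get("meta", {}))
    except (KeyError, TypeError) as e:
        raise TreeError(f"malformed tree file {path}: missing field {e}") from e
    return tree.validate()
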