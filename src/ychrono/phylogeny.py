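"""Allele polarization, SNP-tree construction and parsimony branch mapping.

The non-recombining Y is transmitted as a single linked block, so under the
infinite-sites assumption every variable site is compatible with one rooted
tree whose clades are exactly the distinct derived-allele carrier sets.
This module

* orients REF/ALT calls into ancestral/derived states against an outgroup
  (:func:`polarize`),
* tests sites for pairwise compatibility with the rooted three-gamete test
  (:func:`check_pairwise_compatibility`),
* builds the perfect phylogeny of the mutually compatible sites
  (:func:`build_tree`), collapsing identical samples onto common nodes and
  leaving unresolved orders as polytomies, and
* maps every site onto the branches of a (built or externally supplied)
  rooted tree by minimum-mutation Fitch parsimony with the root state fixed
  to ancestral (:func:`assign_snps_to_branches`), flagging sites that need
  two or more changes as recurrent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .model import CALL_MISSING, GenotypeMatrix
from .tree import Node, PhyloTree

# polarized state codes (int8)
ANCESTRAL: int = 0
DERIVED: int = 1
STATE_MISSING: int = -1

_BIG = 1.0e9  # effectively-infinite change cost for a disallowed tip state


@dataclass
class PolarizeReport:
    sites_in: int = 0
    dropped_outgroup_missing: int = 0
    dropped_no_derived: int = 0
    flipped_polarity: int = 0


@dataclass
class BinaryMatrix:
    """Polarized ingroup states: 0 ancestral, 1 derived, -1 missing."""

    sample_ids: list[str]
    positions: np.ndarray
    states: np.ndarray
    outgroup_id: str
    report: PolarizeReport = field(default_factory=PolarizeReport)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def derived_set(self, site_index: int) -> frozenset[str]:
        """Sample ids with a derived call at one site (missing excluded)."""
        col = self.states[:, site_index]
        return frozenset(s for s, v in zip(self.sample_ids, col)
                         if v == DERIVED)


def polarize(matrix: GenotypeMatrix, outgroup_id: str) -> BinaryMatrix:
    """Orient calls using the outgroup allele as ancestral.

    Sites where the outgroup is missing are dropped (counted); sites where
    the outgroup carries ALT have their polarity flipped. Sites left with
    no derived ingroup call are dropped as uninformative.
    """
    og = matrix.sample_index(outgroup_id)
    ingroup = [i for i in range(matrix.n_samples) if i != og]
    rep = PolarizeReport(sites_in=matrix.n_sites)

    og_calls = matrix.calls[og, :]
    keep = og_calls != CALL_MISSING
    rep.dropped_outgroup_missing = int(np.sum(~keep))

    calls = matrix.calls[ingroup, :][:, keep]
    flip = og_calls[keep] == 1  # outgroup carries ALT: ALT is ancestral
    rep.flipped_polarity = int(np.sum(flip))
    states = calls.copy()
    obs = states != CALL_MISSING
    states[:, flip] = np.where(obs[:, flip], 1 - states[:, flip],
                               STATE_MISSING)

    informative = np.any(states == DERIVED, axis=0)
    rep.dropped_no_derived = int(np.sum(~informative))
    return BinaryMatrix(
        sample_ids=[matrix.sample_ids[i] for i in ingroup],
        positions=matrix.positions[keep][informative],
        states=states[:, informative],
        outgroup_id=outgroup_id,
        report=rep,
    )


def check_pairwise_compatibility(bmatrix: BinaryMatrix
                                 ) -> list[tuple[int, int]]:
    """Rooted three-gamete test over all site pairs.

    Two sites are incompatible iff, among samples non-missing at both,
    the gametes (1,1), (1,0) and (0,1) all occur — i.e. their derived sets
    overlap without one containing the other. Returns (position, position)
    pairs.
    """
    S = bmatrix.n_sites
    st = bmatrix.states
    der = st == DERIVED
    anc = st == ANCESTRAL
    bad: list[tuple[int, int]] = []
    for i in range(S):
        for j in range(i + 1, S):
            both = np.any(der[:, i] & der[:, j])
            only_i = np.any(der[:, i] & anc[:, j])
            only_j = np.any(anc[:, i] & der[:, j])
            if both and only_i and only_j:
                bad.append((int(bmatrix.positions[i]),
                            int(bmatrix.positions[j])))
    return bad


def build_tree(bmatrix: BinaryMatrix) -> PhyloTree:
    """Perfect phylogeny of the mutually compatible sites.

    Distinct derived sets (missing calls treated as ancestral for the set
    definition) are kept while they form a laminar family — processed
    largest-first, a set conflicting with an already accepted one is set
    aside for later Fitch placement. Each accepted set becomes an internal
    node nested by containment; samples attach to the smallest accepted set
    containing them, so identical samples share a node and unresolved
    orders appear as polytomies.
    """
    if bmatrix.n_sites == 0 or bmatrix.n_samples == 0:
        raise InputError("cannot build a tree from an empty matrix")

    sets: dict[frozenset[str], int] = {}
    for j in range(bmatrix.n_sites):
        d = bmatrix.derived_set(j)
        if d:
            sets.setdefault(d, 0)
            sets[d] += 1

    all_samples = frozenset(bmatrix.sample_ids)
    ordered = sorted(sets, key=lambda s: (-len(s), sorted(s)))
    accepted: list[frozenset[str]] = []
    for cand in ordered:
        if cand == all_samples:
            accepted.append(cand)  # stem of the whole ingroup
            continue
        ok = all(cand <= a or a <= cand or not (cand & a) for a in accepted)
        if ok:
            accepted.append(cand)

    root = Node("root")
    node_of: dict[frozenset[str], Node] = {}
    for s in accepted:  # already sorted largest-first
        parent = root
        best: frozenset[str] | None = None
        for a in accepted:
            if s < a and (best is None or len(a) < len(best)):
                best = a
        if best is not None:
            parent = node_of[best]
        node_of[s] = parent.add_child(Node())

    for sample in bmatrix.sample_ids:
        best = None
        for a in accepted:
            if sample in a and (best is None or len(a) < len(best)):
                best = a
        parent = node_of[best] if best is not None else root
        parent.add_child(Node(sample))

    # an internal node with a single child and no tip attached is redundant
    tree = PhyloTree(root)
    _suppress_unifurcations(tree)
    tree.name_internal()
    return tree


def _suppress_unifurcations(tree: PhyloTree) -> None:
    changed = True
    while changed:
        changed = False
        for node in list(tree.preorder()):
            if node.parent is not None and len(node.children) == 1:
                child = node.children[0]
                parent = node.parent
                idx = parent.children.index(node)
                child.parent = parent
                parent.children[idx] = child
                changed = True


def assign_snps_to_branches(tree: PhyloTree,
                            bmatrix: BinaryMatrix) -> PhyloTree:
    """Minimum-mutation assignment of every site to tree branches.

    Dynamic program over states {ancestral, derived} with unit change cost,
    root fixed to ancestral and missing tips unconstrained; vectorized
    across sites. Ties in the traceback prefer the derived state, which
    pushes gains toward the root (the earliest branch consistent with the
    minimum). Sites needing >= 2 changes are recorded in
    ``tree.recurrent``. The input tree is annotated in place and returned.
    """
    tip_names = tree.tip_names
    sample_index = {s: i for i, s in enumerate(bmatrix.sample_ids)}
    missing_tips = [t for t in tip_names if t not in sample_index]
    if missing_tips:
        raise InputError(f"tree tips without matrix data: {missing_tips}")

    S = bmatrix.n_sites
    tree.clear_events()
    if S == 0:
        return tree

    cost: dict[int, np.ndarray] = {}  # id(node) -> (2, S) cost array
    for node in tree.postorder():
        if node.is_tip:
            st = bmatrix.states[sample_index[node.name], :]
            c = np.zeros((2, S))
            c[0, st == DERIVED] = _BIG
            c[1, st == ANCESTRAL] = _BIG
        else:
            c = np.zeros((2, S))
            for child in node.children:
                cc = cost[id(child)]
                c[0] += np.minimum(cc[0], cc[1] + 1.0)
                c[1] += np.minimum(cc[0] + 1.0, cc[1])
        cost[id(node)] = c

    scores = cost[id(tree.root)][0]

    state: dict[int, np.ndarray] = {id(tree.root): np.zeros(S, dtype=np.int8)}
    for node in tree.preorder():
        ps = state[id(node)]
        for child in node.children:
            cc = cost[id(child)]
            with_anc = cc[0] + (ps != ANCESTRAL)
            with_der = cc[1] + (ps != DERIVED)
            cs = np.where(with_der <= with_anc, DERIVED, ANCESTRAL
                          ).astype(np.int8)
            state[id(child)] = cs
            gained = (ps == ANCESTRAL) & (cs == DERIVED)
            lost = (ps == DERIVED) & (cs == ANCESTRAL)
            for j in np.nonzero(gained)[0]:
                child.events.append((int(bmatrix.positions[j]), "gain"))
            for j in np.nonzero(lost)[0]:
                child.events.append((int(bmatrix.positions[j]), "loss"))

    tree.recurrent = {int(bmatrix.positions[j]): int(round(scores[j]))
                      for j in np.nonzero(scores >= 2)[0]}
    return tree


def fitch_score(tree: PhyloTree, site_states: dict[str, int]) -> int:
    """Minimum number of changes for one site on the rooted tree, root
    fixed to the ancestral state; tips absent from ``site_states`` or
    mapped to ``STATE_MISSING`` are unconstrained."""
    cost: dict[int, tuple[float, float]] = {}
    for node in tree.postorder():
        if node.is_tip:
            st = site_states.get(node.name, STATE_MISSING)
            if st == ANCESTRAL:
                c = (0.0, _BIG)
            elif st == DERIVED:
                c = (_BIG, 0.0)
            else:
                c = (0.0, 0.0)
        else:
            c0 = c1 = 0.0
            for child in node.children:
                k0, k1 = cost[id(child)]
                c0 += min(k0, k1 + 1.0)
                c1 += min(k0 + 1.0, k1)
            c = (c0, c1)
        cost[id(node)] = c
    return int(round(cost[id(tree.root)][0]))


def branch_snp_table(tree: PhyloTree):
    """Per-branch summary rows: branch_id, parent, n_snps, positions,
    recurrent flag (any event at a recurrent position)."""
    rows = []
    for node in tree.preorder():
        if node.parent is None:
            continue
        positions = sorted(p for p, _ in node.events)
        rows.append({
            "branch_id": node.name,
            "parent": node.parent.name,
            "n_snps": len(positions),
            "positions": ",".join(str(p) for p in positions),
            "recurrent": any(p in tree.recurrent for p in positions),
        })
    return rows
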