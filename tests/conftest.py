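"""Shared fixtures: tiny hand-enumerable matrices and tree builders."""

from __future__ import annotations

import numpy as np
import pytest

from ychrono.model import (CALL_ALT, CALL_MISSING, CALL_REF, GenotypeMatrix,
                           RegionMask)
from ychrono.tree import Node, PhyloTree

R, A, M = CALL_REF, CALL_ALT, CALL_MISSING


def mk_matrix(sample_ids, positions, calls, depths=None, ref=None, alt=None,
              indel=None) -> GenotypeMatrix:
    """Compact GenotypeMatrix builder for fixtures (rows = samples)."""
    s = len(positions)
    return GenotypeMatrix(
        sample_ids=list(sample_ids),
        positions=np.asarray(positions, dtype=np.int64),
        ref_allele=np.asarray(ref if ref is not None else ["A"] * s,
                              dtype=object),
        alt_allele=np.asarray(alt if alt is not None else ["G"] * s,
                              dtype=object),
        calls=np.asarray(calls, dtype=np.int8),
        depths=None if depths is None else np.asarray(depths,
                                                      dtype=np.int32),
        site_is_indel=None if indel is None else np.asarray(indel,
                                                            dtype=bool),
    )


def tree_from_spec(spec) -> PhyloTree:
    """Build a tree from a nested tuple/str spec, e.g. (("a","b"),"c")."""
    def build(s) -> Node:
        if isinstance(s, str):
            return Node(s)
        node = Node()
        for child in s:
            node.add_child(build(child))
        return node

    t = PhyloTree(build(spec))
    t.root.name = "root"
    t.name_internal()
    return t


@pytest.fixture
def six_site_matrix() -> GenotypeMatrix:
    """The documented toy cascade fixture: 6 sites, one defect each for the
    indel, depth->missingness, and monomorphic stages; 3 clean sites.

    Hand enumeration (4 samples, mask [0, 1000), min_depth 2,
    max_missingness 0.1):
      pos 100  clean, variable                     -> survives
      pos 200  indel                               -> removed (mask/indel)
      pos 300  one depth-1 call -> 1/4 missing     -> removed (missingness)
      pos 400  monomorphic (all ALT)               -> removed (monomorphic)
      pos 500  clean, variable                     -> survives
      pos 600  clean, variable                     -> survives
    """
    calls = [
        # 100 200 300 400 500 600
        [R,   R,  R,  A,  R,  A],
        [A,   A,  R,  A,  R,  R],
        [R,   R,  A,  A,  A,  R],
        [A,   R,  A,  A,  R,  R],
    ]
    depths = [
        [30, 30, 30, 30, 30, 30],
        [30, 30,  1, 30, 30, 30],
        [30, 30, 30, 30, 30, 30],
        [30, 30, 30, 30, 30, 30],
    ]
    return mk_matrix(["s1", "s2", "s3", "s4"],
                     [100, 200, 300, 400, 500, 600], calls, depths=depths,
                     indel=[False, True, False, False, False, False])


@pytest.fixture
def toy_mask() -> RegionMask:
    return RegionMask.from_intervals([(0, 1000)])


@pytest.fixture
def clade_fixture() -> GenotypeMatrix:
    """Four ingroup samples plus outgroup; sites cover every nonempty
    carrier subset of {a, b, c, d} (positions 1..15, subset = bits)."""
    samples = ["a", "b", "c", "d", "OUT"]
    positions = list(range(1, 16))
    calls = []
    for i, _ in enumerate(samples):
        row = []
        for subset in range(1, 16):
            if i < 4:
                row.append(A if subset >> i & 1 else R)
            else:
                row.append(R)  # outgroup all ancestral
        calls.append(row)
    return mk_matrix(samples, positions, calls)
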