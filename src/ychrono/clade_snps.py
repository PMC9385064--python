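"""Clade-relative variant partitioning and novel-SNP discovery.

Given the polarized matrix and a clade (a set of sample ids), every site
with a derived carrier inside the clade falls into exactly one class:

* **defining** — every non-missing clade member derived, every non-missing
  outsider ancestral (the clade's equivalent-SNP class);
* **internal** — derived in a proper, non-empty subset of the clade and in
  no outsider (sub-lineage structure); **private** is the subset of
  internal with exactly one carrier;
* **excluded** — at least one derived carrier outside the clade;
* **unresolved** — no non-missing call on one side of the clade boundary,
  so the defining/internal/excluded distinction cannot be established.

Novelty is assessed against a catalog of known SNPs keyed by position;
novel SNPs receive sequential names in genomic-position order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .model import SnpCatalog
from .phylogeny import ANCESTRAL, DERIVED, BinaryMatrix
from .tree import PhyloTree


@dataclass
class CladePartition:
    clade_samples: frozenset[str]
    defining: set[int] = field(default_factory=set)
    internal: set[int] = field(default_factory=set)
    private: set[int] = field(default_factory=set)
    excluded: set[int] = field(default_factory=set)
    unresolved: set[int] = field(default_factory=set)

    def all_clade_positions(self) -> set[int]:
        """Sites with at least one derived carrier in the clade
        (excluded sites excepted)."""
        return self.defining | self.internal | self.unresolved


@dataclass
class NovelSnpSet:
    positions: list[int]
    names: dict[int, str] = field(default_factory=dict)
    known: dict[int, str] = field(default_factory=dict)
    validation_status: dict[int, str] = field(default_factory=dict)


def clade_variant_partition(bmatrix: BinaryMatrix,
                            clade_samples) -> CladePartition:
    """Classify every site relative to a clade (order-independent).

    Missing calls neither confirm nor deny carrier status: "defining"
    requires all *non-missing* clade members derived and all non-missing
    outsiders ancestral, with at least one non-missing call on each side;
    sites failing that quorum are reported unresolved.
    """
    clade = frozenset(clade_samples)
    if not clade:
        raise InputError("empty clade")
    unknown = clade - set(bmatrix.sample_ids)
    if unknown:
        raise InputError(f"clade samples not in matrix: {sorted(unknown)}")

    in_rows = np.array([s in clade for s in bmatrix.sample_ids])
    out_rows = ~in_rows
    st = bmatrix.states
    part = CladePartition(clade_samples=clade)

    der_in = np.sum(st[in_rows, :] == DERIVED, axis=0)
    anc_in = np.sum(st[in_rows, :] == ANCESTRAL, axis=0)
    der_out = np.sum(st[out_rows, :] == DERIVED, axis=0)
    anc_out = np.sum(st[out_rows, :] == ANCESTRAL, axis=0)

    for j in range(bmatrix.n_sites):
        pos = int(bmatrix.positions[j])
        if der_in[j] == 0:
            continue  # no derived carrier inside the clade
        if der_out[j] > 0:
            part.excluded.add(pos)
            continue
        if out_rows.any() and anc_out[j] == 0:
            part.unresolved.add(pos)  # outside of clade entirely missing
            continue
        if anc_in[j] == 0:
            part.defining.add(pos)
        else:
            part.internal.add(pos)
            if der_in[j] == 1:
                part.private.add(pos)
    return part


def equivalence_classes(partition: CladePartition,
                        tree: PhyloTree) -> list[list[int]]:
    """Group the partition's positions by the branch carrying their
    mutation event: SNPs on one branch are equivalent (cannot be ordered).
    Positions without an event on the tree are omitted."""
    wanted = partition.all_clade_positions() | partition.excluded
    groups: dict[str, list[int]] = {}
    for node in tree.preorder():
        if node.parent is None:
            continue
        here = sorted(p for p, _ in node.events if p in wanted)
        if here:
            groups[node.name] = here
    return [groups[k] for k in sorted(groups)]


def novelty_check(partition: CladePartition,
                  catalog: SnpCatalog) -> NovelSnpSet:
    """Positions of the clade partition absent from the catalog are novel;
    known positions are reported with their catalog names."""
    positions = sorted(partition.all_clade_positions())
    novel = [p for p in positions if p not in catalog]
    known = {p: catalog.name_of(p) for p in positions if p in catalog}
    return NovelSnpSet(positions=novel, known=known)


def name_novel(novel: NovelSnpSet, prefix: str = "GMP",
               start_index: int = 1) -> NovelSnpSet:
    """Assign names prefix+index in genomic-position order, starting at
    ``start_index``; deterministic and gap-free."""
    novel.names = {p: f"{prefix}{start_index + i}"
                   for i, p in enumerate(sorted(novel.positions))}
    return novel
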