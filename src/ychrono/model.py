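"""Core in-memory containers for haploid Y-chromosome variant data.

The pipeline operates on a samples x sites matrix of haploid calls
(:class:`GenotypeMatrix`), a set of callable-region intervals
(:class:`RegionMask`), a catalog of named known SNPs (:class:`SnpCatalog`)
and per-sample metadata (:class:`SampleMeta`).

Coordinate conventions: genomic positions in :class:`GenotypeMatrix` and
:class:`SnpCatalog` are 1-based (VCF convention); :class:`RegionMask`
intervals are 0-based half-open (BED convention). Conversions happen only
at the mask-membership boundary (:meth:`RegionMask.contains`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .errors import InputError

# haploid call codes used throughout the calls matrix (int8)
CALL_REF: int = 0
CALL_ALT: int = 1
CALL_MISSING: int = -1

#: depth value meaning "no DP information for this genotype"
DEPTH_UNKNOWN: int = -1


@dataclass
class GenotypeMatrix:
    """Haploid calls for a set of samples at a set of biallelic SNV sites.

    Parameters
    ----------
    sample_ids
        Ordered sample identifiers (rows of ``calls``).
    positions
        1-based genomic positions, strictly increasing, no duplicates.
    ref_allele, alt_allele
        Per-site single-nucleotide alleles; ``ref != alt`` everywhere
        (indel records keep their full allele strings and are flagged).
    calls
        int8 array of shape (n_samples, n_sites) with values
        ``CALL_REF`` / ``CALL_ALT`` / ``CALL_MISSING``.
    depths
        Optional int32 array of the same shape; ``DEPTH_UNKNOWN`` where the
        VCF carried no per-genotype DP.
    site_is_indel
        Boolean per site; True when either allele is longer than 1 bp.
    """

    sample_ids: list[str]
    positions: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    calls: np.ndarray
    depths: np.ndarray | None = None
    site_is_indel: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.site_is_indel is None:
            self.site_is_indel = np.array(
                [len(str(r)) != 1 or len(str(a)) != 1
                 for r, a in zip(self.ref_allele, self.alt_allele)],
                dtype=bool,
            )
        else:
            self.site_is_indel = np.asarray(self.site_is_indel, dtype=bool)
        if self.depths is not None:
            self.depths = np.asarray(self.depths, dtype=np.int32)
        self._validate()

    def _validate(self) -> None:
        n, s = len(self.sample_ids), len(self.positions)
        if len(set(self.sample_ids)) != n:
            raise InputError("duplicate sample ids")
        if self.calls.shape != (n, s):
            raise InputError(
                f"calls shape {self.calls.shape} != ({n}, {s})")
        if s and np.any(np.diff(self.positions) <= 0):
            raise InputError("positions must be strictly increasing")
        if self.depths is not None and self.depths.shape != (n, s):
            raise InputError("depths shape mismatch")
        for r, a in zip(self.ref_allele, self.alt_allele):
            if str(r) == str(a):
                raise InputError(f"ref == alt allele {r!r}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise InputError(f"sample {sample_id!r} not in matrix") from None

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to sites selected by ``index`` (bool or int)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            positions=self.positions[index],
            ref_allele=self.ref_allele[index],
            alt_allele=self.alt_allele[index],
            calls=self.calls[:, index],
            depths=None if self.depths is None else self.depths[:, index],
            site_is_indel=self.site_is_indel[index],
        )

    def drop_samples(self, sample_ids: Iterable[str]) -> "GenotypeMatrix":
        drop = set(sample_ids)
        keep = [i for i, s in enumerate(self.sample_ids) if s not in drop]
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in keep],
            positions=self.positions.copy(),
            ref_allele=self.ref_allele.copy(),
            alt_allele=self.alt_allele.copy(),
            calls=self.calls[keep, :],
            depths=None if self.depths is None else self.depths[keep, :],
            site_is_indel=self.site_is_indel.copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            positions=self.positions.copy(),
            ref_allele=self.ref_allele.copy(),
            alt_allele=self.alt_allele.copy(),
            calls=self.calls.copy(),
            depths=None if self.depths is None else self.depths.copy(),
            site_is_indel=self.site_is_indel.copy(),
        )


@dataclass(frozen=True)
class RegionMask:
    """Callable territory on one sequence: sorted, merged, 0-based half-open
    intervals whose total span is the effective length L used in dating."""

    starts: np.ndarray
    ends: np.ndarray

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple[int, int]]) -> "RegionMask":
        """Build a mask from arbitrary (start, end) pairs, merging overlaps
        and book-ended intervals with a sweep over the sorted starts."""
        pairs = sorted((int(s), int(e)) for s, e in intervals)
        for s, e in pairs:
            if e <= s:
                raise InputError(f"interval end {e} <= start {s}")
        merged: list[list[int]] = []
        for s, e in pairs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        starts = np.array([m[0] for m in merged], dtype=np.int64)
        ends = np.array([m[1] for m in merged], dtype=np.int64)
        return cls(starts=starts, ends=ends)

    @classmethod
    def empty(cls) -> "RegionMask":
        return cls(starts=np.empty(0, np.int64), ends=np.empty(0, np.int64))

    @property
    def intervals(self) -> list[tuple[int, int]]:
        return [(int(s), int(e)) for s, e in zip(self.starts, self.ends)]

    @property
    def effective_length_bp(self) -> int:
        return int(np.sum(self.ends - self.starts))

    def contains(self, positions_1based: np.ndarray) -> np.ndarray:
        """Boolean membership of 1-based positions in the 0-based mask."""
        pos0 = np.asarray(positions_1based, dtype=np.int64) - 1
        if len(self.starts) == 0:
            return np.zeros(pos0.shape, dtype=bool)
        idx = np.searchsorted(self.starts, pos0, side="right") - 1
        ok = idx >= 0
        out = np.zeros(pos0.shape, dtype=bool)
        out[ok] = pos0[ok] < self.ends[idx[ok]]
        return out


class CatalogEntry(NamedTuple):
    name: str
    ancestral: str
    derived: str


@dataclass
class SnpCatalog:
    """Known-SNP reference set (ISOGG style), keyed by 1-based position."""

    entries: dict[int, CatalogEntry] = field(default_factory=dict)

    def __contains__(self, position: int) -> bool:
        return int(position) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def name_of(self, position: int) -> str | None:
        e = self.entries.get(int(position))
        return e.name if e else None


@dataclass(frozen=True)
class SampleMeta:
    """One metadata row per sample: population label and whether the sample
    is a high-coverage complete sequence (eligible for dating)."""

    sample_id: str
    population: str
    high_coverage: bool


def validate_meta(matrix: GenotypeMatrix,
                  meta: Sequence[SampleMeta]) -> Mapping[str, SampleMeta]:
    """Check that every matrix sample has exactly one metadata row."""
    by_id: dict[str, SampleMeta] = {}
    for m in meta:
        if m.sample_id in by_id:
            raise InputError(f"duplicate metadata row for {m.sample_id!r}")
        by_id[m.sample_id] = m
    missing = [s for s in matrix.sample_ids if s not in by_id]
    if missing:
        raise InputError(f"metadata missing for samples: {missing}")
    return by_id
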