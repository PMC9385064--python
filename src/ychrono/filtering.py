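"""Site/genotype filter cascade for haploid Y-chromosome call matrices.

Stage order: mask & indel removal -> per-genotype depth -> per-site
missingness -> monomorphic removal. The depth stage converts low-depth
calls to missing instead of deleting sites, so the missingness stage then
governs which sites are dropped; the monomorphic stage runs last because
the depth stage can render sites monomorphic. The cascade is idempotent.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .model import CALL_MISSING, DEPTH_UNKNOWN, GenotypeMatrix, RegionMask

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the cascade.

    min_depth
        Genotypes with known depth strictly below this become missing
        (default 2: depth-1 calls are discarded, depth-2 kept).
    max_missingness
        Sites whose missing fraction is strictly greater than this are
        removed (default 0.1; a site at exactly the boundary is kept).
    """

    min_depth: int = 2
    max_missingness: float = 0.1
    drop_indels: bool = True
    require_mask: bool = True
    drop_monomorphic: bool = True

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ConfigError("min_depth must be >= 0")
        if not 0.0 <= self.max_missingness <= 1.0:
            raise ConfigError("max_missingness must be in [0, 1]")


@dataclass
class StageCount:
    stage: str
    sites_in: int
    sites_removed: int
    genotypes_set_missing: int

    @property
    def sites_out(self) -> int:
        return self.sites_in - self.sites_removed


@dataclass
class FilterReport:
    stages: list[StageCount] = field(default_factory=list)

    def add(self, stage: str, sites_in: int, sites_removed: int,
            genotypes_set_missing: int = 0) -> None:
        self.stages.append(
            StageCount(stage, sites_in, sites_removed, genotypes_set_missing))

    @property
    def sites_in(self) -> int:
        return self.stages[0].sites_in if self.stages else 0

    @property
    def sites_out(self) -> int:
        return self.stages[-1].sites_out if self.stages else 0

    def to_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["stage", "sites_in", "sites_removed", "sites_out",
                        "genotypes_set_missing"])
            for s in self.stages:
                w.writerow([s.stage, s.sites_in, s.sites_removed,
                            s.sites_out, s.genotypes_set_missing])


def apply_depth_filter(matrix: GenotypeMatrix,
                       min_depth: int = 2) -> GenotypeMatrix:
    """Set calls with known depth < min_depth to missing. No sites are
    removed here. A matrix without any depth information passes through
    unchanged (logged)."""
    if min_depth < 0:
        raise ConfigError("min_depth must be >= 0")
    if matrix.depths is None or not np.any(matrix.depths != DEPTH_UNKNOWN):
        log.warning("depth filter skipped: no per-genotype depths available")
        return matrix.copy()
    out = matrix.copy()
    low = (out.depths != DEPTH_UNKNOWN) & (out.depths < min_depth)
    out.calls[low] = CALL_MISSING
    return out


def apply_missingness_filter(matrix: GenotypeMatrix,
                             max_missingness: float = 0.1) -> GenotypeMatrix:
    """Remove sites with missing fraction strictly above the threshold."""
    if matrix.n_sites == 0:
        return matrix.copy()
    frac = np.mean(matrix.calls == CALL_MISSING, axis=0)
    return matrix.take_sites(frac <= max_missingness)


def drop_indels_and_masked(matrix: GenotypeMatrix,
                           mask: RegionMask | None,
                           drop_indels: bool = True) -> GenotypeMatrix:
    """Remove indel sites and sites outside the callable mask."""
    keep = np.ones(matrix.n_sites, dtype=bool)
    if drop_indels:
        keep &= ~matrix.site_is_indel
    if mask is not None:
        keep &= mask.contains(matrix.positions)
    return matrix.take_sites(keep)


def drop_monomorphic(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Remove sites whose non-missing calls are all identical (evaluated
    over non-missing calls only; an all-missing site is also removed)."""
    from .variant_io import variable_site_index

    return matrix.take_sites(variable_site_index(matrix))


def run_filter_cascade(matrix: GenotypeMatrix,
                       mask: RegionMask | None = None,
                       config: FilterConfig | None = None,
                       ) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the full cascade in its documented order and account for every
    site and genotype touched."""
    cfg = config or FilterConfig()
    report = FilterReport()
    cur = matrix

    n_in = cur.n_sites
    step = drop_indels_and_masked(
        cur, mask if cfg.require_mask else None, drop_indels=cfg.drop_indels)
    report.add("mask_and_indels", n_in, n_in - step.n_sites)
    cur = step

    n_in = cur.n_sites
    before = int(np.sum(cur.calls == CALL_MISSING))
    step = apply_depth_filter(cur, cfg.min_depth)
    newly = int(np.sum(step.calls == CALL_MISSING)) - before
    report.add("depth", n_in, 0, genotypes_set_missing=newly)
    cur = step

    n_in = cur.n_sites
    step = apply_missingness_filter(cur, cfg.max_missingness)
    report.add("missingness", n_in, n_in - step.n_sites)
    cur = step

    n_in = cur.n_sites
    if cfg.drop_monomorphic:
        step = drop_monomorphic(cur)
    else:
        step = cur.copy()
    report.add("monomorphic", n_in, n_in - step.n_sites)
    return step, report
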