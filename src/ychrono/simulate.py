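"""Clock-tree haplotype simulator with known truth.

Generates a rooted ultrametric tree (tip ages 0), drops mutations on each
branch as Poisson(mu * L * branch_years) at unique positions inside the
callable mask (infinite sites, with optional injected recurrence), and
emits haploid genotypes — optionally corrupted with missingness and
low-depth calls — as VCF plus truth files. Because the dating model only
consumes branch durations, branch times are simulated directly rather
than through a coalescent with an effective population size; an arbitrary
demography can be supplied as a Newick tree with branch lengths in years.

Defaults mirror the study conditions of the pipeline's source data:
a 10.45 Mb callable length and a rate of 0.76e-9 mutations/site/year.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .dating import DEFAULT_RATE, MutationRate
from .errors import ConfigError, InputError
from .model import (CALL_ALT, CALL_MISSING, CALL_REF, GenotypeMatrix,
                    RegionMask, SampleMeta)
from .tree import Node, PhyloTree

#: callable length matching the pipeline's default mask (bp)
DEFAULT_MASK = RegionMask.from_intervals([(0, 10_450_000)])

_NUCS = np.array(["A", "C", "G", "T"])

#: depth assigned to uncorrupted calls / to low-depth corrupted calls
GOOD_DEPTH = 30
LOW_DEPTH = 1


@dataclass(frozen=True)
class SimConfig:
    n_tips: int = 20
    root_age_years: float = 20_000.0
    rate: MutationRate = DEFAULT_RATE
    mask: RegionMask = field(default_factory=lambda: DEFAULT_MASK)
    newick: str | None = None  # user-supplied aged topology overrides n_tips
    recurrent_fraction: float = 0.0
    missingness_rate: float = 0.0
    low_depth_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.newick is None:
            if self.n_tips < 2:
                raise ConfigError("n_tips must be >= 2")
            if self.root_age_years <= 0:
                raise ConfigError("root_age_years must be > 0")
        for name in ("recurrent_fraction", "missingness_rate",
                     "low_depth_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigError(f"{name} must be in [0, 1)")


@dataclass
class SimTruth:
    tree: PhyloTree
    #: branch name -> sorted list of mutation positions (1-based)
    branch_mutations: dict[str, list[int]]
    #: position -> (ref, alt, frozenset of carrier tip names)
    sites: dict[int, tuple[str, str, frozenset[str]]]
    seed: int = 0

    @property
    def n_mutations(self) -> int:
        return sum(len(v) for v in self.branch_mutations.values())


def _substream(seed: int, stage: int) -> np.random.Generator:
    # independent per-stage streams derived from the one global seed
    return np.random.default_rng(np.random.SeedSequence([seed, stage]))


def simulate_tree(config: SimConfig) -> PhyloTree:
    """Random rooted clock tree with fixed root age.

    Lineages start at the tips (age 0) and are joined pairwise at n-2
    uniform random ages below the root age, with the final join fixed at
    the root age; the joining pair is chosen uniformly. Reproducible given
    the seed; node ages strictly decrease from root to tips.
    """
    if config.newick is not None:
        tree = PhyloTree.from_newick(config.newick)
        if any(n.age is None for n in tree.preorder()):
            raise InputError("supplied newick must carry branch lengths")
        tree.name_internal()
        return tree
    rng = _substream(config.seed, 0)
    n = config.n_tips
    ages = np.sort(rng.uniform(0.0, config.root_age_years, size=n - 2))
    lineages: list[Node] = [Node(f"t{i + 1:03d}", age=0.0)
                            for i in range(n)]
    for k in range(n - 1):
        age = config.root_age_years if k == n - 2 else float(ages[k])
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        parent = Node(age=age)
        parent.add_child(lineages[i])
        parent.add_child(lineages[j])
        lineages[j:j + 1] = []
        lineages[i] = parent
    tree = PhyloTree(lineages[0])
    tree.root.name = "root"
    tree.name_internal()
    return tree


def _offsets_to_positions(mask: RegionMask, offsets: np.ndarray) -> np.ndarray:
    lengths = mask.ends - mask.starts
    cum = np.cumsum(lengths)
    idx = np.searchsorted(cum, offsets, side="right")
    prev = np.concatenate([[0], cum[:-1]])
    return mask.starts[idx] + (offsets - prev[idx]) + 1  # 1-based


def _draw_unique_positions(rng: np.random.Generator, mask: RegionMask,
                           k: int, used: set[int]) -> list[int]:
    L = mask.effective_length_bp
    if k + len(used) > L:
        raise ConfigError("mask too small for the requested mutation count")
    out: list[int] = []
    while len(out) < k:
        batch = rng.integers(0, L, size=max(16, 2 * (k - len(out))))
        for pos in _offsets_to_positions(mask, batch):
            p = int(pos)
            if p not in used:
                used.add(p)
                out.append(p)
                if len(out) == k:
                    break
    return out


def drop_mutations(tree: PhyloTree, config: SimConfig) -> SimTruth:
    """Place Poisson mutations on every branch of an aged tree.

    Counts are Poisson(rate.central * L * branch_years); positions are
    sampled uniformly without replacement from the mask. With probability
    ``recurrent_fraction`` a mutation instead reuses a position already
    mutated on an unrelated branch (neither ancestor nor descendant),
    creating a deliberate infinite-sites violation.
    """
    rng = _substream(config.seed, 1)
    L = config.mask.effective_length_bp
    mu = config.rate.central

    branches = [n for n in tree.preorder() if n.parent is not None]
    for b in branches:
        if b.branch_years is None:
            raise InputError("tree must carry node ages for simulation")

    counts = {b.name: int(rng.poisson(mu * L * b.branch_years))
              for b in branches}
    used: set[int] = set()
    branch_mutations: dict[str, list[int]] = {}
    pos_branches: dict[int, list[Node]] = {}
    ancestors: dict[str, set[str]] = {}
    for b in branches:
        anc, cur = set(), b.parent
        while cur is not None:
            anc.add(cur.name)
            cur = cur.parent
        ancestors[b.name] = anc

    for b in branches:
        fresh = _draw_unique_positions(rng, config.mask, counts[b.name], used)
        positions: list[int] = []
        for p in fresh:
            if config.recurrent_fraction > 0 and \
                    rng.random() < config.recurrent_fraction:
                candidates = [q for q, owners in pos_branches.items()
                              if all(_unrelated(b, o, ancestors)
                                     for o in owners)]
                if candidates:
                    p = candidates[int(rng.integers(len(candidates)))]
            positions.append(p)
            pos_branches.setdefault(p, []).append(b)
        branch_mutations[b.name] = sorted(positions)

    sites: dict[int, tuple[str, str, frozenset[str]]] = {}
    allele_rng = _substream(config.seed, 2)
    for p in sorted(pos_branches):
        carriers: set[str] = set()
        for b in pos_branches[p]:
            carriers |= tree.tipset(b)
        ref, alt = allele_rng.choice(4, size=2, replace=False)
        sites[p] = (str(_NUCS[ref]), str(_NUCS[alt]), frozenset(carriers))

    truth = SimTruth(tree=tree, branch_mutations=branch_mutations,
                     sites=sites, seed=config.seed)
    for b in branches:  # annotate the truth tree itself
        b.events = [(p, "gain") for p in branch_mutations[b.name]]
    tree.recurrent = {p: len(v) for p, v in pos_branches.items()
                      if len(v) > 1}
    return truth


def _unrelated(a: Node, b: Node, ancestors: dict[str, set[str]]) -> bool:
    return (a.name != b.name and a.name not in ancestors[b.name]
            and b.name not in ancestors[a.name])


def truth_matrix(truth: SimTruth,
                 outgroup_id: str = "OUTGROUP") -> GenotypeMatrix:
    """Haploid genotype matrix implied by the truth, with an all-ancestral
    outgroup row appended (derived allele encoded as ALT)."""
    tips = truth.tree.tip_names
    positions = sorted(truth.sites)
    n = len(tips) + 1
    calls = np.zeros((n, len(positions)), dtype=np.int8)
    refs, alts = [], []
    tip_index = {t: i for i, t in enumerate(tips)}
    for j, p in enumerate(positions):
        ref, alt, carriers = truth.sites[p]
        refs.append(ref)
        alts.append(alt)
        for c in carriers:
            calls[tip_index[c], j] = CALL_ALT
    return GenotypeMatrix(
        sample_ids=tips + [outgroup_id],
        positions=np.asarray(positions, dtype=np.int64),
        ref_allele=np.asarray(refs, dtype=object),
        alt_allele=np.asarray(alts, dtype=object),
        calls=calls,
        depths=np.full((n, len(positions)), GOOD_DEPTH, dtype=np.int32),
    )


def corrupt(matrix: GenotypeMatrix, config: SimConfig) -> GenotypeMatrix:
    """Stress copy of the matrix: each call is set missing with probability
    ``missingness_rate`` and assigned depth 1 (else 30) with probability
    ``low_depth_rate``. Seeded from the config."""
    rng = _substream(config.seed, 3)
    out = matrix.copy()
    shape = out.calls.shape
    if config.missingness_rate > 0:
        hit = rng.random(shape) < config.missingness_rate
        out.calls[hit] = CALL_MISSING
    depths = np.full(shape, GOOD_DEPTH, dtype=np.int32)
    if config.low_depth_rate > 0:
        depths[rng.random(shape) < config.low_depth_rate] = LOW_DEPTH
    out.depths = depths
    return out


def emit_dataset(truth: SimTruth, out_dir,
                 config: SimConfig | None = None,
                 outgroup_id: str = "OUTGROUP") -> dict[str, Path]:
    """Write VCF + Newick + truth TSVs (+ sample metadata) to a directory.

    When a config with corruption rates is given, the emitted VCF carries
    the corrupted calls; truth files always describe the clean simulation.
    """
    from .variant_io import write_haploid_vcf, write_sample_meta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix = truth_matrix(truth, outgroup_id=outgroup_id)
    if config is not None and (config.missingness_rate > 0
                               or config.low_depth_rate > 0):
        matrix = corrupt(matrix, config)

    paths = {
        "vcf": out / "simulated.vcf",
        "newick": out / "true_tree.nwk",
        "node_ages": out / "node_ages.tsv",
        "branch_mutations": out / "branch_mutations.tsv",
        "metadata": out / "samples.tsv",
    }
    write_haploid_vcf(matrix, paths["vcf"])
    with open(paths["newick"], "w") as fh:
        fh.write(truth.tree.to_newick() + "\n")
    with open(paths["node_ages"], "w") as fh:
        fh.write("node\tage_years\n")
        for n in truth.tree.preorder():
            fh.write(f"{n.name}\t{n.age:.6f}\n")
    with open(paths["branch_mutations"], "w") as fh:
        fh.write("branch\tn_mutations\tpositions\n")
        for name in sorted(truth.branch_mutations):
            pos = truth.branch_mutations[name]
            fh.write(f"{name}\t{len(pos)}\t"
                     + ",".join(map(str, pos)) + "\n")
    meta = [SampleMeta(t, "simulated", True) for t in truth.tree.tip_names]
    meta.append(SampleMeta(outgroup_id, "outgroup", True))
    write_sample_meta(meta, paths["metadata"])
    return paths


def simulate_dataset(config: SimConfig
                     ) -> tuple[SimTruth, GenotypeMatrix]:
    """Convenience: tree + mutations + (possibly corrupted) matrix."""
    tree = simulate_tree(config)
    truth = drop_mutations(tree, config)
    matrix = truth_matrix(truth)
    if config.missingness_rate > 0 or config.low_depth_rate > 0:
        matrix = corrupt(matrix, config)
    return truth, matrix
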