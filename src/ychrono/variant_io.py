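"""Readers and writers for the formats the pipeline touches.

VCF ingestion goes through cyvcf2; FASTA output through Biopython; Newick
through :mod:`ychrono.tree` (dendropy-backed). BED masks, SNP catalogs and
sample metadata are plain TSV read with pandas.

The VCF reader expects haploid genotypes. Diploid records are accepted:
homozygous calls collapse to the single allele, heterozygous calls on the
haploid Y are treated as missing (and counted in the QC report). Records
with several ALT alleles are reduced to the major ALT; genotypes carrying a
minor ALT become missing, so every retained site is strictly biallelic and
each position appears once.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .errors import InputError
from .model import (CALL_ALT, CALL_MISSING, CALL_REF, DEPTH_UNKNOWN,
                    CatalogEntry, GenotypeMatrix, RegionMask, SampleMeta,
                    SnpCatalog)
from .tree import read_newick, write_newick  # re-exported  # noqa: F401

#: character written to FASTA columns where the call is missing
DEFAULT_MISSING_CHAR = "N"


@dataclass
class VcfReadReport:
    """QC counts accumulated while ingesting a VCF."""

    records_total: int = 0
    records_outside_mask: int = 0
    heterozygous_set_missing: int = 0
    minor_alt_set_missing: int = 0
    multiallelic_records: int = 0


def read_haploid_vcf(path, mask: RegionMask | None = None,
                     report: VcfReadReport | None = None) -> GenotypeMatrix:
    """Read a (haploid) VCF into a :class:`GenotypeMatrix`.

    Records outside ``mask`` (when given) are excluded up front. Per-genotype
    depth is taken from the FORMAT/DP field when present.
    """
    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:
        raise InputError(f"cannot read VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise InputError(f"VCF {path} has zero samples")
    rep = report if report is not None else VcfReadReport()

    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    call_cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray] = []
    any_depth = False

    for variant in vcf:
        rep.records_total += 1
        pos = variant.POS
        if mask is not None and not mask.contains(np.array([pos]))[0]:
            rep.records_outside_mask += 1
            continue
        alt_list = [a for a in variant.ALT if a not in (".", "")]
        if not alt_list:
            continue
        if len(alt_list) > 1:
            rep.multiallelic_records += 1

        gt_alleles = _genotype_alleles(variant, len(samples), rep)
        if len(alt_list) > 1:
            # keep the ALT with the most carriers (ties: first listed);
            # genotypes carrying another ALT become missing
            counts = [int(np.sum(gt_alleles == i + 1))
                      for i in range(len(alt_list))]
            major = int(np.argmax(counts))
            keep_code = major + 1
            col = np.full(len(samples), CALL_MISSING, dtype=np.int8)
            col[gt_alleles == 0] = CALL_REF
            col[gt_alleles == keep_code] = CALL_ALT
            rep.minor_alt_set_missing += int(
                np.sum((gt_alleles > 0) & (gt_alleles != keep_code)))
            alt = alt_list[major]
        else:
            col = np.full(len(samples), CALL_MISSING, dtype=np.int8)
            col[gt_alleles == 0] = CALL_REF
            col[gt_alleles == 1] = CALL_ALT
            alt = alt_list[0]

        dp = variant.format("DP")
        if dp is not None:
            dcol = np.asarray(dp, dtype=np.int32).reshape(len(samples))
            dcol[dcol < 0] = DEPTH_UNKNOWN
            any_depth = True
        else:
            dcol = np.full(len(samples), DEPTH_UNKNOWN, dtype=np.int32)

        positions.append(pos)
        refs.append(variant.REF)
        alts.append(alt)
        call_cols.append(col)
        depth_cols.append(dcol)

    order = np.argsort(np.asarray(positions, dtype=np.int64), kind="stable")
    calls = (np.stack(call_cols, axis=1)[:, order]
             if call_cols else np.zeros((len(samples), 0), dtype=np.int8))
    depths = (np.stack(depth_cols, axis=1)[:, order]
              if any_depth and depth_cols else None)
    return GenotypeMatrix(
        sample_ids=samples,
        positions=np.asarray(positions, dtype=np.int64)[order],
        ref_allele=np.asarray(refs, dtype=object)[order],
        alt_allele=np.asarray(alts, dtype=object)[order],
        calls=calls,
        depths=depths,
    )


def _genotype_alleles(variant, n_samples: int,
                      rep: VcfReadReport) -> np.ndarray:
    """Collapse cyvcf2 genotypes to one allele code per sample
    (-1 missing, 0 REF, k = k-th ALT)."""
    out = np.full(n_samples, -1, dtype=np.int32)
    for i, gt in enumerate(variant.genotypes):
        alleles = [a for a in gt[:-1] if a is not None]
        alleles = [a for a in alleles if a >= 0]
        if not alleles:
            continue
        if len(set(alleles)) > 1:  # heterozygous on the haploid Y
            rep.heterozygous_set_missing += 1
            continue
        out[i] = alleles[0]
    return out


def write_haploid_vcf(matrix: GenotypeMatrix, path,
                      chrom: str = "chrY") -> None:
    """Write the matrix back out as a minimal haploid VCF v4.2 (GT and,
    when depths are known, DP per genotype)."""
    with_depth = matrix.depths is not None
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description='
                 '"Genotype">\n')
        if with_depth:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description='
                     '"Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.sample_ids) + "\n")
        fmt = "GT:DP" if with_depth else "GT"
        for j in range(matrix.n_sites):
            fields = [chrom, str(int(matrix.positions[j])), ".",
                      str(matrix.ref_allele[j]), str(matrix.alt_allele[j]),
                      ".", "PASS", ".", fmt]
            for i in range(matrix.n_samples):
                c = matrix.calls[i, j]
                gt = "." if c == CALL_MISSING else str(int(c))
                if with_depth:
                    d = int(matrix.depths[i, j])
                    gt += ":" + ("." if d == DEPTH_UNKNOWN else str(d))
                fields.append(gt)
            fh.write("\t".join(fields) + "\n")


def read_region_mask(path) -> RegionMask:
    """Read a BED3 file (0-based half-open) into a merged RegionMask."""
    intervals: list[tuple[int, int]] = []
    try:
        with open(path) as fh:
            for line_no, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise InputError(
                        f"{path}:{line_no}: BED needs >= 3 columns")
                start, end = int(parts[1]), int(parts[2])
                if end <= start:
                    raise InputError(
                        f"{path}:{line_no}: end {end} <= start {start}")
                intervals.append((start, end))
    except OSError as exc:
        raise InputError(f"cannot read BED {path}: {exc}") from exc
    if not intervals:
        return RegionMask.empty()
    return RegionMask.from_intervals(intervals)


def write_region_mask(mask: RegionMask, path, chrom: str = "chrY") -> None:
    with open(path, "w") as fh:
        for s, e in mask.intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")


def variable_site_index(matrix: GenotypeMatrix) -> np.ndarray:
    """Boolean index of sites with >= 2 distinct non-missing calls."""
    has_ref = np.any(matrix.calls == CALL_REF, axis=0)
    has_alt = np.any(matrix.calls == CALL_ALT, axis=0)
    return has_ref & has_alt


def write_variable_sites_fasta(matrix: GenotypeMatrix, path,
                               missing_char: str = DEFAULT_MISSING_CHAR) -> None:
    """One FASTA record per sample over the variable sites only, REF/ALT
    rendered as their nucleotides and missing calls as ``missing_char``."""
    if matrix.n_samples == 0 or matrix.n_sites == 0:
        raise InputError("cannot write FASTA from an empty matrix")
    keep = variable_site_index(matrix)
    sub = matrix.take_sites(keep)
    records = []
    for i, sid in enumerate(sub.sample_ids):
        chars = []
        for j in range(sub.n_sites):
            c = sub.calls[i, j]
            if c == CALL_REF:
                chars.append(str(sub.ref_allele[j]))
            elif c == CALL_ALT:
                chars.append(str(sub.alt_allele[j]))
            else:
                chars.append(missing_char)
        records.append(SeqRecord(Seq("".join(chars)), id=sid, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_snp_catalog(path) -> SnpCatalog:
    """TSV with columns name, pos, anc, der (header required)."""
    df = _read_tsv(path, required={"name", "pos", "anc", "der"})
    entries: dict[int, CatalogEntry] = {}
    for row in df.itertuples(index=False):
        pos = int(row.pos)
        if pos in entries:
            raise InputError(f"duplicate catalog position {pos}")
        entries[pos] = CatalogEntry(str(row.name), str(row.anc), str(row.der))
    return SnpCatalog(entries=entries)


def write_snp_catalog(catalog: SnpCatalog, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["name", "pos", "anc", "der"])
        for pos in sorted(catalog.entries):
            e = catalog.entries[pos]
            w.writerow([e.name, pos, e.ancestral, e.derived])


def read_sample_meta(path) -> list[SampleMeta]:
    """TSV with columns sample, population, high_coverage (true/false)."""
    df = _read_tsv(path, required={"sample", "population", "high_coverage"})
    out = []
    for row in df.itertuples(index=False):
        out.append(SampleMeta(
            sample_id=str(row.sample),
            population=str(row.population),
            high_coverage=_parse_bool(row.high_coverage),
        ))
    return out


def write_sample_meta(meta: list[SampleMeta], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample", "population", "high_coverage"])
        for m in meta:
            w.writerow([m.sample_id, m.population,
                        "true" if m.high_coverage else "false"])


def _read_tsv(path, required: set[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot read TSV {path}: {exc}") from exc
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    return df


def _parse_bool(value) -> bool:
    s = str(value).strip().lower()
    if s in {"true", "1", "yes", "t"}:
        return True
    if s in {"false", "0", "no", "f"}:
        return False
    raise InputError(f"cannot parse boolean {value!r}")
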