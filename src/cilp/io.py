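"""File formats and dataset alignment.

Tables are tab-separated: traits and covariates have samples as rows with the
sample id in the first column; genotypes are either a plink-traw-like dosage
TSV (SNPs as rows) or a VCF with GT fields.  Readers return the package's
containers; :func:`align_samples` intersects sample ids across inputs with a
logged report of what was dropped.  All coordinates are 1-based (VCF
convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    CilpError,
    CovariateTable,
    GenotypeMatrix,
    StratumLabels,
    TraitMatrix,
)

logger = logging.getLogger("cilp")

__all__ = [
    "read_traits",
    "write_traits",
    "read_covariates",
    "read_annotations",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_genotypes_vcf",
    "write_genotypes_vcf",
    "align_samples",
    "AlignmentReport",
]

_NA = "NA"


def read_traits(path) -> TraitMatrix:
    """Samples x traits TSV: first column sample id, header row of trait ids,
    missing encoded as NA."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[_NA])
    df.index.name = None
    return TraitMatrix(df.sort_index())


def write_traits(traits: TraitMatrix, path) -> None:
    out = traits.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep=_NA)


def read_covariates(
    path, categorical: tuple[str, ...] = (), random_group: str | None = None
) -> CovariateTable:
    """Covariate TSV keyed by sample id; ``categorical`` names columns to be
    dummy-coded, ``random_group`` promotes one column to the mixed-model
    grouping factor."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[_NA]).sort_index()
    df.index.name = None
    rg = None
    if random_group is not None:
        if random_group not in df.columns:
            raise CilpError(f"random_group column {random_group!r} not in {path}")
        rg = df[random_group].astype(str)
        df = df.drop(columns=[random_group])
    return CovariateTable(df, categorical=categorical, random_group=rg)


def read_annotations(path) -> pd.Series:
    """Two-column TSV trait_id -> category."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise CilpError("annotation file needs columns: trait_id, category")
    s = df.set_index(df.columns[0])[df.columns[1]].astype(str)
    if s.index.has_duplicates:
        dups = s.index[s.index.duplicated()].unique().tolist()
        raise CilpError(f"traits annotated more than once: {dups[:5]}")
    return s


def read_genotypes_tsv(path, positions_path=None) -> GenotypeMatrix:
    """Dosage TSV with SNPs as rows (first column snp_id, one column per
    sample), values in {0, 1, 2} or NA; optional positions TSV with columns
    snp_id, chrom, pos (1-based)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[_NA])
    df = df.T.sort_index()
    df.index.name = None
    df.columns.name = None
    positions = None
    if positions_path is not None:
        positions = read_positions(positions_path)
    return GenotypeMatrix(df, positions)


def read_positions(path) -> pd.DataFrame:
    pos = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos"}
    id_col = pos.columns[0]
    if not required <= set(pos.columns):
        raise CilpError(f"positions file needs columns {sorted(required)}")
    pos = pos.set_index(id_col)
    pos["pos"] = pos["pos"].astype(int)
    return pos


def write_genotypes_tsv(genotypes: GenotypeMatrix, path, positions_path=None) -> None:
    out = genotypes.data.T.copy()
    out.index.name = "snp_id"
    out.to_csv(path, sep="\t", na_rep=_NA, float_format="%g")
    if positions_path is not None and genotypes.positions is not None:
        pos = genotypes.positions.copy()
        pos.index.name = "snp_id"
        pos.to_csv(positions_path, sep="\t")


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Read GT fields from a VCF into ALT-allele dosages (phased or unphased);
    missing alleles give NaN.  Requires cyvcf2."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise CilpError("reading VCF requires the cyvcf2 package") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, rows, chroms, positions = [], [], [], []
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        if vid in snp_ids:
            raise CilpError(f"duplicate variant id {vid}")
        gt = np.asarray(var.genotype.array())[:, :2].astype(float)
        gt[gt < 0] = np.nan
        dosage = gt.sum(axis=1)
        snp_ids.append(vid)
        rows.append(dosage)
        chroms.append(var.CHROM)
        positions.append(var.POS)
    data = pd.DataFrame(
        np.array(rows).T if rows else np.empty((len(samples), 0)),
        index=samples,
        columns=snp_ids,
    )
    pos = pd.DataFrame({"chrom": chroms, "pos": positions}, index=snp_ids)
    return GenotypeMatrix(data.sort_index(), pos)


def write_genotypes_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Minimal VCF v4.2 with GT-only FORMAT, unphased, REF=A ALT=B placeholders."""
    if genotypes.positions is None:
        raise CilpError("writing VCF requires SNP positions")
    samples = genotypes.sample_ids
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    order = genotypes.positions.sort_values(["chrom", "pos"]).index
    for snp in order:
        if snp not in genotypes.data.columns:
            continue
        row = genotypes.positions.loc[snp]
        dosages = genotypes.data[snp]
        gts = "\t".join(
            "./." if np.isnan(d) else code[float(d)] for d in dosages
        )
        lines.append(
            f"{row['chrom']}\t{int(row['pos'])}\t{snp}\tA\tB\t.\tPASS\t.\tGT\t{gts}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


@dataclass
class AlignmentReport:
    n_common: int
    dropped: dict[str, list[str]]

    def summary(self) -> str:
        parts = [f"{len(v)} dropped from {k}" for k, v in self.dropped.items() if v]
        return f"{self.n_common} common samples" + (
            "; " + "; ".join(parts) if parts else ""
        )


def align_samples(**named_tables) -> tuple[dict, AlignmentReport]:
    """Subset every table to the sorted intersection of sample ids.

    Accepts TraitMatrix, GenotypeMatrix, CovariateTable, StratumLabels and
    pandas Series/DataFrame keyword arguments; returns aligned copies plus a
    report of dropped samples per input.
    """

    def ids_of(obj):
        if isinstance(obj, (TraitMatrix, GenotypeMatrix)):
            return pd.Index(obj.data.index)
        if isinstance(obj, CovariateTable):
            return pd.Index(obj.fixed.index)
        if isinstance(obj, StratumLabels):
            return pd.Index(obj.labels.index)
        return pd.Index(obj.index)

    common = None
    for obj in named_tables.values():
        ids = ids_of(obj)
        common = ids if common is None else common.intersection(ids)
    if common is None or len(common) == 0:
        raise CilpError("no samples shared across inputs")
    common = common.sort_values()
    dropped = {
        name: sorted(set(ids_of(obj)) - set(common))
        for name, obj in named_tables.items()
    }
    aligned = {}
    for name, obj in named_tables.items():
        if isinstance(obj, TraitMatrix):
            aligned[name] = TraitMatrix(obj.data.loc[common])
        elif isinstance(obj, GenotypeMatrix):
            aligned[name] = GenotypeMatrix(obj.data.loc[common], obj.positions)
        elif isinstance(obj, CovariateTable):
            aligned[name] = CovariateTable(
                obj.fixed.loc[common],
                obj.categorical,
                obj.random_group.loc[common] if obj.random_group is not None else None,
            )
        elif isinstance(obj, StratumLabels):
            aligned[name] = StratumLabels(obj.labels.loc[common])
        else:
            aligned[name] = obj.loc[common]
    report = AlignmentReport(n_common=len(common), dropped=dropped)
    for name, lost in dropped.items():
        if lost:
            logger.info("alignment: dropped %d samples from %s", len(lost), name)
    return aligned, report
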