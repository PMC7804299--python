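"""Genotype ingestion and gene-set construction.

Reads VCF genotypes, orients dosages to the minor allele, applies the
low-frequency variant filters (MAF < 1%, minor allele count >= 4 — i.e.
variants with three or fewer minor alleles removed), groups qualifying
variants into genes (genes need at least two), and assigns Beta(1, 25)
density weights so rarer variants count more.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "GeneVariantSet",
    "read_genotypes",
    "write_vcf",
    "filter_variants",
    "group_by_gene",
    "variant_weights",
]


@dataclass
class GenotypeMatrix:
    """Dosage matrix oriented to the minor allele, with variant metadata.

    ``dosages`` is (n, M) float in {0, 1, 2} with NaN for missing calls.
    ``variants`` has columns variant_id, chrom, pos, ref, alt, maf, mac,
    n_missing, with MAF = MAC / (2 * n_nonmissing) in [0, 0.5].
    """

    ids: np.ndarray
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids).astype(str)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.ids), len(self.variants)):
            raise ValueError("dosage shape does not match ids x variants")
        if (self.variants["pos"] <= 0).any():
            raise ValueError("variant positions must be positive")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)


@dataclass
class GeneVariantSet:
    """Per-gene filtered variant block ready for kernel testing."""

    gene_id: str
    variant_ids: list[str]
    dosages: np.ndarray  # (n, m), NaN-free after imputation
    mafs: np.ndarray
    weights: np.ndarray | None = None
    ids: np.ndarray | None = None

    @property
    def m(self) -> int:
        return len(self.variant_ids)

    @property
    def cumulative_mac(self) -> int:
        return int(np.round(np.nansum(self.dosages)))


def read_genotypes(vcf_path: str, samples: list[str] | None = None) -> GenotypeMatrix:
    """Read a VCF with GT fields into a minor-allele-oriented GenotypeMatrix.

    Multi-allelic sites are skipped (logged); missing calls stay NaN and are
    excluded from the MAF denominator. Requesting samples absent from the
    file is an error listing the discrepancies.
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_path)
    if samples is not None:
        missing = [s for s in samples if s not in vcf.samples]
        if missing:
            raise ValueError(f"samples not in VCF: {missing}")
        vcf = VCF(vcf_path, samples=samples)
    sample_ids = np.asarray(vcf.samples)

    records, cols = [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = np.asarray(v.gt_types)
        dos = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        nonmiss = np.isfinite(dos)
        n_nonmiss = int(nonmiss.sum())
        if n_nonmiss == 0:
            continue
        alt_count = np.nansum(dos)
        flipped = alt_count > n_nonmiss  # alt frequency > 0.5
        if flipped:
            dos = np.where(nonmiss, 2.0 - dos, np.nan)
        mac = int(round(np.nansum(dos)))
        records.append(
            {
                "variant_id": v.ID or f"{v.CHROM}:{v.POS}",
                "chrom": str(v.CHROM),
                "pos": int(v.POS),
                "ref": v.ALT[0] if flipped else v.REF,
                "alt": v.REF if flipped else v.ALT[0],
                "maf": mac / (2.0 * n_nonmiss),
                "mac": mac,
                "n_missing": int((~nonmiss).sum()),
            }
        )
        cols.append(dos)
    if n_multi:
        logger.info("skipped %d multi-allelic sites", n_multi)
    if not records:
        raise ValueError(f"no usable biallelic variants in {vcf_path}")
    dosage = np.column_stack(cols)
    miss_rate = np.isnan(dosage).mean()
    logger.info(
        "read %d variants x %d samples (missingness %.4f)",
        len(records),
        len(sample_ids),
        miss_rate,
    )
    return GenotypeMatrix(sample_ids, pd.DataFrame(records), dosage)


def write_vcf(path: str, g: GenotypeMatrix) -> None:
    """Write an uncompressed VCF 4.2 with GT fields (pysam)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"), ("Description", "Genotype")])
    for chrom in pd.unique(g.variants["chrom"]):
        header.contigs.add(str(chrom))
    for s in g.ids:
        header.add_sample(str(s))
    order = np.lexsort((g.variants["pos"].to_numpy(), g.variants["chrom"].to_numpy()))
    with pysam.VariantFile(path, "w", header=header) as out:
        for j in order:
            row = g.variants.iloc[j]
            rec = out.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                stop=int(row["pos"]),
                alleles=(str(row["ref"]), str(row["alt"])),
                id=str(row["variant_id"]),
            )
            dos = g.dosages[:, j]
            for i, s in enumerate(g.ids):
                d = dos[i]
                if np.isnan(d):
                    rec.samples[str(s)]["GT"] = (None, None)
                else:
                    d = int(round(d))
                    rec.samples[str(s)]["GT"] = (0, 0) if d == 0 else ((0, 1) if d == 1 else (1, 1))
            out.write(rec)


def filter_variants(
    g: GenotypeMatrix, maf_max: float = 0.01, mac_min: int = 4
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Keep variants with MAF < maf_max (strict) and MAC >= mac_min.

    Returns the filtered matrix and a per-variant filter report. The two
    rules commute, so application order is immaterial.
    """
    maf = g.variants["maf"].to_numpy()
    mac = g.variants["mac"].to_numpy()
    pass_maf = maf < maf_max
    pass_mac = mac >= mac_min
    keep = pass_maf & pass_mac
    report = g.variants[["variant_id", "maf", "mac"]].copy()
    report["pass_maf"] = pass_maf
    report["pass_mac"] = pass_mac
    report["kept"] = keep
    logger.info(
        "filter_variants: %d/%d kept (%d fail MAF<%g, %d fail MAC>=%d)",
        keep.sum(),
        len(keep),
        (~pass_maf).sum(),
        maf_max,
        (~pass_mac).sum(),
        mac_min,
    )
    if not keep.any():
        raise ValueError(
            f"no variants pass MAF < {maf_max} and MAC >= {mac_min}; "
            "reconsider thresholds or input"
        )
    out = GenotypeMatrix(
        g.ids, g.variants.loc[keep].reset_index(drop=True), g.dosages[:, keep]
    )
    return out, report


def group_by_gene(
    g: GenotypeMatrix,
    gene_map: pd.DataFrame,
    min_variants: int = 2,
    impute_missing: bool = True,
    beta_a: float = 1.0,
    beta_b: float = 25.0,
) -> list[GeneVariantSet]:
    """Build weighted per-gene variant sets from a filtered GenotypeMatrix.

    Genes with fewer than ``min_variants`` qualifying variants are dropped;
    variants mapping to several genes contribute to each. Missing dosages
    are imputed to 2 * MAF. Variants are ordered by (chrom, pos) within
    genes; gene sets are returned sorted by gene_id.
    """
    known = set(g.variants["variant_id"])
    unmapped = known - set(gene_map["variant_id"])
    if unmapped:
        logger.info("%d filtered variants have no gene mapping", len(unmapped))
    col_of = {vid: j for j, vid in enumerate(g.variants["variant_id"])}
    out: list[GeneVariantSet] = []
    for gene_id, sub in gene_map.groupby("gene_id"):
        vids = [v for v in sub["variant_id"] if v in col_of]
        if len(vids) < min_variants:
            continue
        cols = np.array([col_of[v] for v in vids])
        meta = g.variants.iloc[cols]
        order = np.lexsort((meta["pos"].to_numpy(), meta["chrom"].to_numpy()))
        cols = cols[order]
        vids = [vids[i] for i in order]
        dos = g.dosages[:, cols].copy()
        mafs = g.variants["maf"].to_numpy()[cols]
        if impute_missing:
            for j in range(dos.shape[1]):
                miss = np.isnan(dos[:, j])
                if miss.any():
                    dos[miss, j] = 2.0 * mafs[j]
        out.append(
            GeneVariantSet(
                gene_id=str(gene_id),
                variant_ids=vids,
                dosages=dos,
                mafs=mafs,
                weights=variant_weights(mafs, beta_a, beta_b),
                ids=g.ids,
            )
        )
    out.sort(key=lambda s: s.gene_id)
    logger.info("group_by_gene: %d genes with >= %d variants", len(out), min_variants)
    return out


def variant_weights(
    mafs: np.ndarray, beta_a: float = 1.0, beta_b: float = 25.0
) -> np.ndarray:
    """Beta-density variant weights; Beta(1, 25) upweights rarer variants."""
    mafs = np.asarray(mafs, dtype=float)
    if np.any(mafs <= 0.0):
        raise ValueError("MAF = 0 (monomorphic) should have been filtered out")
    if np.any(mafs > 0.5):
        raise ValueError("MAF must be <= 0.5 after minor-allele orientation")
    return stats.beta.pdf(mafs, beta_a, beta_b)
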