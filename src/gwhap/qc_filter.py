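"""SNP quality filtering, gene-body assignment and spacing-based thinning.

A SNP passes QC iff its minor allele frequency is at least ``maf_min`` and
its missing-call rate is at most ``miss_max`` (both boundaries inclusive).
Allele frequencies are computed on called genotypes only: each homozygote
contributes two alleles, each heterozygote one of each.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .types import ALT_HOM, HET, MISSING, REF_HOM, GeneModel, GeneSNPIndex, GenotypePanel

DEFAULT_MAF_MIN = 0.05
DEFAULT_MISS_MAX = 0.20
DEFAULT_SPACING_BP = 50_000


@dataclass(frozen=True)
class SNPQC:
    """Per-SNP QC metrics. ``maf`` is NaN when every call is missing."""

    snp_id: str
    maf: float
    missing_rate: float
    passed: bool


def compute_snp_qc(
    panel: GenotypePanel,
    maf_min: float = DEFAULT_MAF_MIN,
    miss_max: float = DEFAULT_MISS_MAX,
) -> list[SNPQC]:
    """MAF / missingness QC for every SNP in the panel."""
    if panel.n_snps == 0 or panel.n_accessions == 0:
        raise DataError("cannot QC an empty panel")
    calls = panel.calls
    n_missing = (calls == MISSING).sum(axis=0)
    missing_rate = n_missing / panel.n_accessions
    # allele counts on called genotypes
    n_ref_hom = (calls == REF_HOM).sum(axis=0)
    n_alt_hom = (calls == ALT_HOM).sum(axis=0)
    n_het = (calls == HET).sum(axis=0)
    ref_alleles = 2 * n_ref_hom + n_het
    alt_alleles = 2 * n_alt_hom + n_het
    total = ref_alleles + alt_alleles
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(total > 0, alt_alleles / np.maximum(total, 1), np.nan)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)

    out: list[SNPQC] = []
    for j in range(panel.n_snps):
        if total[j] == 0:
            out.append(SNPQC(panel.snp_ids[j], float("nan"), float(missing_rate[j]), False))
        else:
            passed = bool(maf[j] >= maf_min and missing_rate[j] <= miss_max)
            out.append(SNPQC(panel.snp_ids[j], float(maf[j]), float(missing_rate[j]), passed))
    return out


def filter_panel(panel: GenotypePanel, qc: list[SNPQC]) -> GenotypePanel:
    """Panel restricted to QC-passing SNPs, original order preserved."""
    if len(qc) != panel.n_snps:
        raise DataError(f"QC list length {len(qc)} != panel SNP count {panel.n_snps}")
    keep = [j for j, q in enumerate(qc) if q.passed]
    if not keep:
        n_fail_maf = sum(1 for q in qc if not q.passed)
        raise DataError(
            f"no SNPs pass QC ({n_fail_maf} of {len(qc)} failed)"
        )
    return panel.subset_snps(keep)


def assign_snps_to_genes(panel: GenotypePanel, genes: list[GeneModel]) -> GeneSNPIndex:
    """Map each gene to the panel SNP indices inside [start, end] (inclusive).

    A SNP inside two overlapping genes is listed under both.  Genes with no
    member SNPs are omitted from the index.
    """
    panel_chroms = set(panel.chrom.tolist())
    gene_chroms = {g.chrom for g in genes}
    if genes and panel_chroms.isdisjoint(gene_chroms):
        raise DataError(
            "chromosome labels do not overlap between panel and annotation: "
            f"panel={sorted(panel_chroms)} genes={sorted(gene_chroms)}"
        )
    index = GeneSNPIndex()
    # per-chromosome sorted position arrays for binary search
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in panel_chroms:
        mask = panel.chrom == c
        idx = np.nonzero(mask)[0]
        by_chrom[c] = (panel.pos[idx], idx)
    for g in genes:
        if g.chrom not in by_chrom:
            continue
        pos, idx = by_chrom[g.chrom]
        lo = int(np.searchsorted(pos, g.start, side="left"))
        hi = int(np.searchsorted(pos, g.end, side="right"))
        if hi > lo:
            index.genes[g.gene_id] = idx[lo:hi].tolist()
            index.gene_models[g.gene_id] = g
    return index


def thin_snps(panel: GenotypePanel, spacing_bp: int = DEFAULT_SPACING_BP) -> list[int]:
    """Greedy left-to-right thinning to a minimum inter-SNP spacing.

    Per chromosome: keep the first SNP, then every SNP at least
    ``spacing_bp`` beyond the last kept one.
    """
    kept: list[int] = []
    last_chrom: str | None = None
    last_pos = None
    for j in range(panel.n_snps):
        c, p = panel.chrom[j], int(panel.pos[j])
        if c != last_chrom or p - last_pos >= spacing_bp:
            kept.append(j)
            last_chrom, last_pos = c, p
    return kept
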