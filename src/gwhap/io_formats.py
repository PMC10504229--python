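"""Readers and writers for the external formats: VCF, GFF3, trait CSV, result TSV.

Only biallelic single-nucleotide records are loaded from VCF; multiallelic
sites and indels are counted and skipped with a warning.  Phased and
unphased genotype separators are treated identically (the panels targeted
here are inbred and effectively homozygous).
"""

from __future__ import annotations

import logging
import os
from dataclasses import asdict, dataclass, fields

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import DataError
from .types import (
    ALT_HOM,
    AMINO_ACIDS,
    HET,
    MISSING,
    REF_HOM,
    VALID_BASES,
    GeneModel,
    GenotypePanel,
    TraitTable,
)

logger = logging.getLogger(__name__)

# cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
_GT_TYPE_MAP = {0: REF_HOM, 1: HET, 2: MISSING, 3: ALT_HOM}

_RESULT_COLUMNS = [
    "gene_id", "trait", "chrom", "n_haplotypes_tested", "n_accessions_used",
    "F", "df1", "df2", "p_value", "significant",
    "key_snp_id", "key_snp_pos", "key_snp_p", "key_snp_alleles",
]


def read_vcf(path: str, region_filter: list[tuple[str, int, int]] | None = None) -> GenotypePanel:
    """Read a VCF into a :class:`GenotypePanel`.

    Parameters
    ----------
    path:
        VCF file (plain or bgzipped) with GT fields.
    region_filter:
        Optional list of ``(chrom, start, end)`` 1-based inclusive intervals;
        records outside every interval are dropped.

    Raises
    ------
    DataError
        If the file is absent or no biallelic SNP records are parsed.
    """
    if not os.path.exists(path):
        raise DataError(f"VCF file not found: {path}")
    vcf = VCF(path, gts012=False)
    accession_ids = list(vcf.samples)

    snp_ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    call_rows: list[np.ndarray] = []
    n_skipped = 0
    n_seen = 0

    for var in vcf:
        n_seen += 1
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        ref, alt = var.REF.upper(), var.ALT[0].upper()
        if ref not in VALID_BASES or alt not in VALID_BASES:
            n_skipped += 1
            continue
        if region_filter is not None and not any(
            var.CHROM == c and s <= var.POS <= e for c, s, e in region_filter
        ):
            continue
        gt = np.array(
            [_GT_TYPE_MAP[int(t)] for t in var.gt_types], dtype=np.int8
        )
        snp_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        positions.append(var.POS)
        refs.append(ref)
        alts.append(alt)
        call_rows.append(gt)

    if n_skipped:
        logger.warning(
            "skipped %d non-biallelic-SNP record(s) of %d in %s",
            n_skipped, n_seen, path,
        )
    if not snp_ids:
        raise DataError(
            f"no biallelic SNPs parsed from {path} "
            f"({n_seen} records seen, {n_skipped} skipped)"
        )
    calls = np.stack(call_rows, axis=1)  # (n_acc, n_snp)
    return GenotypePanel(
        accession_ids=accession_ids,
        snp_ids=snp_ids,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        ref_allele=np.array(refs, dtype=object),
        alt_allele=np.array(alts, dtype=object),
        calls=calls,
    )


_CALL_TO_GT = {REF_HOM: "0/0", HET: "0/1", ALT_HOM: "1/1", MISSING: "./."}


def write_vcf(panel: GenotypePanel, path: str) -> None:
    """Write the panel as an uncompressed VCF 4.2 file."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gwhap\n")
        seen: list[str] = []
        for c in panel.chrom:
            if c not in seen:
                seen.append(c)
        for c in seen:
            max_pos = int(panel.pos[panel.chrom == c].max())
            fh.write(f"##contig=<ID={c},length={max_pos + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.accession_ids) + "\n"
        )
        for j in range(panel.n_snps):
            gts = "\t".join(_CALL_TO_GT[int(c)] for c in panel.calls[:, j])
            fh.write(
                f"{panel.chrom[j]}\t{panel.pos[j]}\t{panel.snp_ids[j]}\t"
                f"{panel.ref_allele[j]}\t{panel.alt_allele[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_gff3(path: str, feature_type: str = "gene") -> list[GeneModel]:
    """Parse GFF3 features of ``feature_type`` into :class:`GeneModel` records.

    Coordinates are kept 1-based inclusive as in the GFF3 standard; the
    ``ID`` attribute becomes ``gene_id``.
    """
    if not os.path.exists(path):
        raise DataError(f"GFF3 file not found: {path}")
    genes: list[GeneModel] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise DataError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, got {len(parts)}"
                )
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != feature_type:
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise DataError(f"{path}:{lineno}: non-integer coordinates") from None
            gene_id = None
            for item in attrs.split(";"):
                item = item.strip()
                if item.startswith("ID="):
                    gene_id = item[3:]
                    break
            if gene_id is None:
                raise DataError(f"{path}:{lineno}: feature lacks an ID attribute")
            if strand not in ("+", "-"):
                strand = "+"
            genes.append(GeneModel(gene_id, chrom, start_i, end_i, strand))
    return genes


def write_gff3(genes: list[GeneModel], path: str) -> None:
    """Write gene features as minimal GFF3."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tgwhap\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


def read_trait_table(path: str, units: str = "percent") -> TraitTable:
    """Read an accession x trait CSV (accession id in the first column).

    ``units='g_per_kg'`` divides all values by 10 so the table is stored in
    % (g/100 g).  Empty cells become missing values; the accession row is
    retained.
    """
    if units not in ("percent", "g_per_kg"):
        raise DataError(f"unknown units {units!r}")
    df = pd.read_csv(path, dtype={0: str})
    acc_col = df.columns[0]
    ids = df[acc_col].tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DataError(f"duplicate accession ids in {path}: {dupes}")
    trait_names = [c for c in df.columns[1:]]
    values = df[trait_names].to_numpy(dtype=np.float64)
    if units == "g_per_kg":
        values = values / 10.0
    return TraitTable(accession_ids=ids, trait_names=trait_names, values=values)


def write_trait_table(traits: TraitTable, path: str) -> None:
    df = pd.DataFrame(traits.values, columns=traits.trait_names)
    df.insert(0, "accession", traits.accession_ids)
    df.to_csv(path, index=False)


@dataclass
class ResultRecord:
    """One gene x trait association row joined with its key variant."""

    gene_id: str
    trait: str
    chrom: str
    n_haplotypes_tested: int
    n_accessions_used: int
    F: float
    df1: int
    df2: int
    p_value: float
    significant: bool
    key_snp_id: str = ""
    key_snp_pos: int = -1
    key_snp_p: float = float("nan")
    key_snp_alleles: str = ""


def write_results(records: list[ResultRecord], path: str) -> None:
    """Write association records as a TSV with the canonical column set."""
    rows = [asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_results(path: str) -> list[ResultRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"key_snp_id": str, "key_snp_alleles": str})
    records = []
    field_types = {f.name: f.type for f in fields(ResultRecord)}
    for _, row in df.iterrows():
        kwargs = {}
        for name in field_types:
            v = row[name]
            if name in ("key_snp_id", "key_snp_alleles") and (pd.isna(v) or v == "nan"):
                v = ""
            kwargs[name] = v
        kwargs["significant"] = bool(kwargs["significant"])
        kwargs["key_snp_pos"] = int(kwargs["key_snp_pos"])
        records.append(ResultRecord(**kwargs))
    return records
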