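"""Per-gene haplotype classes from gene-body SNP calls.

An accession's haplotype at a gene is the string of its alleles over the
gene's SNPs (ref base for a ref-homozygote, alt base for an alt-homozygote).
Any heterozygous or missing call at any gene SNP excludes the accession for
that gene: residual heterozygosity in an inbred panel is treated as noise,
and missing calls are never imputed into haplotype identities.

Classes are labelled Hap1, Hap2, ... in descending accession count, ties
broken by order of first occurrence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .types import ALT_HOM, REF_HOM, GeneSNPIndex, GenotypePanel

EXCLUDED: int = -1

DEFAULT_MIN_CLASS_COUNT = 5


@dataclass
class HaplotypeTable:
    gene_id: str
    class_defs: list[str]  # allele strings, ordered Hap1, Hap2, ...
    assignment: np.ndarray  # int per accession; class index or EXCLUDED
    class_counts: list[int]
    n_excluded: int
    accession_ids: list[str] = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return len(self.class_defs)

    @property
    def testable(self) -> bool:
        return self.n_classes >= 2

    def labels(self) -> list[str]:
        return [f"Hap{i + 1}" for i in range(self.n_classes)]


def build_gene_haplotypes(
    panel: GenotypePanel, index: GeneSNPIndex, gene_id: str
) -> HaplotypeTable:
    """Group accessions into haplotype classes for one gene."""
    cols = np.asarray(index.snp_indices(gene_id), dtype=np.int64)
    sub = panel.calls[:, cols]
    homozygous = (sub == REF_HOM) | (sub == ALT_HOM)
    usable = homozygous.all(axis=1)

    ref = np.array([panel.ref_allele[c] for c in cols], dtype=object)
    alt = np.array([panel.alt_allele[c] for c in cols], dtype=object)

    strings: dict[int, str] = {}
    for i in np.nonzero(usable)[0]:
        alleles = np.where(sub[i] == ALT_HOM, alt, ref)
        strings[int(i)] = "".join(alleles)

    counts = Counter(strings.values())
    first_seen: dict[str, int] = {}
    for i in sorted(strings):
        s = strings[i]
        if s not in first_seen:
            first_seen[s] = i
    ordered = sorted(counts, key=lambda s: (-counts[s], first_seen[s]))
    class_of = {s: k for k, s in enumerate(ordered)}

    assignment = np.full(panel.n_accessions, EXCLUDED, dtype=np.int64)
    for i, s in strings.items():
        assignment[i] = class_of[s]
    return HaplotypeTable(
        gene_id=gene_id,
        class_defs=ordered,
        assignment=assignment,
        class_counts=[counts[s] for s in ordered],
        n_excluded=int(panel.n_accessions - usable.sum()),
        accession_ids=list(panel.accession_ids),
    )


def collapse_rare_haplotypes(
    table: HaplotypeTable, min_count: int = DEFAULT_MIN_CLASS_COUNT
) -> HaplotypeTable:
    """Move classes with fewer than ``min_count`` members to EXCLUDED.

    Rare classes are dropped rather than pooled: a pooled pseudo-class has
    no shared allele string and would distort the class F-test.  If fewer
    than two classes survive, the gene is untestable
    (:attr:`HaplotypeTable.testable` is False).
    """
    keep = [k for k, c in enumerate(table.class_counts) if c >= min_count]
    remap = {old: new for new, old in enumerate(keep)}
    assignment = np.full_like(table.assignment, EXCLUDED)
    for old, new in remap.items():
        assignment[table.assignment == old] = new
    n_excluded = int((assignment == EXCLUDED).sum())
    return HaplotypeTable(
        gene_id=table.gene_id,
        class_defs=[table.class_defs[k] for k in keep],
        assignment=assignment,
        class_counts=[table.class_counts[k] for k in keep],
        n_excluded=n_excluded,
        accession_ids=list(table.accession_ids),
    )


@dataclass
class HaplotypeSummary:
    gene_counts: dict[str, int]  # gene_id -> H_g
    histogram: dict[int, int]  # H_g -> number of genes


def summarize_haplotypes(tables: list[HaplotypeTable]) -> HaplotypeSummary:
    """Histogram of per-gene haplotype counts (before rare-class collapse)."""
    if not tables:
        raise DataError("no haplotype tables to summarize")
    gene_counts = {t.gene_id: t.n_classes for t in tables}
    hist = Counter(gene_counts.values())
    return HaplotypeSummary(gene_counts=gene_counts, histogram=dict(sorted(hist.items())))


def export_haplotypes_tsv(table: HaplotypeTable, path: str) -> None:
    """Per-accession haplotype assignment TSV (accession, label, alleles)."""
    labels = table.labels()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("accession\thaplotype\talleles\n")
        for i, acc in enumerate(table.accession_ids):
            k = int(table.assignment[i])
            if k == EXCLUDED:
                fh.write(f"{acc}\tEXCLUDED\t.\n")
            else:
                fh.write(f"{acc}\t{labels[k]}\t{table.class_defs[k]}\n")
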