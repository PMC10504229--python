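"""Shared domain types: genotype panel, gene models and trait tables.

Genotype calls are stored as a compact ``int8`` matrix (accessions x SNPs)
using the codes below.  The coding is chosen so that for fully called sites
the call code *is* the alt-allele dosage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

# call codes (int8); REF_HOM/HET/ALT_HOM double as alt-allele dosage
REF_HOM: int = 0
HET: int = 1
ALT_HOM: int = 2
MISSING: int = -1

VALID_CALLS = frozenset({REF_HOM, HET, ALT_HOM, MISSING})
VALID_BASES = frozenset("ACGT")

#: the 17 amino-acid trait names, in canonical column order
AMINO_ACIDS: tuple[str, ...] = (
    "Asp", "Thr", "Ser", "Glu", "Gly", "Ala", "Cys", "Val", "Met",
    "Ile", "Leu", "Tyr", "Phe", "Lys", "His", "Arg", "Pro",
)


@dataclass
class GenotypePanel:
    """Accessions x SNPs call matrix with per-SNP metadata.

    SNPs must appear in contiguous per-chromosome blocks with strictly
    increasing positions inside each block, and (chrom, pos) pairs must be
    unique.  Alleles are single upper-case bases.
    """

    accession_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray  # dtype=object/str, length n_snps
    pos: np.ndarray  # int64, 1-based
    ref_allele: np.ndarray  # single chars
    alt_allele: np.ndarray
    calls: np.ndarray  # int8, (n_accessions, n_snps)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.validate()

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def validate(self) -> None:
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise DataError("duplicate accession ids in panel")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise DataError("duplicate SNP ids in panel")
        n_acc, n_snp = len(self.accession_ids), len(self.snp_ids)
        if self.calls.shape != (n_acc, n_snp):
            raise DataError(
                f"calls shape {self.calls.shape} != ({n_acc}, {n_snp})"
            )
        for arr, name in (
            (self.chrom, "chrom"),
            (self.pos, "pos"),
            (self.ref_allele, "ref_allele"),
            (self.alt_allele, "alt_allele"),
        ):
            if len(arr) != n_snp:
                raise DataError(f"{name} length {len(arr)} != n_snps {n_snp}")
        bad = set(np.unique(self.calls)) - VALID_CALLS
        if bad:
            raise DataError(f"invalid call codes: {sorted(bad)}")
        for alleles in (self.ref_allele, self.alt_allele):
            for a in alleles:
                if a not in VALID_BASES:
                    raise DataError(f"invalid allele {a!r}; expected one of ACGT")
        # contiguous chromosome blocks, strictly increasing pos within block,
        # no duplicate (chrom, pos)
        seen_chroms: set[str] = set()
        prev_chrom: str | None = None
        prev_pos = -1
        for c, p in zip(self.chrom, self.pos):
            if c != prev_chrom:
                if c in seen_chroms:
                    raise DataError(f"chromosome {c} appears in two blocks")
                seen_chroms.add(c)
                prev_chrom = c
                prev_pos = -1
            if p <= prev_pos:
                raise DataError(
                    f"positions not strictly increasing on {c}: {prev_pos} -> {p}"
                )
            prev_pos = p

    def subset_snps(self, indices: np.ndarray | list[int]) -> "GenotypePanel":
        """New panel restricted to the given SNP indices (order preserved)."""
        idx = np.asarray(indices, dtype=np.int64)
        return GenotypePanel(
            accession_ids=list(self.accession_ids),
            snp_ids=[self.snp_ids[i] for i in idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref_allele=self.ref_allele[idx],
            alt_allele=self.alt_allele[idx],
            calls=self.calls[:, idx],
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene interval (1-based, inclusive on both ends)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise DataError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class TraitTable:
    """Accession x trait value matrix; NaN marks missing observations."""

    accession_ids: list[str]
    trait_names: list[str]
    values: np.ndarray  # float64, (n_accessions, n_traits)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise DataError("duplicate accession ids in trait table")
        if len(set(self.trait_names)) != len(self.trait_names):
            raise DataError("duplicate trait names")
        shape = (len(self.accession_ids), len(self.trait_names))
        if self.values.shape != shape:
            raise DataError(f"trait values shape {self.values.shape} != {shape}")
        with np.errstate(invalid="ignore"):
            if np.any(self.values[~np.isnan(self.values)] < 0):
                raise DataError("trait values must be non-negative")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    def column(self, trait: str) -> np.ndarray:
        """Values for one trait, aligned to ``accession_ids``."""
        try:
            j = self.trait_names.index(trait)
        except ValueError:
            raise DataError(f"unknown trait {trait!r}") from None
        return self.values[:, j]


@dataclass
class GeneSNPIndex:
    """Mapping gene_id -> ordered panel SNP indices inside the gene body."""

    genes: dict[str, list[int]] = field(default_factory=dict)
    gene_models: dict[str, GeneModel] = field(default_factory=dict)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __len__(self) -> int:
        return len(self.genes)

    def snp_indices(self, gene_id: str) -> list[int]:
        if gene_id not in self.genes:
            raise DataError(f"gene {gene_id!r} not present in SNP index")
        return self.genes[gene_id]
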