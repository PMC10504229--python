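"""Synthetic inbred panels with planted population structure and
haplotype-driven trait effects.

Generation is inbred-first: homozygous pristine genotypes are drawn first,
then heterozygous and missing corruptions are overlaid.  Two modes exist:
the default *founder* mode plants a small number of founder haplotypes per
gene (so gene-body SNPs are in strong LD and per-gene class counts are
small), while *independent* mode (``haplotypes_per_gene=None``) draws every
SNP independently so emitted minor-allele frequencies follow the
configured spectrum.  Structure comes from subpopulation divergence of
founder weights (founder mode) or per-SNP allele frequencies (independent
mode).  Trait values are the
sum of planted causal-gene class effects (scaled to a target explained
variance), a per-subpopulation shift, and Gaussian noise, on top of a
positive baseline.

Everything is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ConfigError, DataError
from .types import (
    ALT_HOM,
    AMINO_ACIDS,
    HET,
    MISSING,
    REF_HOM,
    GeneModel,
    GenotypePanel,
    TraitTable,
)
from . import io_formats

_BASES = np.array(list("ACGT"))

_SNP_STEP = 10  # bp between SNPs inside a gene
_GENE_GAP = 1_000  # bp between consecutive genes


@dataclass
class CausalGene:
    """A planted (gene, trait) effect.

    ``effects`` gives one additive value per true haplotype class; when
    None, effects are drawn standard normal.  ``fraction_variance_explained``
    is the target share of total trait variance for this gene.
    """

    gene_index: int
    trait: str
    fraction_variance_explained: float
    effects: list[float] | None = None


def _distinct_founders(rng, H: int, p: np.ndarray) -> np.ndarray:
    """H distinct founder allele rows over SNP alt-frequencies ``p``."""
    s = len(p)
    H = min(H, 2 ** min(s, 30))
    for _ in range(50):
        mat = (rng.random((H, s)) < p).astype(np.int8)
        if len({tuple(r) for r in mat}) == H:
            return mat
    # deterministic fallback: flip a random bit in duplicated rows
    seen: set[tuple] = set()
    for f in range(H):
        while tuple(mat[f]) in seen:
            mat[f, rng.integers(0, s)] ^= 1
        seen.add(tuple(mat[f]))
    return mat


@dataclass
class SimulationConfig:
    seed: int
    n_accessions: int = 164
    n_subpops: int = 2
    subpop_sizes: list[int] | None = None
    divergence: float = 0.5
    n_genes: int = 50
    n_chromosomes: int = 2
    snps_per_gene: tuple[int, int] = (1, 60)
    maf_low: float = 0.05
    maf_high: float = 0.5
    missing_rate: float = 0.0
    het_rate: float = 0.0
    haplotypes_per_gene: tuple[int, int] | None = (2, 8)
    founder_alpha: float = 1.0  # Dirichlet concentration of founder weights
    causal_genes: list[CausalGene] = field(default_factory=list)
    structure_effect: float = 0.0  # trait shift added to subpop 2
    noise_sd: float = 1.0
    baseline: float = 10.0
    trait_names: list[str] = field(default_factory=lambda: list(AMINO_ACIDS))

    def __post_init__(self) -> None:
        if self.subpop_sizes is None:
            base = self.n_accessions // self.n_subpops
            sizes = [base] * self.n_subpops
            sizes[0] += self.n_accessions - base * self.n_subpops
            self.subpop_sizes = sizes
        if sum(self.subpop_sizes) != self.n_accessions:
            raise ConfigError(
                f"subpop_sizes {self.subpop_sizes} do not sum to "
                f"n_accessions {self.n_accessions}"
            )
        if not (0.0 <= self.divergence <= 1.0):
            raise ConfigError("divergence must be in [0, 1]")
        lo, hi = self.snps_per_gene
        if lo < 1 or hi < lo:
            raise ConfigError(f"invalid snps_per_gene range {self.snps_per_gene}")
        if self.haplotypes_per_gene is not None:
            hlo, hhi = self.haplotypes_per_gene
            if hlo < 2 or hhi < hlo:
                raise ConfigError(
                    f"invalid haplotypes_per_gene range {self.haplotypes_per_gene}"
                )
        for c in self.causal_genes:
            if not (0.0 <= c.fraction_variance_explained < 1.0):
                raise ConfigError("fraction_variance_explained must be in [0, 1)")
            if c.gene_index >= self.n_genes:
                raise ConfigError(f"causal gene_index {c.gene_index} out of range")
            if c.trait not in self.trait_names:
                raise ConfigError(f"causal trait {c.trait!r} not in trait_names")


@dataclass
class SimulationTruth:
    subpop_labels: np.ndarray  # 1-based, per accession
    gene_classes: dict[str, np.ndarray]  # pristine class assignment per gene
    gene_n_classes: dict[str, int]
    causal_registry: list[dict] = field(default_factory=list)


def simulate_panel(
    config: SimulationConfig,
) -> tuple[GenotypePanel, list[GeneModel], SimulationTruth]:
    """Generate a structured inbred panel and its gene annotation."""
    rng = np.random.default_rng(config.seed)
    n_acc = config.n_accessions

    subpop = np.repeat(
        np.arange(1, config.n_subpops + 1), config.subpop_sizes
    )

    # gene layout: genes tile chromosomes round-robin with fixed gaps
    lo, hi = config.snps_per_gene
    snps_per_gene = rng.integers(lo, hi + 1, size=config.n_genes)
    genes: list[GeneModel] = []
    chrom_cursor = {f"chr{c + 1:02d}": 1_000 for c in range(config.n_chromosomes)}
    chrom_names = sorted(chrom_cursor)
    chroms_all: list[str] = []
    pos_all: list[int] = []
    gene_cols: list[np.ndarray] = []
    col = 0
    for g in range(config.n_genes):
        chrom = chrom_names[g % config.n_chromosomes]
        s = int(snps_per_gene[g])
        start = chrom_cursor[chrom]
        positions = start + np.arange(s) * _SNP_STEP
        end = int(positions[-1]) + _SNP_STEP - 1
        chrom_cursor[chrom] = end + _GENE_GAP
        genes.append(GeneModel(f"GENE{g + 1:04d}", chrom, start, end, "+"))
        chroms_all.extend([chrom] * s)
        pos_all.extend(int(p) for p in positions)
        gene_cols.append(np.arange(col, col + s))
        col += s
    # panel invariant requires contiguous chromosome blocks: sort by (chrom, pos)
    order = np.lexsort((np.array(pos_all), np.array(chroms_all, dtype=object)))
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    n_snp = len(pos_all)

    if config.haplotypes_per_gene is None:
        # independent mode: per-SNP subpopulation allele frequencies (no LD);
        # emitted MAFs follow the configured spectrum exactly in expectation
        p_anc = rng.uniform(config.maf_low, config.maf_high, size=n_snp)
        freqs = np.tile(p_anc, (config.n_subpops, 1))
        diverged = rng.random(n_snp) < config.divergence
        for s in range(config.n_subpops):
            indep = rng.uniform(config.maf_low, config.maf_high, size=n_snp)
            freqs[s, diverged] = indep[diverged]
        per_acc_freq = freqs[subpop - 1]  # (n_acc, n_snp)
        alt = rng.random((n_acc, n_snp)) < per_acc_freq
        pristine = np.where(alt, ALT_HOM, REF_HOM).astype(np.int8)
    else:
        # founder mode (default): each gene carries a few founder haplotypes
        # so gene-body SNPs are in strong LD and class counts stay small;
        # structure enters through subpopulation founder-frequency divergence
        hlo, hhi = config.haplotypes_per_gene
        pristine = np.empty((n_acc, n_snp), dtype=np.int8)
        for g in range(config.n_genes):
            cols = gene_cols[g]
            s = len(cols)
            H = int(rng.integers(hlo, hhi + 1))
            p = rng.uniform(config.maf_low, config.maf_high, size=s)
            founders = _distinct_founders(rng, H, p)
            H = founders.shape[0]
            w = rng.dirichlet(np.full(H, config.founder_alpha), size=config.n_subpops)
            if rng.random() >= config.divergence:
                w[:] = w[0]  # undiverged gene: same weights in every subpop
            founder_idx = np.empty(n_acc, dtype=np.int64)
            for sp in range(config.n_subpops):
                members = np.nonzero(subpop == sp + 1)[0]
                founder_idx[members] = rng.choice(H, size=len(members), p=w[sp])
            pristine[:, cols] = founders[founder_idx] * ALT_HOM

    calls = pristine.copy()
    if config.het_rate > 0:
        calls[rng.random(calls.shape) < config.het_rate] = HET
    if config.missing_rate > 0:
        calls[rng.random(calls.shape) < config.missing_rate] = MISSING

    ref_idx = rng.integers(0, 4, size=n_snp)
    alt_shift = rng.integers(1, 4, size=n_snp)
    ref_allele = _BASES[ref_idx]
    alt_allele = _BASES[(ref_idx + alt_shift) % 4]

    chrom_sorted = np.array(chroms_all, dtype=object)[order]
    pos_sorted = np.array(pos_all, dtype=np.int64)[order]
    panel = GenotypePanel(
        accession_ids=[f"ACC{i + 1:04d}" for i in range(n_acc)],
        snp_ids=[f"{c}_{p}" for c, p in zip(chrom_sorted, pos_sorted)],
        chrom=chrom_sorted,
        pos=pos_sorted,
        ref_allele=ref_allele[order].astype(object),
        alt_allele=alt_allele[order].astype(object),
        calls=calls[:, order],
    )

    # pristine haplotype classes per gene (classes ordered by descending count)
    gene_classes: dict[str, np.ndarray] = {}
    gene_n_classes: dict[str, int] = {}
    for g, gene in enumerate(genes):
        sub = pristine[:, gene_cols[g]]
        _uniq, first, inverse, counts = np.unique(
            sub, axis=0, return_index=True, return_inverse=True, return_counts=True
        )
        rank = sorted(range(len(counts)), key=lambda k: (-counts[k], first[k]))
        remap = np.empty(len(counts), dtype=np.int64)
        for newk, oldk in enumerate(rank):
            remap[oldk] = newk
        gene_classes[gene.gene_id] = remap[inverse]
        gene_n_classes[gene.gene_id] = len(counts)

    truth = SimulationTruth(
        subpop_labels=subpop.astype(np.int64),
        gene_classes=gene_classes,
        gene_n_classes=gene_n_classes,
    )
    return panel, genes, truth


def simulate_traits(
    panel: GenotypePanel,
    truth: SimulationTruth,
    config: SimulationConfig,
    genes: list[GeneModel] | None = None,
) -> TraitTable:
    """Trait table with planted class effects, structure shift and noise.

    Causal effects are rescaled so the realized explained-variance fraction
    matches the target against the structure + noise background; realized
    fractions are appended to ``truth.causal_registry``.
    """
    rng = np.random.default_rng([config.seed, 7919])
    n_acc = panel.n_accessions
    n_traits = len(config.trait_names)
    noise = rng.normal(0.0, config.noise_sd, size=(n_acc, n_traits))
    shift = np.where(truth.subpop_labels == 2, config.structure_effect, 0.0)
    values = config.baseline + noise + shift[:, None]

    truth.causal_registry = []
    for causal in config.causal_genes:
        gene_id = f"GENE{causal.gene_index + 1:04d}"
        classes = truth.gene_classes[gene_id]
        n_classes = truth.gene_n_classes[gene_id]
        if n_classes < 2:
            raise DataError(
                f"causal gene {gene_id} realized only {n_classes} haplotype class; "
                "regenerate with a different seed"
            )
        t = config.trait_names.index(causal.trait)
        if causal.effects is not None:
            if len(causal.effects) != n_classes:
                raise ConfigError(
                    f"{gene_id}: {len(causal.effects)} effects for {n_classes} classes"
                )
            eff = np.asarray(causal.effects, dtype=np.float64)
        else:
            eff = rng.normal(0.0, 1.0, size=n_classes)
        g = eff[classes]
        g = g - g.mean()
        var_g = float(g.var())
        fve = causal.fraction_variance_explained
        if var_g <= 0 or fve <= 0:
            scaled = np.zeros(n_acc)
            realized = 0.0
        else:
            background = values[:, t] - values[:, t].mean()
            var_bg = float(background.var())
            if var_bg > 0:
                # solve var(a g) = fve * var(a g + background) for a,
                # accounting for cov(g, background) (classes correlate with
                # the subpopulation shift under divergence)
                cov = float(np.mean(g * background))
                disc = fve * fve * cov * cov + var_g * var_bg * fve * (1.0 - fve)
                a = (fve * cov + np.sqrt(disc)) / (var_g * (1.0 - fve))
            else:
                a = 1.0  # noiseless limit: trait is an exact class function
            scaled = a * g
            values[:, t] = values[:, t] + scaled
            realized = float(scaled.var() / values[:, t].var())
        truth.causal_registry.append(
            {
                "gene_id": gene_id,
                "trait": causal.trait,
                "target_fve": fve,
                "realized_fve": realized,
                "n_classes": n_classes,
            }
        )

    # traits are contents: shift columns so every value is non-negative
    col_min = values.min(axis=0)
    neg = col_min < 0
    values[:, neg] -= col_min[neg] - 0.01

    return TraitTable(
        accession_ids=list(panel.accession_ids),
        trait_names=list(config.trait_names),
        values=values,
    )


def _config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["snps_per_gene"] = list(d["snps_per_gene"])
    if d["haplotypes_per_gene"] is not None:
        d["haplotypes_per_gene"] = list(d["haplotypes_per_gene"])
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "snps_per_gene" in d:
        d["snps_per_gene"] = tuple(d["snps_per_gene"])
    if d.get("haplotypes_per_gene") is not None:
        d["haplotypes_per_gene"] = tuple(d["haplotypes_per_gene"])
    causal = [
        c if isinstance(c, CausalGene) else CausalGene(**c)
        for c in d.get("causal_genes", [])
    ]
    d["causal_genes"] = causal
    return SimulationConfig(**d)


def write_fixture_bundle(outdir: str, config: SimulationConfig) -> dict[str, str]:
    """Simulate and write panel.vcf / genes.gff3 / traits.csv / truth.json /
    config.yaml under ``outdir``; returns the path mapping."""
    os.makedirs(outdir, exist_ok=True)
    panel, genes, truth = simulate_panel(config)
    traits = simulate_traits(panel, truth, config)
    paths = {
        "vcf": os.path.join(outdir, "panel.vcf"),
        "gff3": os.path.join(outdir, "genes.gff3"),
        "traits": os.path.join(outdir, "traits.csv"),
        "truth": os.path.join(outdir, "truth.json"),
        "config": os.path.join(outdir, "config.yaml"),
    }
    io_formats.write_vcf(panel, paths["vcf"])
    io_formats.write_gff3(genes, paths["gff3"])
    io_formats.write_trait_table(traits, paths["traits"])
    truth_doc = {
        "subpop_labels": truth.subpop_labels.tolist(),
        "gene_n_classes": truth.gene_n_classes,
        "gene_classes": {g: v.tolist() for g, v in truth.gene_classes.items()},
        "causal_registry": truth.causal_registry,
    }
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(truth_doc, fh, indent=1, sort_keys=True)
    with open(paths["config"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=True)
    return paths
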