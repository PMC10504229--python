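"""Gene-level haplotype association testing with PC covariates.

The gene test is an ordinary-least-squares F-test: trait regressed on
[intercept, Q principal components, n_classes - 1 haplotype indicators]
against the PCs-only reduced model,

    F = ((RSS0 - RSS1) / df1) / (RSS1 / df2),

with df1 = n_classes - 1 and df2 = n_used - n_classes - Q.  A gene x trait
pair is significant when p < alpha (default 1e-4).  Within each significant
gene a per-SNP dosage regression with the same PC correction nominates the
lowest-p SNP as the key natural variant (ties broken by smaller position).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DataError
from .haplotype_core import EXCLUDED, HaplotypeTable
from .popstructure import StructureResult
from .types import MISSING, GeneSNPIndex, GenotypePanel, TraitTable

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 1.0e-4

# median of the chi-square distribution with 1 df
_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


@dataclass
class ScanConfig:
    alpha: float = DEFAULT_ALPHA
    Q: int = 2
    min_class_count: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise DataError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.Q < 0:
            raise DataError("Q must be non-negative")


@dataclass
class GeneAssociationResult:
    gene_id: str
    trait: str
    chrom: str
    n_classes_tested: int
    n_used: int
    F: float
    df1: int
    df2: int
    p_value: float
    significant: bool
    class_means: list[float] = field(default_factory=list)
    degenerate: bool = False
    collinear: bool = False
    testable: bool = True
    gene_start: int = -1
    gene_mid: float = float("nan")


@dataclass
class SNPAssociationResult:
    snp_id: str
    gene_id: str
    trait: str
    chrom: str
    pos: int
    beta: float
    p_value: float
    is_key_variant: bool = False


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and design rank via least squares."""
    beta, _res, rank, _sv = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def fit_haplotype_model(
    trait_values: np.ndarray,
    haplotype_table: HaplotypeTable,
    pc_coords: np.ndarray | None,
    Q: int,
    alpha: float = DEFAULT_ALPHA,
) -> GeneAssociationResult:
    """F-test of haplotype class membership against a PCs-only null.

    ``trait_values`` and ``pc_coords`` rows must align with
    ``haplotype_table.accession_ids``.  Accessions used in the model are
    those with a haplotype class assignment and a non-missing trait value.
    """
    y_all = np.asarray(trait_values, dtype=np.float64)
    n_acc = len(haplotype_table.accession_ids)
    if y_all.shape[0] != n_acc:
        raise DataError("trait vector not aligned with haplotype table")
    if Q > 0:
        if pc_coords is None or pc_coords.shape[0] != n_acc:
            raise DataError("PC coordinates not aligned with haplotype table")

    assignment = haplotype_table.assignment
    used = (assignment != EXCLUDED) & ~np.isnan(y_all)
    y = y_all[used]
    classes = assignment[used]
    present = np.unique(classes)
    k = len(present)
    n = int(used.sum())

    base = GeneAssociationResult(
        gene_id=haplotype_table.gene_id,
        trait="",
        chrom="",
        n_classes_tested=k,
        n_used=n,
        F=float("nan"),
        df1=max(k - 1, 0),
        df2=n - k - Q,
        p_value=float("nan"),
        significant=False,
    )
    if k < 2:
        base.testable = False
        return base
    df1 = k - 1
    df2 = n - k - Q
    if df2 < 1:
        base.testable = False
        return base

    remap = {c: i for i, c in enumerate(present)}
    cls = np.array([remap[c] for c in classes])
    X0 = np.ones((n, 1 + Q))
    if Q > 0:
        X0[:, 1:] = pc_coords[used, :Q]
    ind = np.zeros((n, k - 1))
    for j in range(1, k):  # reference level: most frequent retained class
        ind[cls == j, j - 1] = 1.0
    X1 = np.hstack([X0, ind])

    rss0, rank0 = _ols_rss(X0, y)
    rss1, rank1 = _ols_rss(X1, y)
    eff_df1 = rank1 - rank0
    if eff_df1 < df1:
        base.collinear = True
        if eff_df1 < 1:
            base.testable = False
            return base
        df1 = eff_df1
        df2 = n - rank1
        base.df1, base.df2 = df1, df2
        if df2 < 1:
            base.testable = False
            return base

    # class means on the raw trait scale, ordered by retained class index
    base.class_means = [float(y[cls == j].mean()) for j in range(k)]

    scale = float(y @ y) if n else 0.0
    tiny = max(scale, 1.0) * 1e-12
    if rss0 <= tiny and rss1 <= tiny:
        # constant trait: nothing to test
        base.degenerate = True
        return base
    if rss1 <= tiny:
        # perfect class fit: p is 0-adjacent
        base.degenerate = True
        base.F = float("inf")
        base.p_value = np.nextafter(0.0, 1.0)
        base.significant = base.p_value < alpha
        return base

    F = ((rss0 - rss1) / df1) / (rss1 / df2)
    p = float(stats.f.sf(F, df1, df2))
    base.F = float(F)
    base.p_value = p
    base.significant = p < alpha
    return base


def run_gwha_scan(
    panel: GenotypePanel,
    gene_snp_index: GeneSNPIndex,
    haplotype_tables: dict[str, HaplotypeTable],
    traits: TraitTable,
    structure: StructureResult | None,
    config: ScanConfig,
) -> list[GeneAssociationResult]:
    """One association record per testable gene x trait.

    Records are ordered by (chrom, gene start, trait column order).
    Accession alignment between panel, traits and PCs is by accession id.
    """
    acc_index = {a: i for i, a in enumerate(panel.accession_ids)}
    trait_rows = [acc_index.get(a, -1) for a in traits.accession_ids]

    # trait vectors re-aligned to panel accession order
    aligned = np.full((panel.n_accessions, len(traits.trait_names)), np.nan)
    for r, pi in enumerate(trait_rows):
        if pi >= 0:
            aligned[pi] = traits.values[r]

    pc = None
    if config.Q > 0:
        if structure is None:
            raise DataError("Q > 0 requires a StructureResult")
        if structure.accession_ids != panel.accession_ids:
            s_index = {a: i for i, a in enumerate(structure.accession_ids)}
            try:
                rows = [s_index[a] for a in panel.accession_ids]
            except KeyError as e:
                raise DataError(f"accession {e} missing from structure result") from None
            pc = structure.pc_coords[rows]
        else:
            pc = structure.pc_coords
        if pc.shape[1] < config.Q:
            raise DataError(
                f"structure has {pc.shape[1]} PCs but Q={config.Q} requested"
            )

    ordered_genes = sorted(
        haplotype_tables,
        key=lambda g: (
            gene_snp_index.gene_models[g].chrom,
            gene_snp_index.gene_models[g].start,
            g,
        ),
    )
    results: list[GeneAssociationResult] = []
    for gene_id in ordered_genes:
        table = haplotype_tables[gene_id]
        if not table.testable:
            continue
        model = gene_snp_index.gene_models[gene_id]
        for t, trait in enumerate(traits.trait_names):
            rec = fit_haplotype_model(aligned[:, t], table, pc, config.Q, config.alpha)
            rec.trait = trait
            rec.chrom = model.chrom
            rec.gene_start = model.start
            rec.gene_mid = model.midpoint
            if rec.testable:
                results.append(rec)
    if not results:
        raise DataError(
            f"no testable gene x trait combinations "
            f"({len(haplotype_tables)} genes, {len(traits.trait_names)} traits)"
        )
    return results


def genomic_inflation(p_values: np.ndarray | list[float]) -> float | None:
    """Median-based genomic inflation factor lambda_GC.

    lambda = median(chi2_1 quantile of the p-values) / 0.4549...; returns
    None (with a warning) when fewer than 20 p-values are supplied.
    """
    p = np.asarray([v for v in p_values if np.isfinite(v)], dtype=np.float64)
    if p.size < 20:
        logger.warning("genomic_inflation: only %d p-values (< 20); no lambda", p.size)
        return None
    chi2_obs = stats.chi2.isf(p, df=1)
    return float(np.median(chi2_obs) / _CHI2_1_MEDIAN)


def run_snp_scan(
    panel: GenotypePanel,
    gene_snp_index: GeneSNPIndex,
    traits: TraitTable,
    structure: StructureResult | None,
    config: ScanConfig,
    gene_traits: list[tuple[str, str]],
) -> list[SNPAssociationResult]:
    """Per-SNP dosage regression within the listed (gene, trait) pairs.

    Model per SNP: OLS of trait on [intercept, Q PCs, dosage]; two-sided
    t-test p for the dosage coefficient.  SNPs monomorphic within the used
    accessions are skipped.
    """
    acc_index = {a: i for i, a in enumerate(panel.accession_ids)}
    aligned = np.full((panel.n_accessions, len(traits.trait_names)), np.nan)
    for r, a in enumerate(traits.accession_ids):
        pi = acc_index.get(a, -1)
        if pi >= 0:
            aligned[pi] = traits.values[r]

    pc = None
    if config.Q > 0:
        if structure is None:
            raise DataError("Q > 0 requires a StructureResult")
        s_index = {a: i for i, a in enumerate(structure.accession_ids)}
        rows = [s_index[a] for a in panel.accession_ids]
        pc = structure.pc_coords[rows]

    results: list[SNPAssociationResult] = []
    for gene_id, trait in gene_traits:
        snp_idx = gene_snp_index.snp_indices(gene_id)
        t = traits.trait_names.index(trait)
        y_all = aligned[:, t]
        used = ~np.isnan(y_all)
        y = y_all[used]
        n = int(used.sum())
        n_params = 2 + config.Q
        if n <= n_params:
            continue
        X = np.ones((n, n_params))
        if config.Q > 0:
            X[:, 1:-1] = pc[used, : config.Q]
        for j in snp_idx:
            d = panel.calls[used, j].astype(np.float64)
            miss = d == MISSING
            if miss.all():
                continue
            if miss.any():
                d[miss] = d[~miss].mean()
            if np.ptp(d) == 0.0:
                continue  # monomorphic within used accessions
            X[:, -1] = d
            beta, _res, rank, _sv = np.linalg.lstsq(X, y, rcond=None)
            if rank < n_params:
                continue  # dosage collinear with covariates
            resid = y - X @ beta
            dof = n - n_params
            sigma2 = float(resid @ resid) / dof
            xtx_inv = np.linalg.inv(X.T @ X)
            se = float(np.sqrt(max(sigma2 * xtx_inv[-1, -1], 0.0)))
            if se == 0.0:
                p = np.nextafter(0.0, 1.0)
            else:
                tstat = beta[-1] / se
                p = float(2.0 * stats.t.sf(abs(tstat), dof))
            results.append(
                SNPAssociationResult(
                    snp_id=panel.snp_ids[j],
                    gene_id=gene_id,
                    trait=trait,
                    chrom=str(panel.chrom[j]),
                    pos=int(panel.pos[j]),
                    beta=float(beta[-1]),
                    p_value=p,
                )
            )
    return results


def key_variant_per_gene(
    snp_results: list[SNPAssociationResult], gene_id: str, trait: str
) -> SNPAssociationResult:
    """Flag and return the lowest-p SNP for one gene x trait.

    Ties are broken by smaller genomic position.
    """
    candidates = [r for r in snp_results if r.gene_id == gene_id and r.trait == trait]
    if not candidates:
        raise DataError(f"no scored SNPs for gene {gene_id!r}, trait {trait!r}")
    best = min(candidates, key=lambda r: (r.p_value, r.pos))
    best.is_key_variant = True
    return best


def export_manhattan_qq(
    results: list[GeneAssociationResult], path_prefix: str
) -> tuple[str, str]:
    """Write Manhattan and QQ plot data TSVs; returns the two paths.

    Manhattan rows: (chrom, position = gene midpoint, -log10 p, trait).
    QQ rows per trait: expected -log10((i - 0.5)/n) against observed
    -log10 p, both for ascending p.
    """
    if not results:
        raise DataError("no results to export")
    man_path = f"{path_prefix}.manhattan.tsv"
    qq_path = f"{path_prefix}.qq.tsv"
    with open(man_path, "w", encoding="utf-8") as fh:
        fh.write("chrom\tposition\tneg_log10_p\ttrait\n")
        for r in results:
            nlp = -np.log10(r.p_value) if r.p_value > 0 else np.inf
            fh.write(f"{r.chrom}\t{r.gene_mid:.10g}\t{nlp:.10g}\t{r.trait}\n")
    with open(qq_path, "w", encoding="utf-8") as fh:
        fh.write("trait\texpected\tobserved\n")
        traits = []
        for r in results:
            if r.trait not in traits:
                traits.append(r.trait)
        for trait in traits:
            p = np.sort(
                [r.p_value for r in results if r.trait == trait and np.isfinite(r.p_value)]
            )
            n = len(p)
            for i, pv in enumerate(p, start=1):
                exp = -np.log10((i - 0.5) / n)
                obs = -np.log10(pv) if pv > 0 else np.inf
                fh.write(f"{trait}\t{exp:.10g}\t{obs:.10g}\n")
    return man_path, qq_path
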