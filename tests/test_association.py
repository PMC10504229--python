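import numpy as np
import pytest
from scipy import stats

from gwhap.association import (
    ScanConfig,
    export_manhattan_qq,
    fit_haplotype_model,
    genomic_inflation,
    key_variant_per_gene,
    run_gwha_scan,
    run_snp_scan,
    SNPAssociationResult,
)
from gwhap.errors import DataError
from gwhap.haplotype_core import (
    EXCLUDED,
    HaplotypeTable,
    build_gene_haplotypes,
    collapse_rare_haplotypes,
)
from gwhap.popstructure import StructureResult, dosage_matrix, pca_structure
from gwhap.qc_filter import assign_snps_to_genes
from gwhap.synthetic_data import CausalGene, SimulationConfig, simulate_panel, simulate_traits
from gwhap.types import TraitTable


def make_hap_table(assignment, n_classes, gene_id="G1"):
    assignment = np.asarray(assignment)
    counts = [int((assignment == k).sum()) for k in range(n_classes)]
    return HaplotypeTable(
        gene_id=gene_id,
        class_defs=["A" * (k + 1) for k in range(n_classes)],
        assignment=assignment,
        class_counts=counts,
        n_excluded=int((assignment == EXCLUDED).sum()),
        accession_ids=[f"A{i}" for i in range(len(assignment))],
    )


def oracle_f_test(y, X_full, X_reduced):
    """Explicit normal-equations RSS computation (independent route)."""
    def rss(X):
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        return float(r @ r)

    rss0, rss1 = rss(X_reduced), rss(X_full)
    df1 = X_full.shape[1] - X_reduced.shape[1]
    df2 = X_full.shape[0] - X_full.shape[1]
    F = ((rss0 - rss1) / df1) / (rss1 / df2)
    return F, df1, df2, float(stats.f.sf(F, df1, df2))


class TestFitHaplotypeModel:
    def test_two_class_equals_t_test_squared(self, rng):
        y = np.concatenate([rng.normal(0, 1, 6), rng.normal(1, 1, 6)])
        table = make_hap_table([0] * 6 + [1] * 6, 2)
        rec = fit_haplotype_model(y, table, None, Q=0)
        t, p = stats.ttest_ind(y[:6], y[6:], equal_var=True)
        assert rec.F == pytest.approx(t**2, rel=1e-10)
        assert rec.p_value == pytest.approx(p, rel=1e-10)
        assert rec.df1 == 1 and rec.df2 == 10

    def test_matches_normal_equations_oracle(self, rng):
        n, k, Q = 40, 3, 2
        assignment = rng.integers(0, k, size=n)
        y = rng.normal(0, 1, n)
        pcs = rng.normal(0, 1, (n, Q))
        table = make_hap_table(assignment, k)
        rec = fit_haplotype_model(y, table, pcs, Q=Q)
        X0 = np.column_stack([np.ones(n), pcs])
        ind = np.zeros((n, k - 1))
        for j in range(1, k):
            ind[assignment == j, j - 1] = 1.0
        F, df1, df2, p = oracle_f_test(y, np.hstack([X0, ind]), X0)
        assert rec.F == pytest.approx(F, rel=1e-10)
        assert (rec.df1, rec.df2) == (df1, df2)
        assert rec.p_value == pytest.approx(p, rel=1e-10)

    def test_100_random_instances_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(15, 61))
            k = int(rng.integers(2, 6))
            Q = int(rng.integers(0, 4))
            assignment = rng.integers(0, k, size=n)
            # guarantee every class occupied
            assignment[:k] = np.arange(k)
            y = rng.normal(0, 1, n)
            pcs = rng.normal(0, 1, (n, Q)) if Q else None
            rec = fit_haplotype_model(y, make_hap_table(assignment, k), pcs, Q=Q)
            X0 = np.ones((n, 1 + Q))
            if Q:
                X0[:, 1:] = pcs
            ind = np.zeros((n, k - 1))
            for j in range(1, k):
                ind[assignment == j, j - 1] = 1.0
            F, df1, df2, p = oracle_f_test(y, np.hstack([X0, ind]), X0)
            assert rec.F == pytest.approx(F, rel=1e-8)
            assert (rec.df1, rec.df2) == (df1, df2)
            assert rec.p_value == pytest.approx(p, rel=1e-8, abs=1e-300)

    def test_constant_trait_degenerate(self):
        table = make_hap_table([0] * 5 + [1] * 5, 2)
        rec = fit_haplotype_model(np.full(10, 3.14), table, None, Q=0)
        assert rec.degenerate
        assert not rec.significant
        assert np.isnan(rec.F)

    def test_perfect_class_fit_zero_adjacent_p(self):
        table = make_hap_table([0] * 5 + [1] * 5, 2)
        y = np.array([1.0] * 5 + [2.0] * 5)
        rec = fit_haplotype_model(y, table, None, Q=0)
        assert rec.degenerate
        assert 0 < rec.p_value < 1e-300
        assert rec.significant

    def test_significance_threshold(self, rng):
        # significant <=> p < alpha, checked over many random fits
        seen_both = set()
        for _ in range(50):
            n = int(rng.integers(12, 40))
            assignment = rng.integers(0, 2, size=n)
            assignment[:2] = [0, 1]
            y = rng.normal(0, 1, n) + assignment * rng.choice([0.0, 3.0])
            rec = fit_haplotype_model(y, make_hap_table(assignment, 2), None, Q=0, alpha=1e-4)
            assert rec.significant == (rec.p_value < 1e-4)
            seen_both.add(rec.significant)
        assert seen_both == {True, False}

    def test_excluded_accessions_and_missing_traits_dropped(self, rng):
        assignment = np.array([0, 0, 0, 1, 1, 1, EXCLUDED, 0])
        y = rng.normal(0, 1, 8)
        y[5] = np.nan
        rec = fit_haplotype_model(y, make_hap_table(assignment, 2), None, Q=0)
        assert rec.n_used == 6

    def test_df2_too_small_untestable(self, rng):
        table = make_hap_table([0, 1, 0], 2)
        pcs = rng.normal(0, 1, (3, 1))
        rec = fit_haplotype_model(np.array([1.0, 2.0, 3.0]), table, pcs, Q=1)
        # n=3, k=2, Q=1 -> df2 = 0
        assert not rec.testable

    def test_class_confounded_with_covariate_flagged(self):
        n = 10
        assignment = np.array([0] * 5 + [1] * 5)
        pcs = assignment.astype(float).reshape(-1, 1)  # PC identical to split
        y = np.arange(n, dtype=float)
        rec = fit_haplotype_model(y, make_hap_table(assignment, 2), pcs, Q=1)
        assert rec.collinear
        assert not rec.testable

    def test_class_means_reported(self):
        y = np.array([1.0, 1.0, 2.0, 4.0, 4.0, 4.2])
        table = make_hap_table([0, 0, 0, 1, 1, 1], 2)
        rec = fit_haplotype_model(y, table, None, Q=0)
        assert rec.class_means == pytest.approx([4.0 / 3.0, 61.0 / 15.0])


class TestGenomicInflation:
    def test_uniform_null(self, rng):
        lam = genomic_inflation(rng.uniform(0, 1, 10_000))
        assert 0.95 <= lam <= 1.05

    def test_all_half_exactly_one(self):
        assert genomic_inflation([0.5] * 100) == pytest.approx(1.0)

    def test_too_few_returns_none(self):
        assert genomic_inflation([0.5] * 19) is None


def _scan_inputs(seed, **kw):
    defaults = dict(
        n_accessions=80, n_genes=20, snps_per_gene=(1, 5), divergence=0.6,
        haplotypes_per_gene=(2, 4),
    )
    defaults.update(kw)
    cfg = SimulationConfig(seed=seed, **defaults)
    panel, genes, truth = simulate_panel(cfg)
    traits = simulate_traits(panel, truth, cfg)
    index = assign_snps_to_genes(panel, genes)
    tables = {
        g: collapse_rare_haplotypes(build_gene_haplotypes(panel, index, g), 5)
        for g in index.genes
    }
    dm = dosage_matrix(panel, list(range(panel.n_snps)))
    structure = pca_structure(dm, n_components=3)
    return cfg, panel, index, tables, traits, structure, truth


class TestRunGwhaScan:
    def test_planted_gene_is_minimum_p(self):
        cfg, panel, index, tables, traits, structure, truth = _scan_inputs(
            8, causal_genes=[CausalGene(3, "Glu", 0.5)], noise_sd=0.5,
        )
        results = run_gwha_scan(panel, index, tables, traits, structure, ScanConfig(Q=2))
        glu = [r for r in results if r.trait == "Glu"]
        best = min(glu, key=lambda r: r.p_value)
        assert best.gene_id == "GENE0004"

    def test_single_gene_single_trait(self):
        cfg, panel, index, tables, traits, structure, _ = _scan_inputs(9)
        tt = TraitTable(
            accession_ids=traits.accession_ids,
            trait_names=["Lys"],
            values=traits.values[:, [traits.trait_names.index("Lys")]],
        )
        gene_id = next(g for g, t in tables.items() if t.testable)
        only = {gene_id: tables[gene_id]}
        results = run_gwha_scan(panel, index, only, tt, structure, ScanConfig(Q=2))
        assert len(results) == 1
        assert results[0].gene_id == gene_id and results[0].trait == "Lys"

    def test_deterministic_ordering(self):
        cfg, panel, index, tables, traits, structure, _ = _scan_inputs(10)
        r1 = run_gwha_scan(panel, index, tables, traits, structure, ScanConfig(Q=2))
        r2 = run_gwha_scan(panel, index, tables, traits, structure, ScanConfig(Q=2))
        assert [(a.gene_id, a.trait, a.p_value) for a in r1] == [
            (a.gene_id, a.trait, a.p_value) for a in r2
        ]
        keys = [(a.chrom, a.gene_start) for a in r1]
        assert keys == sorted(keys)

    def test_permuted_traits_null_calibrated(self, rng):
        cfg, panel, index, tables, traits, structure, _ = _scan_inputs(11, n_genes=30)
        n_sig = 0
        n_tests = 0
        for perm_seed in range(5):
            perm = np.random.default_rng(perm_seed).permutation(traits.n_accessions)
            permuted = TraitTable(
                accession_ids=traits.accession_ids,
                trait_names=traits.trait_names,
                values=traits.values[perm],
            )
            results = run_gwha_scan(
                panel, index, tables, permuted, structure, ScanConfig(Q=2, alpha=0.01)
            )
            n_tests += len(results)
            n_sig += sum(r.significant for r in results)
        assert n_tests > 500
        assert n_sig <= 5 * 0.01 * n_tests  # <= 5x the null expectation


class TestSNPScan:
    def test_beta_p_match_statsmodels(self, rng):
        import statsmodels.api as sm

        cfg, panel, index, tables, traits, structure, _ = _scan_inputs(12, n_accessions=30)
        gene_id = next(iter(index.genes))
        results = run_snp_scan(
            panel, index, traits, structure, ScanConfig(Q=2), [(gene_id, "Asp")]
        )
        assert results
        y = traits.values[:, traits.trait_names.index("Asp")]
        pcs = structure.pc_coords[:, :2]
        for r in results:
            j = panel.snp_ids.index(r.snp_id)
            d = panel.calls[:, j].astype(float)
            d[d == -1] = d[d != -1].mean()
            X = sm.add_constant(np.column_stack([pcs, d]))
            fit = sm.OLS(y, X).fit()
            assert r.beta == pytest.approx(fit.params[-1], rel=1e-8)
            assert r.p_value == pytest.approx(fit.pvalues[-1], rel=1e-6)

    def test_monomorphic_dosage_skipped(self, rng):
        from conftest import make_panel
        from gwhap.types import GeneModel, REF_HOM

        panel = make_panel(np.full((10, 2), REF_HOM, dtype=np.int8))
        panel.calls[:5, 1] = 2
        index = assign_snps_to_genes(panel, [GeneModel("G1", "chr01", 50, 500)])
        traits = TraitTable(panel.accession_ids, ["t"], rng.random((10, 1)))
        res = run_snp_scan(panel, index, traits, None, ScanConfig(Q=0), [("G1", "t")])
        assert [r.snp_id for r in res] == [panel.snp_ids[1]]

    def test_planted_collinear_snp_minimum_p(self):
        cfg, panel, index, tables, traits, structure, truth = _scan_inputs(
            13, causal_genes=[CausalGene(2, "Val", 0.5)], noise_sd=0.5,
            haplotypes_per_gene=(2, 2), snps_per_gene=(3, 6),
        )
        gene_id = "GENE0003"
        res = run_snp_scan(
            panel, index, traits, structure, ScanConfig(Q=2), [(gene_id, "Val")]
        )
        key = key_variant_per_gene(res, gene_id, "Val")
        # with exactly two founder haplotypes, SNPs that differ between them
        # perfectly tag the class split; the key variant must be one of those
        cols = index.snp_indices(gene_id)
        classes = truth.gene_classes[gene_id]
        tagging = []
        for j in cols:
            d = panel.calls[:, j]
            if len(np.unique(d[classes == 0])) == 1 and len(np.unique(d[classes == 1])) == 1 \
                    and d[classes == 0][0] != d[classes == 1][0]:
                tagging.append(panel.snp_ids[j])
        assert key.snp_id in tagging


class TestKeyVariant:
    def _mk(self, snp_id, pos, p):
        return SNPAssociationResult(
            snp_id=snp_id, gene_id="G", trait="t", chrom="chr01", pos=pos,
            beta=0.0, p_value=p,
        )

    def test_single_snp(self):
        res = [self._mk("s1", 100, 0.5)]
        assert key_variant_per_gene(res, "G", "t").snp_id == "s1"
        assert res[0].is_key_variant

    def test_tie_break_by_position(self):
        res = [self._mk("s2", 200, 1e-6), self._mk("s1", 100, 1e-6)]
        assert key_variant_per_gene(res, "G", "t").pos == 100

    def test_argmin_oracle(self, rng):
        ps = rng.uniform(0, 1, 30)
        res = [self._mk(f"s{i}", 100 + i, p) for i, p in enumerate(ps)]
        assert key_variant_per_gene(res, "G", "t").snp_id == f"s{int(np.argmin(ps))}"

    def test_no_snps_fatal(self):
        with pytest.raises(DataError):
            key_variant_per_gene([], "G", "t")


class TestExportManhattanQQ:
    def test_rows_and_qq_columns(self, tmp_path, rng):
        cfg, panel, index, tables, traits, structure, _ = _scan_inputs(14, n_genes=5)
        results = run_gwha_scan(panel, index, tables, traits, structure, ScanConfig(Q=2))
        man, qq = export_manhattan_qq(results[:3], str(tmp_path / "plots"))
        man_lines = open(man).read().strip().split("\n")
        assert len(man_lines) == 4  # header + 3
        qq_lines = open(qq).read().strip().split("\n")[1:]
        by_trait = {}
        for line in qq_lines:
            t, e, o = line.split("\t")
            by_trait.setdefault(t, []).append((float(e), float(o)))
        for t, rows in by_trait.items():
            n = len(rows)
            expected = [-np.log10((i - 0.5) / n) for i in range(1, n + 1)]
            assert [r[0] for r in rows] == pytest.approx(expected)
            obs = [r[1] for r in rows]
            assert obs == sorted(obs, reverse=True)
            inp = sorted(
                -np.log10(r.p_value) for r in results[:3] if r.trait == t
            )[::-1]
            assert obs == pytest.approx(inp)
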