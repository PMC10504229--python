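"""Population structure (PCA + k-means) and centered-IBS kinship.

The association model consumes principal components of a thinned dosage
matrix; subpopulation labels come from k-means on the leading PCs.  Kinship
uses column-centered dosages with VanRaden-style scaling and is provided as
a diagnostic (the association test itself is PC-corrected OLS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .errors import DataError
from .types import MISSING, GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class DosageMatrix:
    """Accession x SNP alt-dosage matrix (0/1/2, missing mean-imputed)."""

    accession_ids: list[str]
    snp_indices: list[int]  # indices into the source panel
    values: np.ndarray  # float64


@dataclass
class StructureResult:
    accession_ids: list[str]
    pc_coords: np.ndarray  # (n_accessions, Q)
    eigenvalues: np.ndarray  # descending
    variance_explained: np.ndarray  # fractions
    cluster_labels: np.ndarray | None = None  # 1-based


@dataclass
class KinshipMatrix:
    accession_ids: list[str]
    values: np.ndarray  # symmetric


def dosage_matrix(panel: GenotypePanel, snp_subset: list[int] | np.ndarray) -> DosageMatrix:
    """Alt-allele dosage for a SNP subset; missing calls take the SNP mean.

    SNPs with every call missing carry no information and are dropped with
    a warning.
    """
    idx = list(int(i) for i in snp_subset)
    if not idx:
        raise DataError("empty SNP subset for dosage matrix")
    raw = panel.calls[:, idx].astype(np.float64)
    raw[raw == MISSING] = np.nan
    col_ok = ~np.all(np.isnan(raw), axis=0)
    if not col_ok.all():
        dropped = [idx[j] for j in np.nonzero(~col_ok)[0]]
        logger.warning("dropping %d all-missing SNP(s) from dosage matrix", len(dropped))
        idx = [idx[j] for j in np.nonzero(col_ok)[0]]
        raw = raw[:, col_ok]
    col_means = np.nanmean(raw, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(raw))
    raw[nan_r, nan_c] = col_means[nan_c]
    return DosageMatrix(accession_ids=list(panel.accession_ids), snp_indices=idx, values=raw)


def pca_structure(dosage: DosageMatrix, n_components: int = 10) -> StructureResult:
    """PCA of the column-centered dosage matrix via SVD.

    Sign convention: each PC is flipped so that its largest-magnitude SNP
    loading is positive, making results deterministic across solvers.
    """
    X = dosage.values
    n, m = X.shape
    if n < 2 or m < 2:
        raise DataError("PCA requires at least 2 accessions and 2 SNPs")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = S.max(initial=0.0) * max(n, m) * np.finfo(float).eps
    rank = int((S > tol).sum())
    q = min(n_components, rank)
    if q < n_components:
        logger.warning("n_components=%d exceeds rank %d; truncating", n_components, rank)
    # deterministic sign: largest-|loading| entry of each right singular vector > 0
    for k in range(q):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    coords = U[:, :q] * S[:q]
    eigenvalues = (S[:q] ** 2) / (n - 1)
    total_var = float((S**2).sum()) / (n - 1)
    var_explained = (S[:q] ** 2 / (n - 1)) / total_var if total_var > 0 else np.zeros(q)
    return StructureResult(
        accession_ids=list(dosage.accession_ids),
        pc_coords=coords,
        eigenvalues=eigenvalues,
        variance_explained=var_explained,
    )


def cluster_accessions(structure: StructureResult, K: int = 2, seed: int = 0) -> np.ndarray:
    """K-means subpopulation labels on the leading PCs.

    Uses the first ``max(3, ceil(log2 K))`` PCs (or all available if fewer).
    Labels are 1-based with label 1 assigned to the largest cluster; ties go
    to the cluster containing the earliest accession.
    """
    n = len(structure.accession_ids)
    if K > n:
        raise DataError(f"K={K} exceeds number of accessions {n}")
    if K == 1:
        labels = np.ones(n, dtype=np.int64)
        structure.cluster_labels = labels
        return labels
    n_pcs = max(3, int(np.ceil(np.log2(K))))
    n_pcs = min(n_pcs, structure.pc_coords.shape[1])
    X = structure.pc_coords[:, :n_pcs]
    km = KMeans(n_clusters=K, random_state=seed, n_init=10)
    raw = km.fit_predict(X)
    order = sorted(
        range(K),
        key=lambda c: (-int((raw == c).sum()), int(np.nonzero(raw == c)[0][0])),
    )
    remap = {c: r + 1 for r, c in enumerate(order)}
    labels = np.array([remap[c] for c in raw], dtype=np.int64)
    structure.cluster_labels = labels
    return labels


def centered_ibs_kinship(dosage: DosageMatrix) -> KinshipMatrix:
    """Genomic relationship matrix from column-centered dosages.

    K = W W' / c with W the column-centered dosage matrix and
    c = sum_l 2 p_l (1 - p_l), p_l = column mean / 2.
    """
    X = dosage.values
    if X.shape[0] < 2:
        raise DataError("kinship requires at least 2 accessions")
    p = X.mean(axis=0) / 2.0
    c = float(np.sum(2.0 * p * (1.0 - p)))
    if c <= 0:
        raise DataError("no polymorphism in dosage matrix (scaling constant is 0)")
    W = X - X.mean(axis=0, keepdims=True)
    K = (W @ W.T) / c
    K = (K + K.T) / 2.0  # enforce exact symmetry
    return KinshipMatrix(accession_ids=list(dosage.accession_ids), values=K)


def write_pcs_tsv(structure: StructureResult, path: str) -> None:
    q = structure.pc_coords.shape[1]
    with open(path, "w", encoding="utf-8") as fh:
        header = "accession\t" + "\t".join(f"PC{k + 1}" for k in range(q))
        if structure.cluster_labels is not None:
            header += "\tcluster"
        fh.write(header + "\n")
        for i, acc in enumerate(structure.accession_ids):
            row = acc + "\t" + "\t".join(f"{v:.10g}" for v in structure.pc_coords[i])
            if structure.cluster_labels is not None:
                row += f"\t{int(structure.cluster_labels[i])}"
            fh.write(row + "\n")


def write_kinship_tsv(kinship: KinshipMatrix, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("accession\t" + "\t".join(kinship.accession_ids) + "\n")
        for i, acc in enumerate(kinship.accession_ids):
            fh.write(acc + "\t" + "\t".join(f"{v:.10g}" for v in kinship.values[i]) + "\n")
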