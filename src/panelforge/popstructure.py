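"""Population-structure analytics: genotype PCA and adjacent-pair LD.

The PCA normalises each marker by its theoretical standard deviation
under Hardy-Weinberg equilibrium, sqrt(2 p (1-p)), under an additive
(dosage) model — the standard genotype-PCA scaling that equalises the
contribution of rare and common variants' drift signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .validation import MISSING, GenotypeMatrix, SEX_CHROMS


@dataclass
class PcaResult:
    scores: pd.DataFrame                 # samples x components
    explained_variance_fraction: np.ndarray
    snps_used: int
    eigenvalues: np.ndarray


def _normalized_matrix(matrix: GenotypeMatrix, autosomes_only: bool) -> np.ndarray:
    calls = matrix.calls.astype(float)
    if autosomes_only and matrix.snp_chroms is not None:
        calls = calls[:, ~np.isin(matrix.snp_chroms, list(SEX_CHROMS))]
    miss = calls == MISSING
    calls[miss] = np.nan
    with np.errstate(invalid="ignore"):
        p = np.nanmean(calls, axis=0) / 2.0
    keep = np.isfinite(p) & (p > 0) & (p < 1)
    calls = calls[:, keep]
    p = p[keep]
    # mean imputation: missing dosage replaced by 2p, hence exact zero
    # column means after centring
    calls = np.where(np.isnan(calls), 2 * p, calls)
    return (calls - 2 * p) / np.sqrt(2 * p * (1 - p))


def pca_genotypes(matrix: GenotypeMatrix, n_components: int = 10,
                  autosomes_only: bool = True) -> PcaResult:
    """PCA of HWE-normalised genotypes.

    Monomorphic SNPs are dropped, missing calls imputed at the SNP mean
    dosage 2p.  Components come from the eigendecomposition of the
    sample x sample covariance (efficient when samples << SNPs) and are
    identical, up to sign, to the SVD of the normalised matrix; the sign
    is fixed so each component's largest-magnitude SNP loading is
    positive.
    """
    if matrix.n_samples < 2:
        raise ValueError("PCA needs at least two samples")
    Z = _normalized_matrix(matrix, autosomes_only)
    m = Z.shape[1]
    if m == 0:
        raise ValueError("no polymorphic SNPs available for PCA")
    n = Z.shape[0]
    cov = Z @ Z.T / m
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    k = min(n_components, n - 1 if n > 1 else 1)
    scores = evecs[:, :k] * np.sqrt(np.maximum(evals[:k], 0))
    # fix signs via SNP loadings Z^T u
    for j in range(k):
        if evals[j] <= 0:
            continue
        loading = Z.T @ evecs[:, j]
        pivot = np.argmax(np.abs(loading))
        if loading[pivot] < 0:
            scores[:, j] = -scores[:, j]
    total = evals.sum()
    frac = evals[:k] / total if total > 0 else np.zeros(k)
    df = pd.DataFrame(scores, index=matrix.samples,
                      columns=[f"PC{i + 1}" for i in range(k)])
    if matrix.sample_lines is not None:
        df.insert(0, "line", matrix.sample_lines)
    return PcaResult(scores=df, explained_variance_fraction=frac,
                     snps_used=m, eigenvalues=evals[:k])


def adjacent_ld(matrix: GenotypeMatrix, panel: pd.DataFrame) -> pd.DataFrame:
    """r^2 between consecutive panel SNPs within each chromosome.

    ``panel`` is a frame with snp_id, chrom, pos defining the order;
    pairs spanning a chromosome boundary emit no value.  r^2 is the
    squared Pearson correlation of dosages over samples called at both
    SNPs; a pair with a monomorphic member (or <2 joint calls) yields
    NaN.
    """
    panel = panel.sort_values(["chrom", "pos"], kind="mergesort")
    rows = []
    for chrom, sub in panel.groupby("chrom", sort=False):
        ids = sub["snp_id"].tolist()
        for a, b in zip(ids, ids[1:]):
            ga = matrix.calls[:, matrix.snp_idx(a)].astype(float)
            gb = matrix.calls[:, matrix.snp_idx(b)].astype(float)
            both = (ga != MISSING) & (gb != MISSING)
            r2 = np.nan
            if both.sum() >= 2:
                xa, xb = ga[both], gb[both]
                if xa.std() > 0 and xb.std() > 0:
                    r = np.corrcoef(xa, xb)[0, 1]
                    r2 = float(r * r)
            rows.append({"chrom": chrom, "snp_a": a, "snp_b": b, "r2": r2})
    return pd.DataFrame(rows, columns=["chrom", "snp_a", "snp_b", "r2"])
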