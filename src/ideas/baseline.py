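"""Pseudo-bulk baseline and multiplicity / summary statistics.

The pseudo-bulk baseline collapses each individual's cells to a single vector
of summed counts and tests each gene with an NB regression (log total-depth
offset, Wald test on the group coefficient). Because summation only preserves
the mean signal, this baseline detects mean shifts but is essentially blind
to variance-only differences — the contrast the distribution-based test is
designed to expose.

Summaries: Storey q-values with the lambda = 0.5 estimator
pi0_hat = mean(p > 0.5) / 0.5, the DE-proportion estimate 1 - 2 p0_hat(0.5),
and the pseudo-dispersion theta_hat = mu^2 / (var - mu) that inverts the NB
mean-variance relation to separate dispersion signal from mean signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_model import CellData, INDIVIDUAL_COL
from .permanova import CenteredKernel, gower_center, permutation_test, TestResult

__all__ = [
    "PseudoBulkMatrix",
    "pseudobulk",
    "nb_pseudobulk_test",
    "qvalues",
    "de_proportion",
    "pseudo_dispersion",
    "scalar_permutation_test",
]


@dataclass
class PseudoBulkMatrix:
    """Genes x individuals matrix of per-individual summed counts."""

    matrix: np.ndarray
    gene_ids: list[str]
    individuals: list[str]

    @property
    def depth(self) -> np.ndarray:
        """Per-individual total count (column sums)."""
        return self.matrix.sum(axis=0)


def pseudobulk(data: CellData) -> PseudoBulkMatrix:
    """Sum counts over each individual's cells (exact integer sums)."""
    individuals = data.individuals
    mat = np.zeros((data.n_genes, len(individuals)), dtype=np.int64)
    for j, ind in enumerate(individuals):
        idx = data.cell_indices_of(ind)
        mat[:, j] = data.counts[:, idx].sum(axis=1)
    return PseudoBulkMatrix(mat, list(data.gene_ids), individuals)


def nb_pseudobulk_test(
    pb: PseudoBulkMatrix,
    X: np.ndarray | pd.Series,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene NB Wald test of the group coefficient on pseudo-bulk counts.

    Fits counts ~ intercept + X + covariates with a log total-depth offset.
    Non-convergent NB fits fall back to a Poisson GLM; if that also fails the
    gene's p-value is NaN. Returns a DataFrame (gene_id, coef, pvalue).
    """
    x = np.asarray(X, dtype=float)
    n = x.size
    if np.ptp(x) == 0:
        raise ValueError("X is constant: design is rank deficient")
    cols = [np.ones(n), x]
    if covariates is not None and np.asarray(covariates).size:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        cols += [cov[:, j] for j in range(cov.shape[1])]
    Z = np.column_stack(cols)
    q = Z.shape[1]
    if n < q + 2:
        raise ValueError(f"need n >= q + 2 (n={n}, q={q})")
    offset = np.log(pb.depth.astype(float))
    rows = []
    for g, gene in enumerate(pb.gene_ids):
        y = pb.matrix[g].astype(float)
        coef, pval = np.nan, np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.NegativeBinomial(y, Z, offset=offset).fit(disp=0, maxiter=200)
                if res.mle_retvals.get("converged", False) and np.all(
                    np.isfinite(res.bse[:q])
                ):
                    coef, pval = float(res.params[1]), float(res.pvalues[1])
            except Exception:
                pass
            if not np.isfinite(pval):
                try:
                    res = sm.GLM(
                        y, Z, family=sm.families.Poisson(), offset=offset
                    ).fit()
                    coef, pval = float(res.params[1]), float(res.pvalues[1])
                except Exception:
                    coef, pval = np.nan, np.nan
        rows.append({"gene_id": gene, "coef": coef, "pvalue": pval})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# multiplicity
# ----------------------------------------------------------------------

def qvalues(pvals: np.ndarray, pi0: float | None = None) -> tuple[np.ndarray, float]:
    """Storey q-values with the fixed lambda = 0.5 estimator of pi0.

    pi0_hat = mean(p > 0.5) / 0.5, clamped to (0, 1]; forcing ``pi0=1``
    reproduces Benjamini-Hochberg exactly. NaN p-values stay NaN in place.
    Returns (qvalues, pi0_hat). q-values are monotone in p-value rank.
    """
    p = np.asarray(pvals, dtype=float)
    ok = np.isfinite(p)
    pv = p[ok]
    if pv.size < 10:
        raise ValueError("need at least 10 p-values")
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values outside [0, 1]")
    m = pv.size
    if pi0 is None:
        pi0 = float(np.mean(pv > 0.5) / 0.5)
    pi0 = float(min(1.0, max(pi0, 1.0 / m)))
    order = np.argsort(pv, kind="mergesort")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * pv[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.full(p.shape, np.nan)
    qv = np.empty(m)
    qv[order] = q_sorted
    q[ok] = qv
    return q, pi0


def de_proportion(pvals: np.ndarray) -> float:
    """Estimated proportion of DE genes: 1 - 2 * mean(p > 0.5), clamped to [0, 1].

    Under a uniform null about half the p-values exceed 0.5, so twice that
    fraction estimates the null proportion pi0 and the remainder the signal.
    """
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("empty p-value vector")
    return float(min(1.0, max(0.0, 1.0 - 2.0 * np.mean(p > 0.5))))


def pseudo_dispersion(mu: float, var: float) -> float:
    """Invert the NB mean-variance relation: theta_hat = mu^2 / (var - mu).

    Returns ``inf`` when var <= mu (Poisson or underdispersed: no finite NB
    dispersion reproduces those moments).
    """
    if mu <= 0 or var <= 0:
        raise ValueError("moments must be positive")
    if var <= mu:
        return np.inf
    return float(mu**2 / (var - mu))


def scalar_permutation_test(
    values: np.ndarray,
    Z: pd.DataFrame,
    x_col: str,
    n_perm: int = 999,
    seed: int | None = 0,
) -> TestResult:
    """Exploratory: permutation test of a per-individual scalar summary.

    Runs the same centered-kernel pseudo-F machinery on the absolute-difference
    distance |v_i - v_j| of a scalar (e.g. a per-individual mean or
    pseudo-dispersion). Non-canonical: a pragmatic reduction for asking
    whether the mean or the dispersion alone carries the group signal.
    """
    v = np.asarray(values, dtype=float)
    D = np.abs(v[:, None] - v[None, :])
    kernel = gower_center(D)
    kernel.individuals = list(Z.index.astype(str))
    return permutation_test(kernel, Z, x_col, n_perm=n_perm, seed=seed)
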