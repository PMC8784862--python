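"""Covariate-adjusted distance-based pseudo-F permutation test.

The distance matrix D is turned into Gower's centered kernel
G = C (-1/2 D^2) C with C = I - (1/n) 11'; negative eigenvalues of G (which
arise when the distances are not Euclidean-embeddable) are truncated to zero.
With Z the design matrix holding the intercept, the variable of interest X and
any individual-level covariates, and H_Z = Z (Z'Z)^-1 Z' the hat matrix, the
statistic is

    F = tr(H_Z G H_Z) / tr[(I - H_Z) G (I - H_Z)].

Unlike the classical PERMANOVA partitioning, the numerator projects on the
full design so covariates with strong expression association are absorbed
rather than inflating the residual. The null distribution is built by
permuting the X column only (or re-sampling it given the covariates), reusing
the same G: permuting X with G fixed is algebraically identical to permuting
G's rows and columns with X fixed, so distances are never recomputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import CellData, LOG_RD_COL
from .distance import build_distance_matrix, DistanceMatrix
from .distribution import (
    adjust_log_counts,
    fit_nb_individual,
    fit_zinb_individual,
)

__all__ = [
    "CenteredKernel",
    "AnalysisConfig",
    "TestResult",
    "gower_center",
    "pseudo_F",
    "permutation_test",
    "test_gene",
]

#: denominators below this make the design saturated and the test degenerate
DEGENERATE_TOL = 1e-12
#: numerical slack when counting permuted F values tying the observed one
TIE_TOL = 1e-9
#: permutations drawn before the first adaptive-stopping check
ADAPTIVE_CHECK = 100


@dataclass
class CenteredKernel:
    """PSD kernel from Gower centering of a squared-distance matrix."""

    G: np.ndarray
    individuals: list[str]

    def __post_init__(self) -> None:
        G = np.asarray(self.G, dtype=float)
        n = G.shape[0]
        scale = max(np.abs(G).max(), 1.0)
        if np.abs(G.sum(axis=0)).max() > 1e-10 * n * scale:
            raise ValueError("kernel rows/columns do not sum to ~0")
        self.G = G


@dataclass
class TestResult:
    """Per-gene outcome of the distance-based permutation test."""

    gene_id: str
    F_obs: float = np.nan
    pvalue: float = np.nan
    n_perm_used: int = 0
    status: str = "ok"
    seed: int | None = None
    qvalue: float | None = None


@dataclass
class AnalysisConfig:
    """Per-gene analysis settings shared by the library and the CLI.

    ``fit`` selects the distribution-estimation path: ``nb`` / ``zinb``
    (parametric regression), ``kde`` / ``empirical`` (covariate-adjusted log
    counts, compared by KDE-JSD or sample Wasserstein), and the metric is
    ``was`` or ``jsd``. ``mode`` chooses permutation or covariate-conditional
    re-sampling of X. The asymptotic kernel-regression p-value path is not
    implemented; permutation is used at every sample size.
    """

    metric: str = "was"
    fit: str = "nb"
    n_perm: int = 999
    seed: int = 0
    mode: str = "permute"
    min_cells: int = 10
    min_frac: float = 0.20
    x_column: str = "status"
    cell_covariates: list[str] = field(default_factory=lambda: [LOG_RD_COL])
    indiv_covariates: list[str] = field(default_factory=list)
    adaptive: bool = True
    zinb_infl: str = "covars"

    def __post_init__(self) -> None:
        if self.metric not in ("was", "jsd"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.fit not in ("nb", "zinb", "kde", "empirical"):
            raise ValueError(f"unknown fit {self.fit!r}")
        if self.mode == "asymptotic":
            raise ValueError(
                "the asymptotic kernel-regression p-value path is not "
                "implemented; use mode='permute' or 'resample'"
            )
        if self.mode not in ("permute", "resample"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_perm < 99:
            raise ValueError("n_perm must be >= 99")


# ----------------------------------------------------------------------
# kernel and statistic
# ----------------------------------------------------------------------

def gower_center(D: DistanceMatrix | np.ndarray) -> CenteredKernel:
    """Gower's centered kernel of a distance matrix, with PSD truncation.

    A = -1/2 * D∘D (elementwise square), G = C A C, then negative eigenvalues
    of G are set to zero and the kernel reconstructed.
    """
    if isinstance(D, DistanceMatrix):
        mat, ids = D.matrix, D.individuals
    else:
        mat = np.asarray(D, dtype=float)
        if not np.allclose(mat, mat.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        ids = [str(i) for i in range(mat.shape[0])]
    A = -0.5 * mat**2
    row = A.mean(axis=1, keepdims=True)
    col = A.mean(axis=0, keepdims=True)
    G = A - row - col + A.mean()
    vals, vecs = np.linalg.eigh((G + G.T) / 2.0)
    vals = np.clip(vals, 0.0, None)
    G = (vecs * vals) @ vecs.T
    G = (G + G.T) / 2.0
    # re-center exactly: eigen-truncation can leave ~1e-13 row sums behind
    row = G.mean(axis=1, keepdims=True)
    G = G - row - row.T + G.mean()
    return CenteredKernel(G=G, individuals=list(ids))


def _check_design(Z: np.ndarray) -> None:
    n, q = Z.shape
    if n < q + 1:
        raise ValueError(f"need n >= q + 1 (n={n}, q={q})")
    if np.linalg.matrix_rank(Z) < q:
        raise ValueError("rank-deficient design matrix")


def pseudo_F(G: CenteredKernel | np.ndarray, Z: np.ndarray) -> float:
    """Trace-ratio pseudo-F statistic tr(H G H) / tr[(I-H) G (I-H)].

    Returns NaN when the denominator vanishes (saturated design); the caller
    records the gene as degenerate. An intercept-only design gives exactly 0
    because Gower centering removes the grand mean.
    """
    Gm = G.G if isinstance(G, CenteredKernel) else np.asarray(G, dtype=float)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    _check_design(Z)
    Q, _ = np.linalg.qr(Z)
    t = float(np.sum(Q * (Gm @ Q)))  # tr(H G H) = tr(Q' G Q)
    denom = float(np.trace(Gm)) - t
    if abs(denom) < DEGENERATE_TOL:
        return np.nan
    return t / denom


def _trace_stats(Gm: np.ndarray, Z: np.ndarray) -> tuple[float, float]:
    Q, _ = np.linalg.qr(Z)
    t = float(np.sum(Q * (Gm @ Q)))
    return t, float(np.trace(Gm)) - t


# ----------------------------------------------------------------------
# permutation engine
# ----------------------------------------------------------------------

def _build_design(
    Z_df: pd.DataFrame, x_col: str, x: np.ndarray | None = None
) -> np.ndarray:
    cols = [c for c in Z_df.columns if c != x_col]
    xv = Z_df[x_col].to_numpy(dtype=float) if x is None else x
    return np.column_stack(
        [np.ones(len(Z_df))] + [Z_df[c].to_numpy(dtype=float) for c in cols] + [xv]
    )


def _resample_x(
    x: np.ndarray, covars: np.ndarray | None, rng: np.random.Generator
) -> np.ndarray:
    """Redraw X given covariates (covariate-conditional resampling scheme).

    Binary X: logistic regression of X on the covariates, then independent
    Bernoulli draws from the fitted probabilities. Continuous X: fitted values
    from OLS plus a permutation of the residuals.
    """
    import statsmodels.api as sm

    n = x.size
    W = np.ones((n, 1)) if covars is None or covars.size == 0 else np.column_stack(
        [np.ones(n), covars]
    )
    binary = set(np.unique(x)) <= {0.0, 1.0}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if binary:
            try:
                p = sm.GLM(x, W, family=sm.families.Binomial()).fit().fittedvalues
            except Exception:
                p = np.full(n, x.mean())
            return (rng.random(n) < p).astype(float)
        fitted = W @ np.linalg.lstsq(W, x, rcond=None)[0]
        resid = x - fitted
        return fitted + rng.permutation(resid)


def permutation_test(
    G: CenteredKernel,
    Z: pd.DataFrame,
    x_col: str,
    n_perm: int = 999,
    seed: int | None = 0,
    mode: str = "permute",
    *,
    adaptive: bool = True,
    gene_id: str = "",
) -> TestResult:
    """Permutation p-value for the pseudo-F of the X column in ``Z``.

    ``Z`` holds the variable of interest and individual-level covariates (no
    intercept column; one is added). Only the X column is permuted (or
    re-sampled given covariates when ``mode='resample'``); the kernel G is
    reused across permutations. The p-value is the add-one estimator
    (1 + #{F_b >= F_obs}) / (1 + B), ties counting as exceedances.

    For binary X where the number of distinct case/control assignments is at
    most ``n_perm``, the null is enumerated exhaustively and the p-value is the
    exact proportion of assignments (observed one included) with F >= F_obs.
    With ``adaptive`` on, clearly null genes stop after 100 permutations once
    the running p-value exceeds 0.5.
    """
    if x_col not in Z.columns:
        raise ValueError(f"x column {x_col!r} not in design table")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    Gm = G.G
    x = Z[x_col].to_numpy(dtype=float)
    n = x.size
    cov_cols = [c for c in Z.columns if c != x_col]
    covars = Z[cov_cols].to_numpy(dtype=float) if cov_cols else None

    Z_obs = _build_design(Z, x_col)
    try:
        num, denom = _trace_stats(Gm, Z_obs)
    except ValueError:
        return TestResult(gene_id=gene_id, status="degenerate", seed=seed)
    if abs(denom) < DEGENERATE_TOL:
        return TestResult(gene_id=gene_id, status="degenerate", seed=seed)
    F_obs = num / denom

    binary = set(np.unique(x)) <= {0.0, 1.0}
    if binary and mode == "permute":
        n_case = int(x.sum())
        n_assign = comb(n, n_case)
        if n_assign <= n_perm:
            warnings.warn(
                f"only {n_assign} distinct assignments; using exhaustive enumeration"
            )
            exceed = 0
            for idx in combinations(range(n), n_case):
                xb = np.zeros(n)
                xb[list(idx)] = 1.0
                num_b, denom_b = _trace_stats(Gm, _build_design(Z, x_col, xb))
                Fb = num_b / denom_b if abs(denom_b) > DEGENERATE_TOL else np.inf
                if Fb >= F_obs - TIE_TOL * max(1.0, abs(F_obs)):
                    exceed += 1
            return TestResult(
                gene_id=gene_id,
                F_obs=F_obs,
                pvalue=exceed / n_assign,
                n_perm_used=n_assign,
                status="ok",
                seed=seed,
            )

    rng = np.random.default_rng(seed)
    exceed = 0
    b_done = 0
    for b in range(n_perm):
        if mode == "resample":
            xb = _resample_x(x, covars, rng)
            if np.ptp(xb) == 0:  # degenerate redraw: all one class
                xb = rng.permutation(x)
        else:
            xb = rng.permutation(x)
        num_b, denom_b = _trace_stats(Gm, _build_design(Z, x_col, xb))
        Fb = num_b / denom_b if abs(denom_b) > DEGENERATE_TOL else np.inf
        if Fb >= F_obs - TIE_TOL * max(1.0, abs(F_obs)):
            exceed += 1
        b_done = b + 1
        if adaptive and b_done == ADAPTIVE_CHECK:
            if (1 + exceed) / (1 + b_done) > 0.5:
                break
    pvalue = (1 + exceed) / (1 + b_done)
    return TestResult(
        gene_id=gene_id,
        F_obs=F_obs,
        pvalue=pvalue,
        n_perm_used=b_done,
        status="ok",
        seed=seed,
    )


# ----------------------------------------------------------------------
# per-gene orchestration
# ----------------------------------------------------------------------

def _fit_individual(
    counts: np.ndarray,
    covars: np.ndarray | None,
    ref_covars: np.ndarray | None,
    config: AnalysisConfig,
):
    if config.fit == "nb":
        return fit_nb_individual(counts, covars, ref_covars, min_cells=config.min_cells)
    if config.fit == "zinb":
        return fit_zinb_individual(
            counts, covars, ref_covars, min_cells=config.min_cells, infl=config.zinb_infl
        )
    # non-parametric paths share the adjusted-log-count sample
    if counts.size < config.min_cells:
        from .distribution import _failed

        return _failed("empirical_sample")
    return adjust_log_counts(counts, covars, ref_covars)


def gene_seed(global_seed: int, gene_index: int) -> int:
    """Deterministic per-gene seed so genes are independently reproducible."""
    ss = np.random.SeedSequence([int(global_seed), int(gene_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def test_gene(
    data: CellData,
    gene: str | int,
    config: AnalysisConfig,
    *,
    ref_covars: np.ndarray | None = None,
    gene_index: int | None = None,
) -> TestResult:
    """Full per-gene pipeline: distribution fits -> distances -> permutation test.

    Any individual whose fit fails (too few cells, all-zero or zero-variance
    counts, non-convergent regression past every fallback) makes the gene
    untestable: dropping individuals gene by gene would change n across genes
    and break comparability of the permutation null, so the gene is reported
    with status ``fit_failed`` instead. Errors never propagate past the gene.
    """
    if isinstance(gene, (int, np.integer)):
        gi = int(gene)
        gene_id = data.gene_ids[gi]
    else:
        gene_id = str(gene)
        gi = data.gene_ids.index(gene_id)
    if gene_index is None:
        gene_index = gi
    seed = gene_seed(config.seed, gene_index)

    covar_cols = [c for c in config.cell_covariates if c in data.cell_meta.columns]
    all_covars = data.cell_meta[covar_cols].to_numpy(dtype=float) if covar_cols else None
    if ref_covars is None and all_covars is not None:
        ref_covars = np.median(all_covars, axis=0)

    individuals = data.individuals
    row = data.counts[gi]
    dists = []
    for ind in individuals:
        idx = data.cell_indices_of(ind)
        covars = all_covars[idx] if all_covars is not None else None
        dists.append(_fit_individual(row[idx], covars, ref_covars, config))
    if any(not d.ok for d in dists):
        return TestResult(gene_id=gene_id, status="fit_failed", seed=seed)

    try:
        # kde/empirical fits yield samples; the metrics route them through a
        # pairwise shared-grid KDE (jsd) or the sample quantile form (was)
        cap = 10 * (int(row.max()) + 1)
        D = build_distance_matrix(
            dists,
            config.metric,
            gene_id=gene_id,
            individuals=individuals,
            support_cap=cap,
        )
        kernel = gower_center(D)
        Z = data.indiv_meta.loc[individuals, [config.x_column] + config.indiv_covariates]
        return permutation_test(
            kernel,
            Z,
            config.x_column,
            n_perm=config.n_perm,
            seed=seed,
            mode=config.mode,
            adaptive=config.adaptive,
            gene_id=gene_id,
        )
    except Exception:
        return TestResult(gene_id=gene_id, status="fit_failed", seed=seed)
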