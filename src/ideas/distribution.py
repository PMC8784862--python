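"""Per-individual gene-expression distribution estimation.

For one gene, each individual's expression law across their cells is estimated
conditioning on cell-level covariates (log read depth by default), by one of:

* **parametric** — NB or zero-inflated NB (ZINB) regression; the returned
  distribution is the conditional law at a reference covariate vector
  (by default, per-covariate medians over all cells of all individuals);
* **non-parametric** — covariate-adjusted log counts, used either directly as
  an empirical sample (for Wasserstein distances) or through a Gaussian KDE
  (for Jensen-Shannon divergence);
* **denoiser aggregation** — an external denoiser supplies a ZINB (or Poisson)
  distribution per gene per cell, and the individual's distribution is the
  equal-weight mixture of its cells' distributions, or is re-estimated from
  counts sampled from them.

UMI counts are usually well captured by a plain NB, so the parametric fits use
a fallback ladder ZINB -> NB -> Poisson -> failed: a zero-inflation estimate
collapsing below 1e-4 demotes ZINB to NB, a dispersion estimate above 1e4
demotes NB to Poisson, and non-convergence demotes one rung at a time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.discrete.count_model import ZeroInflatedNegativeBinomialP

__all__ = [
    "IndividualDistribution",
    "CellDistributionTable",
    "fit_nb_individual",
    "fit_zinb_individual",
    "discretize",
    "choose_support",
    "adjust_log_counts",
    "kde_density",
    "aggregate_cell_distributions",
    "sample_from_cell_distributions",
]

#: zero-inflation estimate below this collapses ZINB to NB
PI_COLLAPSE = 1e-4
#: dispersion estimate above this collapses NB to Poisson
THETA_COLLAPSE = 1e4
#: default minimum number of cells per individual for a fit
MIN_CELLS = 10
#: upper-tail mass allowed beyond the discretization support
TAIL_MASS = 1e-6


@dataclass
class IndividualDistribution:
    """One individual's gene-expression law, in one of four representations.

    ``kind`` is one of ``parametric`` (zero inflation ``pi``, NB mean ``mu``
    and overdispersion ``theta``; ``pi == 0`` is plain NB and
    ``theta == inf`` is Poisson), ``discrete`` (density ``pmf`` over integer
    counts 0..K), ``continuous_density`` (``grid`` + ``density``), or
    ``empirical_sample`` (``sample`` of adjusted expression values).

    The NB component has variance ``mu + mu**2 / theta``.
    """

    kind: str
    status: str = "ok"
    pi: float | None = None
    mu: float | None = None
    theta: float | None = None
    pmf: np.ndarray | None = None
    grid: np.ndarray | None = None
    density: np.ndarray | None = None
    sample: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.status == "failed":
            return
        if self.kind == "parametric":
            if not (0 <= self.pi < 1):
                raise ValueError(f"zero proportion pi={self.pi} outside [0, 1)")
            if not (np.isfinite(self.mu) and self.mu > 0):
                raise ValueError(f"mean mu={self.mu} must be finite and > 0")
            if not self.theta > 0:
                raise ValueError(f"overdispersion theta={self.theta} must be > 0")
        elif self.kind == "discrete":
            p = np.asarray(self.pmf, dtype=float)
            if np.any(p < -1e-12):
                raise ValueError("negative probabilities in discrete density")
            if abs(p.sum() - 1.0) > 1e-10:
                raise ValueError(f"discrete density sums to {p.sum()}, not 1")
            self.pmf = np.clip(p, 0.0, None)
        elif self.kind == "continuous_density":
            if self.grid is None or self.density is None:
                raise ValueError("continuous_density needs grid and density")
        elif self.kind == "empirical_sample":
            if self.sample is None:
                raise ValueError("empirical_sample needs a sample vector")
        else:
            raise ValueError(f"unknown kind {self.kind!r}")

    @property
    def ok(self) -> bool:
        return self.status != "failed"


def _failed(kind: str = "parametric") -> IndividualDistribution:
    return IndividualDistribution(kind=kind, status="failed")


# ----------------------------------------------------------------------
# parametric pmf helpers
# ----------------------------------------------------------------------

def nb_pmf(y: np.ndarray, mu: float, theta: float) -> np.ndarray:
    """NB(mu, theta) pmf with variance mu + mu^2/theta; theta=inf is Poisson."""
    y = np.asarray(y)
    if np.isinf(theta):
        return stats.poisson.pmf(y, mu)
    return stats.nbinom.pmf(y, theta, theta / (theta + mu))


def zinb_pmf(y: np.ndarray, pi: float, mu: float, theta: float) -> np.ndarray:
    y = np.asarray(y)
    p = (1.0 - pi) * nb_pmf(y, mu, theta)
    return np.where(y == 0, pi + p, p)


def _nb_sf(k: int, pi: float, mu: float, theta: float) -> float:
    """Upper-tail mass P(Y > k) of the ZINB."""
    if np.isinf(theta):
        return (1.0 - pi) * stats.poisson.sf(k, mu)
    return (1.0 - pi) * stats.nbinom.sf(k, theta, theta / (theta + mu))


# ----------------------------------------------------------------------
# parametric fits
# ----------------------------------------------------------------------

def _prepare_design(
    counts: np.ndarray, covars: np.ndarray | None, ref_covars: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    y = np.asarray(counts, dtype=float)
    if covars is None:
        covars = np.empty((y.size, 0))
    covars = np.atleast_2d(np.asarray(covars, dtype=float))
    if covars.shape[0] != y.size:
        covars = covars.T
    if ref_covars is None:
        ref_covars = np.median(covars, axis=0) if covars.shape[1] else np.empty(0)
    ref_covars = np.asarray(ref_covars, dtype=float).ravel()
    X = np.column_stack([np.ones_like(y)] + [covars[:, j] for j in range(covars.shape[1])])
    xref = np.concatenate([[1.0], ref_covars])
    return y, X, xref


def _fit_poisson(y: np.ndarray, X: np.ndarray, xref: np.ndarray) -> IndividualDistribution:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        mu = float(np.exp(xref @ res.params))
        if not (np.isfinite(mu) and mu > 0):
            return _failed()
        return IndividualDistribution(
            kind="parametric", status="fallback_poisson", pi=0.0, mu=mu, theta=np.inf
        )
    except Exception:
        return _failed()


def fit_nb_individual(
    counts: np.ndarray,
    covars: np.ndarray | None = None,
    ref_covars: np.ndarray | None = None,
    *,
    min_cells: int = MIN_CELLS,
    status: str = "ok",
) -> IndividualDistribution:
    """Fit an NB log-linear regression and return the conditional NB law.

    The mean is evaluated at ``ref_covars`` (defaulting to the per-covariate
    medians of the supplied ``covars``); the dispersion is the fitted constant
    overdispersion. Non-convergence, or a dispersion estimate collapsing above
    ``THETA_COLLAPSE``, falls back to a Poisson GLM. All-zero or zero-variance
    counts fail outright.
    """
    counts = np.asarray(counts)
    if counts.size < min_cells:
        return _failed()
    if counts.min() == counts.max():
        # includes the all-zero case; no distribution is identifiable
        return _failed()
    y, X, xref = _prepare_design(counts, covars, ref_covars)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.NegativeBinomial(y, X).fit(disp=0, maxiter=200)
        converged = res.mle_retvals.get("converged", False)
        alpha = float(res.params[-1])
        beta = res.params[:-1]
        mu = float(np.exp(xref @ beta))
        if not converged or not np.isfinite(mu) or not np.all(np.isfinite(res.params)):
            return _fit_poisson(y, X, xref)
        if alpha <= 1.0 / THETA_COLLAPSE:
            return _fit_poisson(y, X, xref)
        theta = 1.0 / alpha
        return IndividualDistribution(
            kind="parametric", status=status, pi=0.0, mu=mu, theta=theta
        )
    except Exception:
        return _fit_poisson(y, X, xref)


def fit_zinb_individual(
    counts: np.ndarray,
    covars: np.ndarray | None = None,
    ref_covars: np.ndarray | None = None,
    *,
    min_cells: int = MIN_CELLS,
    infl: str = "covars",
) -> IndividualDistribution:
    """Fit a ZINB regression (log link on the NB mean, logit on zero inflation).

    ``infl`` chooses the zero-inflation design: ``"covars"`` uses the same
    covariates as the NB mean, ``"intercept"`` an intercept only. The returned
    law is the conditional (pi, mu, theta) at the reference covariates. If the
    zero-inflation estimate collapses (pi < 1e-4) or the fit does not converge,
    the fit falls back to plain NB with status ``fallback_nb``.
    """
    counts = np.asarray(counts)
    if counts.size < min_cells:
        return _failed()
    if counts.min() == counts.max():
        return _failed()
    if counts.min() > 0:
        # no zeros: zero-inflation unidentifiable, go straight to NB
        return fit_nb_individual(
            counts, covars, ref_covars, min_cells=min_cells, status="fallback_nb"
        )
    y, X, xref = _prepare_design(counts, covars, ref_covars)
    X_infl = X if infl == "covars" else X[:, :1]
    xref_infl = xref if infl == "covars" else xref[:1]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ZeroInflatedNegativeBinomialP(y, X, exog_infl=X_infl).fit(
                disp=0, maxiter=500, method="bfgs"
            )
        if not np.all(np.isfinite(res.params)):
            raise RuntimeError("non-finite ZINB parameters")
        k_infl = X_infl.shape[1]
        gamma = res.params[:k_infl]
        beta = res.params[k_infl:-1]
        alpha = float(res.params[-1])
        pi = float(1.0 / (1.0 + np.exp(-(xref_infl @ gamma))))
        mu = float(np.exp(xref @ beta))
        if not (np.isfinite(mu) and mu > 0 and 0 <= pi < 1):
            raise RuntimeError("out-of-range ZINB estimates")
        if pi < PI_COLLAPSE:
            return fit_nb_individual(
                counts, covars, ref_covars, min_cells=min_cells, status="fallback_nb"
            )
        if alpha <= 1.0 / THETA_COLLAPSE:
            theta = np.inf
        else:
            theta = 1.0 / alpha
        return IndividualDistribution(
            kind="parametric", status="ok", pi=pi, mu=mu, theta=theta
        )
    except Exception:
        return fit_nb_individual(
            counts, covars, ref_covars, min_cells=min_cells, status="fallback_nb"
        )


# ----------------------------------------------------------------------
# discretization
# ----------------------------------------------------------------------

def choose_support(
    dists: Sequence[IndividualDistribution], cap: int | None = None
) -> int:
    """Smallest K with upper-tail mass beyond K below ``TAIL_MASS`` for all fits.

    Optionally capped (e.g. at 10x the max observed count + 1); the folded tail
    then keeps densities normalized.
    """
    K = 1
    for d in dists:
        if d.kind != "parametric" or not d.ok:
            raise ValueError("choose_support expects valid parametric distributions")
        if np.isinf(d.theta):
            k = int(stats.poisson.isf(TAIL_MASS / max(1 - d.pi, 1e-12), d.mu)) + 1
        else:
            k = int(
                stats.nbinom.isf(
                    TAIL_MASS / max(1 - d.pi, 1e-12),
                    d.theta,
                    d.theta / (d.theta + d.mu),
                )
            ) + 1
        K = max(K, k)
    if cap is not None:
        K = min(K, cap)
    return K


def discretize(dist: IndividualDistribution, K: int) -> IndividualDistribution:
    """Discrete density over 0..K from a parametric fit; tail mass folds into bin K.

    ``p[y]`` equals the ZINB pmf for y < K and the full upper-tail mass at
    y = K, so the vector sums to 1 exactly up to floating tolerance.
    """
    if dist.kind != "parametric" or not dist.ok:
        raise ValueError("discretize requires a valid parametric distribution")
    if K < 1:
        raise ValueError("K must be >= 1")
    y = np.arange(K)
    p = zinb_pmf(y, dist.pi, dist.mu, dist.theta)
    tail = _nb_sf(K - 1, dist.pi, dist.mu, dist.theta)
    if tail > 0.10:
        warnings.warn(f"tail bin holds {tail:.1%} of the mass; increase K")
    pmf = np.concatenate([p, [tail]])
    pmf = np.clip(pmf, 0.0, None)
    pmf /= pmf.sum()
    return IndividualDistribution(kind="discrete", status=dist.status, pmf=pmf)


# ----------------------------------------------------------------------
# non-parametric path
# ----------------------------------------------------------------------

def adjust_log_counts(
    counts: np.ndarray,
    covars: np.ndarray | None = None,
    ref_covars: np.ndarray | None = None,
    *,
    pseudocount: float = 1.0,
) -> IndividualDistribution:
    """Covariate-adjusted log expression values for the non-parametric path.

    Regresses ``log(count + pseudocount)`` on the covariates by ordinary least
    squares and returns, per cell, the fitted value at the reference covariates
    plus that cell's residual.
    """
    counts = np.asarray(counts, dtype=float)
    ylog = np.log(counts + pseudocount)
    _, X, xref = _prepare_design(ylog, covars, ref_covars)
    if counts.size < X.shape[1] + 2:
        return _failed("empirical_sample")
    beta, *_ = np.linalg.lstsq(X, ylog, rcond=None)
    resid = ylog - X @ beta
    adjusted = float(xref @ beta) + resid
    return IndividualDistribution(kind="empirical_sample", sample=adjusted)


def kde_density(
    sample: IndividualDistribution, grid: np.ndarray
) -> IndividualDistribution:
    """Gaussian KDE of an adjusted-expression sample, evaluated on ``grid``.

    Uses Silverman's rule-of-thumb bandwidth and renormalizes by the trapezoid
    rule so the density integrates to 1 on the grid. Fails when the sample is
    degenerate (fewer than two distinct values).
    """
    if sample.kind != "empirical_sample" or not sample.ok:
        raise ValueError("kde_density requires a valid empirical sample")
    x = np.asarray(sample.sample, dtype=float)
    if np.unique(x).size < 2:
        return _failed("continuous_density")
    grid = np.asarray(grid, dtype=float)
    kde = stats.gaussian_kde(x, bw_method="silverman")
    dens = kde(grid)
    area = np.trapezoid(dens, grid)
    if area <= 0:
        return _failed("continuous_density")
    return IndividualDistribution(
        kind="continuous_density", grid=grid, density=dens / area
    )


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth for a 1-d Gaussian KDE."""
    x = np.asarray(x, dtype=float)
    n = x.size
    return float(np.std(x, ddof=1) * (4.0 / (3.0 * n)) ** 0.2)


# ----------------------------------------------------------------------
# denoiser-aggregation path
# ----------------------------------------------------------------------

class CellDistributionTable:
    """Per-cell distribution parameters from an external denoiser.

    One row per (gene, cell). Two dialects: ZINB with columns
    ``gene, cell, mu, theta, pi`` (a deep-count autoencoder style output) or
    Poisson with columns ``gene, cell, lambda`` (a posterior-mean style
    output, stored internally as ZINB with pi=0, theta=inf).
    """

    REQUIRED_ZINB = {"gene", "cell", "mu", "theta", "pi"}
    REQUIRED_POISSON = {"gene", "cell", "lambda"}

    def __init__(self, table: pd.DataFrame):
        cols = set(table.columns)
        if self.REQUIRED_ZINB <= cols:
            df = table[["gene", "cell", "mu", "theta", "pi"]].copy()
        elif self.REQUIRED_POISSON <= cols:
            df = table[["gene", "cell"]].copy()
            df["mu"] = table["lambda"].astype(float)
            df["theta"] = np.inf
            df["pi"] = 0.0
        else:
            raise ValueError(
                "need columns (gene, cell, mu, theta, pi) or (gene, cell, lambda)"
            )
        df["gene"] = df["gene"].astype(str)
        df["cell"] = df["cell"].astype(str)
        if df.duplicated(["gene", "cell"]).any():
            raise ValueError("duplicated (gene, cell) rows")
        bad = (
            (df["mu"] <= 0)
            | (df["theta"] <= 0)
            | (df["pi"] < 0)
            | (df["pi"] >= 1)
            | ~np.isfinite(df["mu"])
        )
        if bad.any():
            raise ValueError(f"{int(bad.sum())} rows have out-of-range parameters")
        self._df = df.set_index(["gene", "cell"])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CellDistributionTable":
        return cls(pd.read_csv(path, sep="\t"))

    def params_for(self, gene: str, cells: Sequence[str]) -> pd.DataFrame:
        try:
            sub = self._df.loc[[(str(gene), str(c)) for c in cells]]
        except KeyError:
            have = set(self._df.loc[str(gene)].index) if str(gene) in self._df.index.get_level_values(0) else set()
            missing = [c for c in cells if str(c) not in have]
            raise KeyError(f"missing parameters for gene {gene!r}, cells {missing[:5]}")
        return sub.reset_index()


def aggregate_cell_distributions(
    table: CellDistributionTable, gene: str, cells: Sequence[str], K: int
) -> IndividualDistribution:
    """Equal-weight mixture of one individual's cell-level densities on 0..K.

    The individual density is ``(1/n_cells) * sum_c pmf_c(y)``; each cell's
    tail mass beyond K folds into bin K so the mixture sums to 1.
    """
    params = table.params_for(gene, cells)
    y = np.arange(K)
    acc = np.zeros(K + 1)
    for _, row in params.iterrows():
        p = zinb_pmf(y, row["pi"], row["mu"], row["theta"])
        tail = _nb_sf(K - 1, row["pi"], row["mu"], row["theta"])
        acc[:K] += p
        acc[K] += tail
    pmf = acc / len(params)
    pmf = np.clip(pmf, 0.0, None)
    pmf /= pmf.sum()
    return IndividualDistribution(kind="discrete", pmf=pmf)


def sample_from_cell_distributions(
    table: CellDistributionTable,
    gene: str,
    cells: Sequence[str],
    m: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw ``m`` counts from each cell's distribution (m x n_cells in total).

    The draws form a denoised pseudo-sample suitable for re-fitting an NB
    regression with cell-level covariates (each cell's covariates repeated
    m times).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(rng)
    params = table.params_for(gene, cells)
    out = np.empty(m * len(params), dtype=np.int64)
    for j, (_, row) in enumerate(params.iterrows()):
        pi, mu, theta = row["pi"], row["mu"], row["theta"]
        if np.isinf(theta):
            draws = rng.poisson(mu, size=m)
        else:
            draws = rng.negative_binomial(theta, theta / (theta + mu), size=m)
        if pi > 0:
            draws = np.where(rng.random(m) < pi, 0, draws)
        out[j * m : (j + 1) * m] = draws
    return out
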