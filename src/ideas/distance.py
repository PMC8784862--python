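"""Distances between individual expression distributions.

Two metrics are supported: the Jensen-Shannon divergence (symmetrized KL
against the average distribution, natural log, bounded by ln 2) and the
Wasserstein-1 (earth-mover) distance, which in one dimension is the integral
of the absolute difference of the two CDFs. Between-individual distances for
one gene are assembled into a symmetric n x n matrix that downstream testing
consumes.

Permutation p-values are rank-based over permuted pseudo-F values, so the JSD
log base (which rescales all distances by a constant) does not affect them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .distribution import (
    IndividualDistribution,
    choose_support,
    discretize,
    kde_density,
    silverman_bandwidth,
)

__all__ = ["DistanceMatrix", "jsd", "wasserstein1", "build_distance_matrix"]

#: distances below this are clamped to zero to absorb negative round-off
CLAMP = 1e-14

#: grid size for KDE-based JSD between empirical samples
KDE_GRID_POINTS = 512


@dataclass
class DistanceMatrix:
    """Symmetric matrix of between-individual distances for one gene."""

    gene_id: str
    matrix: np.ndarray
    metric: str
    individuals: list[str]

    def __post_init__(self) -> None:
        D = np.asarray(self.matrix, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(D, D.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(~np.isfinite(D)) or np.any(D < 0):
            raise ValueError("distances must be finite and non-negative")
        self.matrix = D

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix, index=self.individuals, columns=self.individuals).to_csv(
            path, sep="\t"
        )


def _as_density_pair(
    P: IndividualDistribution, Q: IndividualDistribution
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Common-support densities for P and Q; returns (p, q, grid-or-None)."""
    if P.kind == "discrete" and Q.kind == "discrete":
        n = max(P.pmf.size, Q.pmf.size)
        p = np.pad(P.pmf, (0, n - P.pmf.size))
        q = np.pad(Q.pmf, (0, n - Q.pmf.size))
        return p, q, None
    if P.kind == "continuous_density" and Q.kind == "continuous_density":
        if P.grid.size != Q.grid.size or not np.allclose(P.grid, Q.grid):
            raise ValueError("continuous densities must share a grid")
        return P.density, Q.density, P.grid
    raise ValueError(f"cannot compare kinds {P.kind!r} and {Q.kind!r}")


def _check_normalized(p: np.ndarray, grid: np.ndarray | None) -> None:
    total = np.trapezoid(p, grid) if grid is not None else p.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"unnormalized density (total {total})")


def jsd(P: IndividualDistribution, Q: IndividualDistribution) -> float:
    """Jensen-Shannon divergence, natural log, in [0, ln 2].

    JSD(P, Q) = [KL(P||M) + KL(Q||M)] / 2 with M the equal mixture of P and Q;
    terms where a density vanishes contribute zero. Empirical samples are
    routed through a shared-grid Gaussian KDE.
    """
    if P.kind == "empirical_sample" and Q.kind == "empirical_sample":
        P, Q = _kde_pair(P, Q)
    p, q, grid = _as_density_pair(P, Q)
    _check_normalized(p, grid)
    _check_normalized(q, grid)
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_p = np.where(p > 0, p * np.log(p / m), 0.0)
        t_q = np.where(q > 0, q * np.log(q / m), 0.0)
    if grid is not None:
        val = 0.5 * (np.trapezoid(t_p, grid) + np.trapezoid(t_q, grid))
    else:
        val = 0.5 * (t_p.sum() + t_q.sum())
    return 0.0 if val < CLAMP else float(min(val, np.log(2.0)))


def _kde_pair(
    P: IndividualDistribution, Q: IndividualDistribution
) -> tuple[IndividualDistribution, IndividualDistribution]:
    """Shared-grid KDE for two empirical samples (range +/- 3 bandwidths)."""
    xs = np.concatenate([P.sample, Q.sample])
    bw = max(silverman_bandwidth(P.sample), silverman_bandwidth(Q.sample))
    if bw <= 0:
        raise ValueError("degenerate samples: zero bandwidth")
    grid = np.linspace(xs.min() - 3 * bw, xs.max() + 3 * bw, KDE_GRID_POINTS)
    dP, dQ = kde_density(P, grid), kde_density(Q, grid)
    if not (dP.ok and dQ.ok):
        raise ValueError("KDE failed on a degenerate sample")
    return dP, dQ


def wasserstein1(P: IndividualDistribution, Q: IndividualDistribution) -> float:
    """Wasserstein-1 distance: integral of |F_P - F_Q|.

    Exact for discrete densities on the integers (sum of absolute CDF
    differences times unit bin width); empirical samples use the standard
    one-dimensional quantile formulation; continuous densities integrate the
    CDF difference by the trapezoid rule on their shared grid.
    """
    if P.kind == "empirical_sample" and Q.kind == "empirical_sample":
        val = stats.wasserstein_distance(P.sample, Q.sample)
        return 0.0 if val < CLAMP else float(val)
    p, q, grid = _as_density_pair(P, Q)
    _check_normalized(p, grid)
    _check_normalized(q, grid)
    if grid is None:
        val = float(np.abs(np.cumsum(p) - np.cumsum(q))[:-1].sum())
    else:
        # CDFs of grid densities via cumulative trapezoid weights
        from scipy.integrate import cumulative_trapezoid

        Fp = cumulative_trapezoid(p, grid, initial=0.0)
        Fq = cumulative_trapezoid(q, grid, initial=0.0)
        val = float(np.trapezoid(np.abs(Fp - Fq), grid))
    return 0.0 if val < CLAMP else val


_METRICS = {"jsd": jsd, "was": wasserstein1}


def build_distance_matrix(
    dists: Sequence[IndividualDistribution],
    metric: str,
    *,
    gene_id: str = "",
    individuals: Sequence[str] | None = None,
    support_cap: int | None = None,
) -> DistanceMatrix:
    """Pairwise distance matrix over individuals for one gene.

    Parametric fits are first discretized on a common support (JSD/Wasserstein
    need comparable densities); discrete, continuous and empirical inputs are
    compared directly. Any failed distribution makes the gene untestable and
    raises; callers convert that into a per-gene failure status.
    """
    metric = metric.lower()
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    n = len(dists)
    if n < 3:
        raise ValueError("need at least 3 individuals")
    if individuals is None:
        individuals = [str(i) for i in range(n)]
    bad = [individuals[i] for i, d in enumerate(dists) if not d.ok]
    if bad:
        raise ValueError(f"failed distribution for individuals {bad}")
    if all(d.kind == "parametric" for d in dists):
        K = choose_support(dists, cap=support_cap)
        dists = [discretize(d, K) for d in dists]
    fn = _METRICS[metric]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = fn(dists[i], dists[j])
    return DistanceMatrix(
        gene_id=gene_id, matrix=D, metric=metric, individuals=list(individuals)
    )
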