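"""Flanking-marker probability models for binary RIL genotypes.

Two conditional models drive imputation: an interior model giving
P(genotype | both flanking genotypes, distances) governed by a
recombination-rate-like parameter ``alpha`` >= 0, and an edge model
P(genotype | single neighbor) governed by a retention parameter
``beta`` in [0, 1],

    P(x = 1 | x0) = 1/2 + 1/2 * delta(x0) * beta**d,

with delta(x) = +1 for genotype 1 and -1 for genotype 0 and d the cM
distance to the neighbor.  The interior model is the bridge of a
stationary two-state Markov (telegraph) process whose agreement
probability across distance d is (1 + exp(-alpha*d)) / 2:

    P(x=1 | x0, x1) = (1 + d0*u) (1 + d1*v) / (2 (1 + d0*d1*u*v)),

u = exp(-alpha*d_left), v = exp(-alpha*d_right), d0 = delta(x0),
d1 = delta(x1).  At alpha = 0 agreeing flanks determine the genotype
with certainty; as alpha -> inf the flanks carry no information and the
probability tends to 1/2; for disagreeing flanks the alpha -> 0 limit
is linear interpolation in distance.

Both parameters are estimated by maximizing a pseudo log-likelihood:
the sum of full-conditional Bernoulli log-probabilities over every
(RIL, marker) whose conditioning neighbors are observed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .genmap import GeneticMap, GenotypeMatrix

__all__ = [
    "RecombParams",
    "FitReport",
    "HomogeneityTest",
    "EstimationError",
    "interior_probability",
    "edge_probability",
    "pseudo_loglik",
    "estimate_params",
    "homogeneity_lrt",
    "pearson_gof",
    "simulate_markov_genotypes",
]


class EstimationError(ValueError):
    """No usable terms / degenerate data for pseudo-ML estimation."""


@dataclass(frozen=True)
class RecombParams:
    """Interior rate ``alpha`` >= 0 and edge retention ``beta`` in [0, 1]."""

    alpha: float
    beta: float
    per_chromosome: dict | None = None

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must lie in [0, 1]")


@dataclass(frozen=True)
class FitReport:
    loglik: float
    n_terms: int
    estimate: RecombParams


@dataclass(frozen=True)
class HomogeneityTest:
    lrt: float
    df: int
    p_chisq: float
    p_bootstrap: float | None = None
    per_chromosome: dict | None = None


def _delta(x) -> np.ndarray:
    return 2.0 * np.asarray(x, dtype=float) - 1.0


def interior_probability(x0, x1, d_left, d_right, alpha):
    """P(x = 1 | left flank x0, right flank x1) under the bridge model.

    Broadcasts over array arguments; returns a scalar for scalar input.
    """
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    a = np.asarray(d_left, dtype=float)
    b = np.asarray(d_right, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("flanking distances must be strictly positive")
    alpha = float(alpha)
    if alpha < 0:
        raise ValueError("alpha must be >= 0")

    d0 = _delta(x0)
    d1 = _delta(x1)
    u = np.exp(-alpha * a)
    v = np.exp(-alpha * b)
    agree = d0 * d1 > 0

    with np.errstate(divide="ignore", invalid="ignore"):
        p_agree = (1.0 + d0 * u) * (1.0 + d1 * v) / (2.0 * (1.0 + u * v))
        # disagreeing flanks: expm1 keeps the alpha -> 0 limit stable
        num = np.where(
            d0 < 0,
            -np.expm1(-alpha * a) * (1.0 + v),
            (1.0 + u) * -np.expm1(-alpha * b),
        )
        den = -2.0 * np.expm1(-alpha * (a + b))
        p_disagree = np.where(
            den > 0,
            num / np.where(den > 0, den, 1.0),
            np.where(d0 < 0, a, b) / (a + b),  # exact alpha = 0 limit
        )
    out = np.where(agree, p_agree, p_disagree)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def edge_probability(x0, d, beta, side: str = "right"):
    """P(edge genotype = 1 | nearest neighbor genotype x0 at distance d).

    ``side`` records which chromosome end the marker sits on; the formula
    is symmetric, conditioning always on the single interior neighbor.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    beta = float(beta)
    if not (0.0 <= beta <= 1.0):
        raise ValueError("beta must lie in [0, 1]")
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distance must be strictly positive")
    out = 0.5 + 0.5 * _delta(x0) * beta**d
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# pseudo log-likelihood terms


def _interior_terms(G: GenotypeMatrix, gmap: GeneticMap, chrom=None):
    """Complete (left, mid, right) triples: x, x0, x1, d_left, d_right."""
    xs, x0s, x1s, dls, drs = [], [], [], [], []
    chroms = [chrom] if chrom is not None else list(gmap.chromosome_names)
    for c in chroms:
        sl = gmap.chromosome_slice(c)
        vals = G.values[:, sl]
        pos = gmap.positions[sl]
        m = vals.shape[1]
        for t in range(1, m - 1):
            ok = ~np.isnan(vals[:, t - 1 : t + 2]).any(axis=1)
            if not ok.any():
                continue
            xs.append(vals[ok, t])
            x0s.append(vals[ok, t - 1])
            x1s.append(vals[ok, t + 1])
            dls.append(np.full(ok.sum(), pos[t] - pos[t - 1]))
            drs.append(np.full(ok.sum(), pos[t + 1] - pos[t]))
    if not xs:
        return tuple(np.empty(0) for _ in range(5))
    return tuple(np.concatenate(a) for a in (xs, x0s, x1s, dls, drs))


def _edge_terms(G: GenotypeMatrix, gmap: GeneticMap, chrom=None):
    """Complete (edge, neighbor) pairs: x, x0, d."""
    xs, x0s, ds = [], [], []
    chroms = [chrom] if chrom is not None else list(gmap.chromosome_names)
    for c in chroms:
        sl = gmap.chromosome_slice(c)
        vals = G.values[:, sl]
        pos = gmap.positions[sl]
        m = vals.shape[1]
        if m < 2:
            continue
        for edge, nb in ((0, 1), (m - 1, m - 2)):
            ok = ~np.isnan(vals[:, edge]) & ~np.isnan(vals[:, nb])
            if not ok.any():
                continue
            xs.append(vals[ok, edge])
            x0s.append(vals[ok, nb])
            ds.append(np.full(ok.sum(), abs(pos[edge] - pos[nb])))
    if not xs:
        return tuple(np.empty(0) for _ in range(3))
    return tuple(np.concatenate(a) for a in (xs, x0s, ds))


def _bernoulli_loglik(x, p) -> float:
    with np.errstate(divide="ignore"):
        terms = np.where(x == 1.0, np.log(p), np.log1p(-p))
    return float(np.sum(terms))


def pseudo_loglik(
    G: GenotypeMatrix,
    gmap: GeneticMap,
    params: RecombParams,
    which: str,
    chrom=None,
) -> tuple[float, int]:
    """Pseudo log-likelihood and term count for the interior or edge model.

    Terms with any missing member are skipped (complete-triple/-pair
    analysis); raises :class:`EstimationError` when no term is usable.
    """
    if which == "interior":
        x, x0, x1, dl, dr = _interior_terms(G, gmap, chrom)
        if x.size == 0:
            raise EstimationError("no usable interior terms")
        p = interior_probability(x0, x1, dl, dr, params.alpha)
    elif which == "edge":
        x, x0, d = _edge_terms(G, gmap, chrom)
        if x.size == 0:
            raise EstimationError("no usable edge terms")
        p = edge_probability(x0, d, params.beta)
    else:
        raise ValueError("which must be 'interior' or 'edge'")
    return _bernoulli_loglik(x, p), int(x.size)


def _maximize_1d(negloglik, grid: np.ndarray, bounds: tuple[float, float]) -> float:
    """Bracket on a grid, then Brent-style bounded refinement (xatol 1e-8)."""
    vals = np.array([negloglik(g) for g in grid])
    i = int(np.nanargmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if lo == hi:
        return float(grid[i])
    res = optimize.minimize_scalar(
        negloglik,
        bounds=(max(lo, bounds[0]), min(hi, bounds[1])),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x) if res.fun <= vals[i] else float(grid[i])


_ALPHA_GRID = np.concatenate(([0.0], np.geomspace(1e-5, 5.0, 60)))
_BETA_GRID = np.linspace(0.0, 1.0, 61)


def _fit_alpha(G, gmap, chrom=None) -> tuple[float, float, int]:
    x, x0, x1, dl, dr = _interior_terms(G, gmap, chrom)
    if x.size == 0:
        raise EstimationError("no usable interior terms")

    def nll(a):
        return -_bernoulli_loglik(x, interior_probability(x0, x1, dl, dr, a))

    ahat = _maximize_1d(nll, _ALPHA_GRID, (0.0, np.inf))
    return ahat, -nll(ahat), int(x.size)


def _fit_beta(G, gmap, chrom=None) -> tuple[float, float, int]:
    x, x0, d = _edge_terms(G, gmap, chrom)
    if x.size == 0:
        raise EstimationError("no usable edge terms")

    def nll(b):
        return -_bernoulli_loglik(x, edge_probability(x0, d, b))

    bhat = _maximize_1d(nll, _BETA_GRID, (0.0, 1.0))
    return bhat, -nll(bhat), int(x.size)


def estimate_params(G: GenotypeMatrix, gmap: GeneticMap) -> tuple[FitReport, FitReport]:
    """Pseudo-ML estimates (alpha-hat, beta-hat) with their fit reports.

    The caller is expected to have excluded parental rows.  Returns the
    (interior, edge) reports; both carry the joint estimate.
    """
    ahat, ll_a, n_a = _fit_alpha(G, gmap)
    bhat, ll_b, n_b = _fit_beta(G, gmap)
    est = RecombParams(ahat, bhat)
    return FitReport(ll_a, n_a, est), FitReport(ll_b, n_b, est)


def simulate_markov_genotypes(
    gmap: GeneticMap, n_rils: int, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary telegraph chain at the map positions: the generative
    process whose bridge is the interior model.  Agreement probability
    between adjacent markers at distance d is (1 + exp(-rate*d)) / 2.
    """
    vals = np.empty((n_rils, gmap.n_markers))
    for c in gmap.chromosome_names:
        sl = gmap.chromosome_slice(c)
        pos = gmap.positions[sl]
        m = pos.size
        x = rng.integers(0, 2, size=n_rils).astype(float)
        vals[:, sl.start] = x
        for t in range(1, m):
            p_same = 0.5 * (1.0 + np.exp(-rate * (pos[t] - pos[t - 1])))
            stay = rng.random(n_rils) < p_same
            x = np.where(stay, x, 1.0 - x)
            vals[:, sl.start + t] = x
    return vals


def homogeneity_lrt(
    G: GenotypeMatrix,
    gmap: GeneticMap,
    which: str = "interior",
    bootstrap: tuple[int, int] | None = None,
) -> HomogeneityTest:
    """Test one shared parameter against one parameter per chromosome.

    LRT = -2 [ l(shared) - sum_c l(per-chromosome) ], referred to a
    chi-square with (C - 1) degrees of freedom; optionally a parametric
    bootstrap (B replicates regenerated under the fitted shared model,
    preserving the observed missingness pattern) supplies ``bootstrap=(B,
    seed)`` -> p_bootstrap.
    """
    fit_one = _fit_alpha if which == "interior" else _fit_beta

    usable = []
    for c in gmap.chromosome_names:
        try:
            est, ll, _ = fit_one(G, gmap, c)
        except EstimationError:
            warnings.warn(f"chromosome {c!r} has no usable {which} terms; dropped")
            continue
        usable.append((c, est, ll))
    if len(usable) < 2:
        raise EstimationError("need >= 2 chromosomes with usable terms")

    def observed_lrt(mat: GenotypeMatrix) -> tuple[float, dict]:
        per = {}
        ll_sep = 0.0
        for c, _, _ in usable:
            est_c, ll_c, _ = fit_one(mat, gmap, c)
            per[c] = est_c
            ll_sep += ll_c
        shared_est, _, _ = fit_one(mat, gmap)
        # shared model evaluated on the kept chromosomes only
        ll_shared = 0.0
        params = (
            RecombParams(shared_est, 1.0)
            if which == "interior"
            else RecombParams(0.0, shared_est)
        )
        for c, _, _ in usable:
            ll_c, _ = pseudo_loglik(mat, gmap, params, which, c)
            ll_shared += ll_c
        return max(-2.0 * (ll_shared - ll_sep), 0.0), per, shared_est

    lrt, per, shared_est = observed_lrt(G)
    df = len(usable) - 1
    p_chisq = float(stats.chi2.sf(lrt, df))

    p_boot = None
    if bootstrap is not None:
        B, seed = bootstrap
        rng = np.random.default_rng(seed)
        rate = shared_est if which == "interior" else -np.log(max(shared_est, 1e-12))
        mask = G.missing_mask
        count = 0
        for _ in range(B):
            sim = simulate_markov_genotypes(gmap, G.n_rils, rate, rng)
            sim[mask] = np.nan
            sim_G = GenotypeMatrix(sim, G.ril_ids, gmap)
            try:
                lrt_b, _, _ = observed_lrt(sim_G)
            except EstimationError:
                continue
            if lrt_b >= lrt:
                count += 1
        p_boot = count / B
    return HomogeneityTest(lrt, df, p_chisq, p_boot, per)


def pearson_gof(
    G: GenotypeMatrix, gmap: GeneticMap, params: RecombParams, which: str
) -> tuple[float, int, float]:
    """Pearson chi-squared goodness of fit of the fitted conditional model.

    statistic = sum (x - pi)^2 / (pi (1 - pi)) over usable terms; df is
    the term count minus the single fitted parameter.  A degenerate
    fitted probability (0 or 1) contributes 0 when the observation
    matches and +inf (lack of fit) when it does not.
    """
    if which == "interior":
        x, x0, x1, dl, dr = _interior_terms(G, gmap)
        if x.size == 0:
            raise EstimationError("no usable interior terms")
        p = np.atleast_1d(interior_probability(x0, x1, dl, dr, params.alpha))
    else:
        x, x0, d = _edge_terms(G, gmap)
        if x.size == 0:
            raise EstimationError("no usable edge terms")
        p = np.atleast_1d(edge_probability(x0, d, params.beta))
    x = np.atleast_1d(x)
    degen = (p <= 0.0) | (p >= 1.0)
    mismatch = degen & (x != np.round(p))
    if mismatch.any():
        stat = np.inf
    else:
        ok = ~degen
        stat = float(np.sum((x[ok] - p[ok]) ** 2 / (p[ok] * (1.0 - p[ok]))))
    df = int(x.size) - 1
    pval = float(stats.chi2.sf(stat, df)) if np.isfinite(stat) else 0.0
    return stat, df, pval
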