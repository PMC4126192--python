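"""Synthetic genotype/trait generator and ROC benchmarking harness.

Genotypes are simulated per chromosome as a one-dimensional Ising (binary
Markov) chain on a 1-cM lattice: adjacent lattice sites agree with
probability exp(eta) / (exp(eta) + exp(-eta)), the stationary marginal is
1/2, and chromosomes are independent.  The observed markers are read off
the lattice at the (rounded) map positions, so realistic inter-marker
distances enter through subsampling.  Defaults mirror a Bay x Sha-sized
RIL panel: 165 RILs on the 69-marker/5-chromosome map, coupling eta =
0.4, six true QTLs with alternating effects +-0.5, residual variance
sigma^2 in {0.5, 1, 2, 3}, 10% missingness that is either MCAR
(independent Bernoulli) or MAR (an Ising chain over the missingness
indicators with stronger coupling eta_MAR = 0.6, its external field
calibrated so the marginal missing probability matches the target rate).

``run_study`` benchmarks method combinations over replicates: each
selector is swept across its regularization path (or significance grid),
TP/FP/TN/FN against the true QTL set are recorded at every sweep point,
and TPR/FPR are averaged pointwise over replicates on a sweep grid fixed
once per study.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .genmap import GeneticMap, GenotypeMatrix, arabidopsis_like_map
from .impute import impute, nearest_marker_impute
from .recomb import RecombParams, estimate_params
from .select import (
    WlassoConfig,
    adaptive_lasso_baseline,
    default_lambda_grid,
    default_threshold_grid,
    lasso_baseline,
    multiple_regression_scan,
    wlasso_path,
)

__all__ = [
    "SimulationScenario",
    "ROCResult",
    "simulate_genotypes",
    "apply_missingness",
    "place_qtls",
    "simulate_trait",
    "run_study",
    "KNOWN_METHODS",
]

KNOWN_METHODS = (
    "model1",  # model-based imputation + wlasso
    "model2",  # model-based imputation + multiple regression scan
    "model3",  # nearest-marker imputation + wlasso
    "model4",  # nearest-marker imputation + multiple regression scan
    "lasso",  # model-based imputation, rounded genotypes, ordinary lasso
    "alasso_0.5",
    "alasso_1",
    "alasso_2",
)


@dataclass
class SimulationScenario:
    map: GeneticMap = field(default_factory=arabidopsis_like_map)
    n_rils: int = 165
    eta: float = 0.4
    missing_rate: float = 0.1
    mechanism: str = "MCAR"  # MCAR | MAR | none
    eta_mar: float = 0.6
    qtl_layout: str = "evenly_spaced"  # evenly_spaced | clustered
    n_qtl: int = 6
    effects: np.ndarray | None = None  # default +-0.5 alternating
    sigma2: float = 1.0
    n_reps: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effects is None:
            self.effects = 0.5 * (-1.0) ** np.arange(self.n_qtl)
        self.effects = np.asarray(self.effects, dtype=float)
        if self.effects.size != self.n_qtl:
            raise ValueError("effects length must equal n_qtl")
        if self.n_qtl > self.map.n_markers:
            raise ValueError("more QTLs than markers")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.mechanism not in ("MCAR", "MAR", "none"):
            raise ValueError("mechanism must be MCAR, MAR or none")


@dataclass
class ROCResult:
    method: str
    sweep: np.ndarray  # lambda grid or threshold grid
    tpr: np.ndarray  # mean over replicates, per sweep point
    fpr: np.ndarray
    confusion: np.ndarray  # n_reps x n_sweep x 4 (TP, FP, TN, FN)
    auc: float


def _lattice_map(gmap: GeneticMap) -> tuple[GeneticMap, np.ndarray]:
    """1-cM lattice covering each (rounded) chromosome plus the column
    indices of the observed markers on it."""
    names: list[str] = []
    chroms: list[str] = []
    pos: list[float] = []
    obs_cols: list[int] = []
    offset = 0
    for c in gmap.chromosome_names:
        sl = gmap.chromosome_slice(c)
        p = gmap.positions[sl]
        length = int(round(p[-1] - p[0]))
        sites = np.arange(length + 1)
        names.extend(f"{c}L{s:03d}" for s in sites)
        chroms.extend([c] * sites.size)
        pos.extend(sites.astype(float))
        rounded = np.round(p - p[0]).astype(int)
        obs_cols.extend(offset + np.minimum(rounded, length))
        offset += sites.size
    return GeneticMap(tuple(names), tuple(chroms), np.array(pos)), np.array(obs_cols)


def simulate_genotypes(
    scenario: SimulationScenario, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Simulate the 1-cM lattice chains and subsample the observed map.

    Returns (complete lattice matrix, complete observed-marker matrix).
    """
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    lat_map, obs_cols = _lattice_map(scenario.map)
    p_same = np.exp(scenario.eta) / (np.exp(scenario.eta) + np.exp(-scenario.eta))
    vals = np.empty((scenario.n_rils, lat_map.n_markers))
    for c in lat_map.chromosome_names:
        sl = lat_map.chromosome_slice(c)
        m = sl.stop - sl.start
        x = rng.integers(0, 2, size=scenario.n_rils).astype(float)
        vals[:, sl.start] = x
        stay = rng.random((scenario.n_rils, m - 1)) < p_same
        for t in range(1, m):
            x = np.where(stay[:, t - 1], x, 1.0 - x)
            vals[:, sl.start + t] = x
    ril_ids = tuple(f"RIL{i + 1:03d}" for i in range(scenario.n_rils))
    lattice = GenotypeMatrix(vals, ril_ids, lat_map)
    observed = GenotypeMatrix(vals[:, obs_cols].copy(), ril_ids, scenario.map)
    return lattice, observed


def _mar_field(rate: float, eta: float, _cache: dict = {}) -> float:
    """External field h making the stationary missing probability equal
    ``rate`` for the two-state chain P(next=1 | cur s) = sigmoid(2 (eta
    sigma_s + h)), sigma in {-1, +1}."""
    key = (round(rate, 12), round(eta, 12))
    if key in _cache:
        return _cache[key]

    def stationary(h: float) -> float:
        p11 = 1.0 / (1.0 + np.exp(-2.0 * (eta + h)))
        p10 = 1.0 / (1.0 + np.exp(-2.0 * (-eta + h)))
        return p10 / (1.0 - p11 + p10)

    h = optimize.brentq(lambda h: stationary(h) - rate, -30.0, 30.0, xtol=1e-12)
    _cache[key] = h
    return h


def apply_missingness(
    G: GenotypeMatrix,
    mechanism: str,
    rate: float,
    eta_mar: float = 0.6,
    rng: np.random.Generator | int | None = None,
) -> GenotypeMatrix:
    """Blank entries under MCAR (independent Bernoulli) or MAR (Ising
    chain over the missingness indicators along the marker order)."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must lie in [0, 1)")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    vals = G.values.copy()
    if mechanism == "none" or rate == 0.0:
        return GenotypeMatrix(vals, G.ril_ids, G.map)
    if mechanism == "MCAR":
        mask = rng.random(vals.shape) < rate
    elif mechanism == "MAR":
        h = _mar_field(rate, eta_mar)
        n, m = vals.shape
        mask = np.empty((n, m), dtype=bool)
        state = rng.random(n) < rate  # stationary start
        mask[:, 0] = state
        for t in range(1, m):
            sigma = np.where(state, 1.0, -1.0)
            p1 = 1.0 / (1.0 + np.exp(-2.0 * (eta_mar * sigma + h)))
            state = rng.random(n) < p1
            mask[:, t] = state
    else:
        raise ValueError("mechanism must be MCAR, MAR or none")
    vals[mask] = np.nan
    return GenotypeMatrix(vals, G.ril_ids, G.map)


def place_qtls(gmap: GeneticMap, layout: str, n_qtl: int) -> np.ndarray:
    """Deterministic true-QTL marker indices.

    evenly_spaced: floor((k + 1/2) M / n) over all M markers; clustered:
    ceil(n/2) markers in the first half of chromosome 1 and the rest in
    the first half of chromosome 2, evenly within each half.
    """
    M = gmap.n_markers
    if n_qtl > M:
        raise ValueError("more QTLs than markers")
    if layout == "evenly_spaced":
        return np.array([int((k + 0.5) * M / n_qtl) for k in range(n_qtl)])
    if layout == "clustered":
        chroms = gmap.chromosome_names
        if len(chroms) < 2:
            raise ValueError("clustered layout needs >= 2 chromosomes")
        counts = [int(np.ceil(n_qtl / 2)), n_qtl - int(np.ceil(n_qtl / 2))]
        out: list[int] = []
        for c, want in zip(chroms[:2], counts):
            sl = gmap.chromosome_slice(c)
            p = gmap.positions[sl]
            half = (p[0] + p[-1]) / 2.0
            cand = np.flatnonzero(p <= half) + sl.start
            if cand.size < want:
                raise ValueError(f"chromosome {c!r} first half too small")
            out.extend(cand[int((k + 0.5) * cand.size / want)] for k in range(want))
        return np.array(out)
    raise ValueError("layout must be 'evenly_spaced' or 'clustered'")


def simulate_trait(
    values: np.ndarray,
    qtl_idx: np.ndarray,
    effects: np.ndarray,
    sigma2: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Additive trait y_i = sum_k effects_k x_{i, qtl_k} + N(0, sigma^2)."""
    qtl_idx = np.asarray(qtl_idx)
    effects = np.asarray(effects, dtype=float)
    if qtl_idx.size != effects.size:
        raise ValueError("qtl_idx and effects must align")
    y = values[:, qtl_idx] @ effects
    if sigma2 > 0:
        y = y + rng.normal(0.0, np.sqrt(sigma2), size=values.shape[0])
    return y


def _confusion(selected: np.ndarray, truth: set, p: int) -> tuple[int, int, int, int]:
    sel = set(int(s) for s in selected)
    tp = len(sel & truth)
    fp = len(sel - truth)
    fn = len(truth - sel)
    tn = p - tp - fp - fn
    return tp, fp, tn, fn


def _auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    f = np.concatenate(([0.0], fpr, [1.0]))
    t = np.concatenate(([0.0], tpr, [1.0]))
    order = np.lexsort((t, f))
    return float(np.trapezoid(t[order], f[order]))


def _sweep_selections(method, X, W, y, lam_grid, thr_grid, wcfg):
    """Selected index sets at every sweep point for one replicate."""
    if method in ("model1", "model3"):
        fit = wlasso_path(X, y, W, replace(wcfg, lambda_grid=lam_grid))
        return [np.flatnonzero(c) for c in fit.coef_path]
    if method in ("model2", "model4"):
        _, sel, _ = multiple_regression_scan(X, y, thr_grid)
        return sel
    if method == "lasso":
        _, path = lasso_baseline(X, y, lam_grid)
        return [np.flatnonzero(c) for c in path]
    if method.startswith("alasso_"):
        gamma = float(method.split("_", 1)[1])
        _, path = adaptive_lasso_baseline(X, y, lam_grid, gamma)
        return [np.flatnonzero(c) for c in path]
    raise ValueError(f"unknown method {method!r}")


def run_study(
    scenario: SimulationScenario, methods: list[str]
) -> dict[str, ROCResult]:
    """Replicated benchmark of imputation x selection combinations.

    Per replicate: simulate genotypes, generate the trait from the
    complete observed-marker genotypes, impose missingness, impute per
    each method's imputer, sweep each selector, and score selections
    against the true QTL set.  TPR/FPR are averaged pointwise over
    replicates; the lambda grid is fixed once from a seeded reference
    replicate so every replicate shares the same sweep.
    """
    for m in methods:
        if m not in KNOWN_METHODS:
            raise ValueError(f"unknown method {m!r}; known: {KNOWN_METHODS}")
    if not methods:
        raise ValueError("empty method list")
    gmap = scenario.map
    p = gmap.n_markers
    truth_idx = place_qtls(gmap, scenario.qtl_layout, scenario.n_qtl)
    truth = set(int(t) for t in truth_idx)

    seeds = np.random.SeedSequence(scenario.seed).spawn(scenario.n_reps + 1)
    # common sweep grids, fixed from a reference replicate
    ref_rng = np.random.default_rng(seeds[-1])
    _, ref_obs = simulate_genotypes(scenario, ref_rng)
    ref_y = simulate_trait(
        ref_obs.values, truth_idx, scenario.effects, scenario.sigma2, ref_rng
    )
    lam_grid = default_lambda_grid(ref_obs.values, ref_y)
    thr_grid = default_threshold_grid()
    wcfg = WlassoConfig()

    needs_model = any(m in ("model1", "model2", "lasso") or m.startswith("alasso") for m in methods)
    needs_nearest = any(m in ("model3", "model4") for m in methods)

    conf: dict[str, list] = {m: [] for m in methods}
    for r in range(scenario.n_reps):
        rng = np.random.default_rng(seeds[r])
        _, obs = simulate_genotypes(scenario, rng)
        y = simulate_trait(
            obs.values, truth_idx, scenario.effects, scenario.sigma2, rng
        )
        G_miss = apply_missingness(
            obs, scenario.mechanism, scenario.missing_rate, scenario.eta_mar, rng
        )
        imputed = {}
        if needs_model:
            if scenario.mechanism == "none" or scenario.missing_rate == 0.0:
                # nothing to fill; parameters are irrelevant placeholders
                res = impute(G_miss, gmap, RecombParams(0.01, 0.95))
            else:
                rep_int, _ = estimate_params(G_miss, gmap)
                res = impute(G_miss, gmap, rep_int.estimate)
            imputed["model"] = res
        if needs_nearest:
            imputed["nearest"] = nearest_marker_impute(G_miss, gmap)

        for m in methods:
            imp = imputed["nearest" if m in ("model3", "model4") else "model"]
            X = imp.genotypes
            W = imp.weights
            sels = _sweep_selections(m, X, W, y, lam_grid, thr_grid, wcfg)
            conf[m].append([_confusion(s, truth, p) for s in sels])

    out: dict[str, ROCResult] = {}
    for m in methods:
        arr = np.array(conf[m], dtype=float)  # reps x sweep x 4
        tp, fp, tn, fn = arr[..., 0], arr[..., 1], arr[..., 2], arr[..., 3]
        tpr = (tp / (tp + fn)).mean(axis=0)
        fpr = (fp / (fp + tn)).mean(axis=0)
        sweep = thr_grid if m in ("model2", "model4") else lam_grid
        out[m] = ROCResult(m, sweep, tpr, fpr, arr.astype(int), _auc(fpr, tpr))
    return out
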