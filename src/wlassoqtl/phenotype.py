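"""Nuisance-covariate adjustment of raw trait observations.

Traits are measured repeatedly per RIL under varying conditions (age,
plate, temperature, ...).  An ordinary least-squares fit of the trait on
the nuisance covariates removes their effects; the residuals are the
responses fed to marker selection.  Rows with a missing trait value are
dropped (their share is assumed small enough for complete-case analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genmap import GenotypeMatrix, PhenotypeTable

__all__ = ["AdjustedPhenotype", "adjust", "aggregate_to_rils"]


@dataclass
class AdjustedPhenotype:
    residuals: np.ndarray
    ril_index: np.ndarray  # parallel RIL identifiers (object array)
    n_params: int
    sigma2_hat: float


def _design(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Treatment-contrast design: lexicographic levels, first as reference."""
    cols = []
    for name in covariates:
        col = df[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.astype(float).rename(name))
        else:
            cat = pd.Categorical(col.astype(str), categories=sorted(col.astype(str).unique()))
            dummies = pd.get_dummies(
                pd.Series(cat, index=df.index, name=name), prefix=name, drop_first=True
            ).astype(float)
            cols.append(dummies)
    X = pd.concat(cols, axis=1) if cols else pd.DataFrame(index=df.index)
    X.insert(0, "const", 1.0)
    return X


def adjust(
    pheno: PhenotypeTable,
    trait: str,
    covariates: list[str],
    drop_missing: bool = True,
) -> AdjustedPhenotype:
    """OLS adjustment: residual = observed - fitted, with an intercept."""
    df = pheno.data
    missing = [c for c in covariates + [trait] if c not in df.columns]
    if missing:
        raise KeyError(f"columns not in phenotype table: {missing}")
    if drop_missing:
        df = df[df[trait].notna()]
    X = _design(df, covariates)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the trailing columns that do not raise the rank
        bad = []
        r = 0
        for k in range(1, X.shape[1] + 1):
            rk = np.linalg.matrix_rank(X.iloc[:, :k].to_numpy())
            if rk == r:
                bad.append(X.columns[k - 1])
            r = rk
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad}")
    fit = sm.OLS(df[trait].to_numpy(dtype=float), X.to_numpy()).fit()
    resid = np.asarray(fit.resid)
    dof = len(resid) - X.shape[1]
    sigma2 = float(resid @ resid / dof) if dof > 0 else float("nan")
    return AdjustedPhenotype(
        residuals=resid,
        ril_index=df[pheno.ril_column].to_numpy(dtype=object),
        n_params=X.shape[1],
        sigma2_hat=sigma2,
    )


def aggregate_to_rils(
    adj: AdjustedPhenotype, G: GenotypeMatrix, mode: str = "replicate_rows"
) -> tuple[np.ndarray, np.ndarray]:
    """Map residuals to genotype rows.

    ``replicate_rows`` keeps one response per observation and points it at
    its RIL's genotype row (rows repeat); ``mean_per_ril`` averages the
    residuals of each RIL into a single response.  Returns (response
    vector, genotype-row index).
    """
    ril_to_row = {rid: i for i, rid in enumerate(G.ril_ids)}
    unknown = sorted({r for r in adj.ril_index if r not in ril_to_row})
    if unknown:
        raise KeyError(f"RILs absent from genotype matrix: {unknown}")
    rows = np.array([ril_to_row[r] for r in adj.ril_index], dtype=int)
    if mode == "replicate_rows":
        return adj.residuals.copy(), rows
    if mode == "mean_per_ril":
        order = []
        seen = set()
        for r in rows:  # deterministic: first-appearance order
            if r not in seen:
                seen.add(r)
                order.append(r)
        order = np.array(order, dtype=int)
        means = np.array([adj.residuals[rows == r].mean() for r in order])
        return means, order
    raise ValueError("mode must be 'replicate_rows' or 'mean_per_ril'")
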