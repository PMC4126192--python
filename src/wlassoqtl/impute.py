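"""Missing-genotype imputation with certainty weights.

Model-based imputation conditions each missing entry on its nearest
*observed* flanking markers: both sides present -> interior bridge model;
one side -> edge model; none (whole chromosome missing for that RIL) ->
uninformative fallback P = 1/2.  The imputed genotype is the rounded
probability and its certainty weight is

    w = 2 |P - 1/2|,

so w = 1 for observed entries (kept untouched) and w = 0 for a fully
uninformative imputation.  A nearest-marker baseline is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genmap import GeneticMap, GenotypeMatrix
from .recomb import RecombParams, edge_probability, interior_probability

__all__ = ["ImputationResult", "impute", "nearest_marker_impute"]

OBSERVED, MODEL_IMPUTED, EDGE_IMPUTED, FALLBACK = "observed", "model_imputed", "edge_imputed", "fallback"


@dataclass
class ImputationResult:
    """Completed genotypes plus per-entry probabilities and weights."""

    probabilities: np.ndarray  # RIL x marker, in [0, 1]
    genotypes: np.ndarray  # completed {0, 1}
    weights: np.ndarray  # certainty weights in [0, 1]
    provenance: np.ndarray  # object array of per-entry flags

    def completed(self, G: GenotypeMatrix) -> GenotypeMatrix:
        return GenotypeMatrix(self.genotypes.copy(), G.ril_ids, G.map)


def _result_shell(G: GenotypeMatrix):
    vals = G.values
    prob = np.where(np.isnan(vals), np.nan, vals).astype(float)
    geno = vals.copy()
    weights = np.where(np.isnan(vals), np.nan, 1.0)
    prov = np.full(vals.shape, OBSERVED, dtype=object)
    return prob, geno, weights, prov


def impute(
    G: GenotypeMatrix, gmap: GeneticMap, params: RecombParams
) -> ImputationResult:
    """Model-based imputation of every missing entry.

    Probability rounded to the genotype (ties at exactly 0.5 round down,
    deterministically — their weight is 0 so downstream influence is nil);
    weight = 2 |P - 1/2|.
    """
    prob, geno, weights, prov = _result_shell(G)
    vals = G.values
    for c in gmap.chromosome_names:
        sl = gmap.chromosome_slice(c)
        pos = gmap.positions[sl]
        block = vals[:, sl]
        for i in range(block.shape[0]):
            row = block[i]
            obs_idx = np.flatnonzero(~np.isnan(row))
            miss_idx = np.flatnonzero(np.isnan(row))
            if miss_idx.size == 0:
                continue
            for t in miss_idx:
                col = sl.start + t
                left = obs_idx[obs_idx < t]
                right = obs_idx[obs_idx > t]
                if left.size and right.size:
                    l, r = left[-1], right[0]
                    p = interior_probability(
                        row[l], row[r], pos[t] - pos[l], pos[r] - pos[t], params.alpha
                    )
                    prov[i, col] = MODEL_IMPUTED
                elif left.size:
                    l = left[-1]
                    p = edge_probability(row[l], pos[t] - pos[l], params.beta, "right")
                    prov[i, col] = EDGE_IMPUTED
                elif right.size:
                    r = right[0]
                    p = edge_probability(row[r], pos[r] - pos[t], params.beta, "left")
                    prov[i, col] = EDGE_IMPUTED
                else:
                    p = 0.5
                    prov[i, col] = FALLBACK
                prob[i, col] = p
                geno[i, col] = 1.0 if p > 0.5 else 0.0
                weights[i, col] = 2.0 * abs(p - 0.5)
    return ImputationResult(prob, geno, weights, prov)


def nearest_marker_impute(G: GenotypeMatrix, gmap: GeneticMap) -> ImputationResult:
    """Baseline: copy the genotype of the nearest observed marker (cM).

    Distance ties break toward the lower map position.  The baseline
    carries no certainty notion, so every filled entry gets weight 1;
    a RIL whose whole chromosome is missing falls back to genotype 0
    with weight 0.
    """
    prob, geno, weights, prov = _result_shell(G)
    vals = G.values
    for c in gmap.chromosome_names:
        sl = gmap.chromosome_slice(c)
        pos = gmap.positions[sl]
        block = vals[:, sl]
        for i in range(block.shape[0]):
            row = block[i]
            obs_idx = np.flatnonzero(~np.isnan(row))
            miss_idx = np.flatnonzero(np.isnan(row))
            if miss_idx.size == 0:
                continue
            for t in miss_idx:
                col = sl.start + t
                if obs_idx.size == 0:
                    prob[i, col] = 0.5
                    geno[i, col] = 0.0
                    weights[i, col] = 0.0
                    prov[i, col] = FALLBACK
                    continue
                dist = np.abs(pos[obs_idx] - pos[t])
                best = np.flatnonzero(dist == dist.min())
                j = obs_idx[best[0]]  # obs_idx sorted -> lower position wins ties
                g = row[j]
                prob[i, col] = g
                geno[i, col] = g
                weights[i, col] = 1.0
                prov[i, col] = "nearest"
    return ImputationResult(prob, geno, weights, prov)
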