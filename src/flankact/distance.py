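"""Logistic model of activation probability versus enhancer-to-TLS distance.

pi(x) = exp(b0 + b1*x) / (1 + exp(b0 + b1*x)), with x the distance in bp.
The coefficients published for the rice activation-tagging training set
(b0 = 1.448, b1 = -7.099e-5) ship as a frozen default model so prediction
works without refitting; training refits on the data at hand.  pi(x) also
serves as a per-record weight on the feature encodings, so that identical
promoter sequences observed at different insertion distances map to
distinct feature vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

# frozen default coefficients (rice activation-tagging fit)
DEFAULT_BETA0 = 1.448
DEFAULT_BETA1 = -7.099e-05

# bin edges (bp) for the activation-ratio-by-distance analysis
DEFAULT_BIN_EDGES = (0, 2_000, 5_000, 10_000, 20_000, 30_000)


@dataclass
class DistanceLogisticModel:
    beta0: float = DEFAULT_BETA0
    beta1: float = DEFAULT_BETA1
    n: int | None = None
    converged: bool = True

    def probability(self, x) -> np.ndarray | float:
        return activation_probability(self, x)


def fit_distance_logistic(
    distances, labels
) -> DistanceLogisticModel:
    """Maximum-likelihood logistic fit of activation on distance.

    ``labels`` may be Ac/NAc strings or 0/1.  Non-convergence is flagged on
    the returned model but coefficients are still reported.
    """
    import statsmodels.api as sm

    x = np.asarray(distances, dtype=float)
    y = _as_binary(labels)
    if len(x) < 10:
        raise ValueError("need at least 10 records to fit the distance model")
    if y.min() == y.max():
        raise ValueError("both classes must be present to fit the logistic")
    if np.ptp(x) == 0:
        raise ValueError("distances are constant; design is degenerate")
    X = sm.add_constant(x)
    res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    converged = bool(res.mle_retvals.get("converged", True))
    return DistanceLogisticModel(
        beta0=float(res.params[0]),
        beta1=float(res.params[1]),
        n=len(x),
        converged=converged,
    )


def activation_probability(model: DistanceLogisticModel, x):
    """Evaluate pi(x); strictly decreasing in x when beta1 < 0."""
    eta = model.beta0 + model.beta1 * np.asarray(x, dtype=float)
    out = 1.0 / (1.0 + np.exp(-eta))
    if out.ndim == 0:
        return float(out)
    return out


def weight_feature_vector(v: np.ndarray, p: float) -> np.ndarray:
    """Elementwise scaling of a feature vector by the activation probability."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"weight must be in (0, 1], got {p}")
    return np.asarray(v, dtype=float) * p


def activation_ratio_by_distance(
    distances, labels, bin_edges=DEFAULT_BIN_EDGES
) -> pd.DataFrame:
    """Per-bin record count and activation fraction (NaN for empty bins)."""
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    x = np.asarray(distances, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative distance encountered")
    y = _as_binary(labels)
    idx = np.digitize(x, edges[1:-1], right=False)
    rows = []
    for b in range(len(edges) - 1):
        in_bin = idx == b
        n = int(in_bin.sum())
        frac = float(y[in_bin].mean()) if n else np.nan
        rows.append(
            {
                "bin_start": edges[b],
                "bin_end": edges[b + 1],
                "n": n,
                "activation_fraction": frac,
            }
        )
    return pd.DataFrame(rows)


def factor_association(records: pd.DataFrame, factor: str):
    """Contingency table of ``factor`` levels vs Ac/NAc with chi-square p.

    ``records`` needs columns ``label`` and the factor column
    (gene_orientation / tdna_orientation / location_class).
    Returns (table: DataFrame, chi2: float, p: float).
    """
    if factor not in records.columns:
        raise KeyError(f"records lack a {factor!r} column")
    table = pd.crosstab(records[factor], records["label"])
    if table.shape[0] < 2:
        raise ValueError(f"factor {factor!r} has a single level; no test possible")
    chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return table, float(chi2), float(p)


def _as_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        return (arr == "Ac").astype(float)
    return arr.astype(float)
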