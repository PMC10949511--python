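"""Redundancy analysis (RDA) of community data on operational parameters,
plus single parameter-taxon correlations over time.

RDA regresses the (Hellinger-transformed, column-centered) community
matrix Y on standardized explanatory variables X, then decomposes the
fitted values: canonical eigenvalues are the spectrum of Yhat' Yhat /
(n-1), the constrained proportion is |Yhat|^2 / |Y|^2, and significance
comes from permuting sample rows of X against the pseudo-F statistic.
Parameter importance is the marginal (single-variable) constrained
proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RdaResult:
    """Constrained-ordination output."""

    eigenvalues: np.ndarray  # canonical, non-increasing
    constrained_proportion: float
    sample_scores: pd.DataFrame  # samples x axes
    response_scores: pd.DataFrame  # taxa x axes
    biplot_scores: pd.DataFrame  # parameters x axes
    marginal: pd.DataFrame  # per parameter: proportion, pseudo_F, p_value; ranked
    global_p: float
    pseudo_f: float


def hellinger(y: np.ndarray) -> np.ndarray:
    """Square root of row-closed relative abundances."""
    totals = y.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("Hellinger transform needs positive row totals")
    return np.sqrt(y / totals)


def _pseudo_f(y: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """(pseudo-F, SS_fit, SS_res) for centered y on standardized x via QR."""
    n, p = x.shape
    q, _ = np.linalg.qr(x)
    yhat = q @ (q.T @ y)
    ss_fit = float((yhat**2).sum())
    ss_res = float(((y - yhat) ** 2).sum())
    df_res = n - p - 1
    if ss_res <= 0 or df_res <= 0:
        return np.inf, ss_fit, ss_res
    return (ss_fit / p) / (ss_res / df_res), ss_fit, ss_res


def rda(
    Y: pd.DataFrame,
    X: pd.DataFrame,
    transform: str | None = "hellinger",
    n_perm: int = 999,
    seed: int = 0,
    n_axes: int | None = None,
) -> RdaResult:
    """Redundancy analysis of responses ``Y`` (samples x taxa) on
    parameters ``X`` (samples x parameters).

    ``transform`` is ``"hellinger"`` (default) or ``None``.  X columns
    are z-standardized; collinear or constant columns raise.  Permutation
    tests (``n_perm`` permutations of X's rows, seeded) give a global
    p-value and per-parameter marginal p-values.
    """
    if list(Y.index) != list(X.index):
        raise ValueError("Y and X must be aligned on the same samples")
    n, q = Y.shape
    p = X.shape[1]
    if n <= p + 1:
        raise ValueError(f"need n > p+1 samples; got n={n}, p={p}")
    y = Y.to_numpy(dtype=float)
    if transform == "hellinger":
        y = hellinger(y)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    y = y - y.mean(axis=0, keepdims=True)

    x = X.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [c for c, s in zip(X.columns, sd) if s == 0]
        raise ValueError(f"constant parameter column(s): {bad}")
    x = (x - x.mean(axis=0, keepdims=True)) / sd
    if np.linalg.matrix_rank(x) < p:
        corr = np.corrcoef(x, rowvar=False)
        np.fill_diagonal(corr, 0)
        i, j = np.unravel_index(np.abs(corr).argmax(), corr.shape)
        raise ValueError(
            f"rank-deficient parameter matrix; most collinear pair: "
            f"{X.columns[i]!r} and {X.columns[j]!r}"
        )

    f_obs, ss_fit, _ = _pseudo_f(y, x)
    ss_total = float((y**2).sum())
    constrained = ss_fit / ss_total if ss_total > 0 else 0.0

    # canonical decomposition of the fitted values
    qmat, _ = np.linalg.qr(x)
    yhat = qmat @ (qmat.T @ y)
    u, s, vt = np.linalg.svd(yhat, full_matrices=False)
    eig = s**2 / (n - 1)
    k = min(p, q, (eig > 1e-12 * max(eig[0], 1e-300)).sum())
    if n_axes is not None:
        k = min(k, n_axes)
    axes = [f"RDA{i + 1}" for i in range(k)]
    sample_scores = pd.DataFrame(u[:, :k] * s[:k], index=Y.index, columns=axes)
    response_scores = pd.DataFrame(vt[:k].T, index=Y.columns, columns=axes)
    biplot = pd.DataFrame(
        (x.T @ u[:, :k]) / np.sqrt((x**2).sum(axis=0))[:, None],
        index=X.columns,
        columns=axes,
    )

    rng = np.random.default_rng(seed)
    perms = [rng.permutation(n) for _ in range(n_perm)]
    exceed = sum(1 for idx in perms if _pseudo_f(y, x[idx])[0] >= f_obs)
    global_p = (1 + exceed) / (1 + n_perm)

    rows = []
    for ci, col in enumerate(X.columns):
        xi = x[:, [ci]]
        f_i, ss_i, _ = _pseudo_f(y, xi)
        exceed_i = sum(1 for idx in perms if _pseudo_f(y, xi[idx])[0] >= f_i)
        rows.append(
            {
                "parameter": col,
                "marginal_proportion": ss_i / ss_total if ss_total > 0 else 0.0,
                "pseudo_F": f_i,
                "p_value": (1 + exceed_i) / (1 + n_perm),
            }
        )
    marginal = (
        pd.DataFrame(rows)
        .sort_values("marginal_proportion", ascending=False)
        .set_index("parameter")
    )
    return RdaResult(
        eigenvalues=eig,
        constrained_proportion=constrained,
        sample_scores=sample_scores,
        response_scores=response_scores,
        biplot_scores=biplot,
        marginal=marginal,
        global_p=global_p,
        pseudo_f=f_obs,
    )


def param_taxon_correlation(
    series_x: pd.Series,
    series_y: pd.Series,
    method: str = "spearman",
) -> dict:
    """Correlation between an operational parameter and a taxon's
    abundance over aligned time points.

    Returns coefficient, two-sided p, sign and n; constant series yield
    NaN with ``undefined=True``.
    """
    x = series_x.to_numpy(dtype=float)
    y = series_y.reindex(series_x.index).to_numpy(dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 4:
        raise ValueError(f"need at least 4 aligned points, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        return {"coefficient": np.nan, "p_value": np.nan, "sign": None, "n": n, "undefined": True}
    if method == "spearman":
        res = stats.spearmanr(x, y)
    elif method == "pearson":
        res = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    coef = float(res.statistic if hasattr(res, "statistic") else res.correlation)
    return {
        "coefficient": coef,
        "p_value": float(res.pvalue),
        "sign": "+" if coef >= 0 else "-",
        "n": n,
        "undefined": False,
    }
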