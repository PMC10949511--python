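"""Sloan neutral community model: occurrence frequency vs abundance.

The model predicts the fraction of local communities in which a taxon is
detected from its metacommunity mean relative abundance p.  With N reads
per local community and migration rate m, the stationary distribution of
a taxon's local relative abundance is Beta(Nmp, Nm(1-p)), so the
predicted occurrence frequency above a detection limit d is

    F(p) = 1 - I_d(Nmp, Nm(1-p))

with I the regularized incomplete beta function.  Nm (metacommunity size
times immigration) is the single free parameter, estimated by bounded
least squares of observed occupancies on F(p); fit quality is the
ordinary R^2 and 95% confidence intervals come from bootstrap resampling
of taxa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .tables import OtuTable, relative_abundance


@dataclass
class NcmInput:
    """Per-taxon (mean relative abundance, occupancy) pairs plus design
    constants: reads per sample N, detection limit d, sample count."""

    taxon_ids: list[str]
    p: np.ndarray  # mean relative abundance, in (0, 1]
    f: np.ndarray  # occurrence frequency, in (0, 1]
    N: int
    d: float
    n_samples: int


@dataclass
class NcmFit:
    """Fitted neutral model."""

    m_hat: float
    Nm: float
    r2: float
    n_taxa: int
    N: int
    d: float
    n_samples: int
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    per_taxon: pd.DataFrame | None = None  # p, f, predicted, lower, upper, class

    @property
    def class_counts(self) -> dict[str, int]:
        if self.per_taxon is None:
            return {}
        return self.per_taxon["class"].value_counts().to_dict()


def build_ncm_input(table: OtuTable, detection_limit: float | None = None) -> NcmInput:
    """Derive (p_i, f_i) from a rarefied table.

    p_i is the mean of per-sample relative abundances, f_i the fraction
    of samples with a non-zero count.  Taxa absent everywhere are
    excluded.  N is the rounded mean sample total; d defaults to 1/N
    (one read).  Unequal sample totals beyond 1% of their mean draw a
    warning — the model assumes a common local community size.
    """
    if table.n_samples < 2:
        raise ValueError("neutral-model input needs at least 2 samples")
    totals = table.sample_totals().to_numpy()
    mean_total = totals.mean()
    if np.abs(totals - mean_total).max() > 0.01 * mean_total:
        warnings.warn(
            "sample totals differ by more than 1% of their mean; rarefy first for a clean fit",
            stacklevel=2,
        )
    rel = relative_abundance(table)
    p = rel.mean(axis=1).to_numpy()
    f = (table.counts.to_numpy() > 0).mean(axis=1)
    keep = f > 0
    N = int(round(mean_total))
    d = 1.0 / N if detection_limit is None else detection_limit
    return NcmInput(
        taxon_ids=[t for t, k in zip(table.taxon_ids, keep) if k],
        p=p[keep],
        f=f[keep],
        N=N,
        d=d,
        n_samples=table.n_samples,
    )


def predict_occurrence(p, m: float, N: int, d: float):
    """Predicted occurrence frequency F = 1 - I_d(Nmp, Nm(1-p)).

    ``p`` may be a scalar or array in (0, 1); m in (0, 1]; d in (0, 1).
    """
    p = np.asarray(p, dtype=float)
    nm = N * m
    a = nm * p
    b = nm * (1.0 - p)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("Nm*p and Nm*(1-p) must both be positive")
    return stats.beta.sf(d, a, b)


def _sse(m: float, p: np.ndarray, f: np.ndarray, N: int, d: float) -> float:
    resid = f - predict_occurrence(p, m, N, d)
    return float(resid @ resid)


def _fit_m(p: np.ndarray, f: np.ndarray, N: int, d: float) -> float:
    res = optimize.minimize_scalar(
        _sse,
        bounds=(1e-6, 1.0),
        args=(p, f, N, d),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:  # pragma: no cover - bounded Brent rarely fails
        raise RuntimeError(f"migration-rate optimization failed: {res.message}")
    return float(res.x)


def _wilson_bounds(F: np.ndarray, n: int, z: float = 1.959963984540054):
    """Wilson score interval for a proportion F observed over n samples."""
    denom = 1.0 + z**2 / n
    center = (F + z**2 / (2 * n)) / denom
    half = (z / denom) * np.sqrt(F * (1.0 - F) / n + z**2 / (4 * n**2))
    return center - half, center + half


def fit_ncm(inp: NcmInput, n_boot: int = 1000, seed: int = 0) -> NcmFit:
    """Fit the neutral model and classify taxa against the 95% bands.

    m is estimated by bounded scalar least squares on (1e-6, 1]; R^2 is
    1 - SSE/SST on occupancies.  ``n_boot`` bootstrap resamples of taxa
    (with replacement) give percentile CIs for m, Nm and R^2; pass
    ``n_boot=0`` to skip.  A taxon is *above* (or *below*) the model if
    its occupancy exceeds (falls below) the Wilson 95% score bounds of
    the prediction at the study's sample count, otherwise *within*.
    """
    p, f = inp.p, inp.f
    if len(p) < 20:
        warnings.warn(f"only {len(p)} taxa; neutral-model fit will be unstable", stacklevel=2)
    m_hat = _fit_m(p, f, inp.N, inp.d)
    sse = _sse(m_hat, p, f, inp.N, inp.d)
    sst = float(((f - f.mean()) ** 2).sum())
    if sst == 0:
        warnings.warn("occupancies are constant; R^2 undefined", stacklevel=2)
        r2 = np.nan
    else:
        r2 = 1.0 - sse / sst

    ci: dict[str, tuple[float, float]] = {}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(p)
        ms = np.empty(n_boot)
        r2s = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            pb, fb = p[idx], f[idx]
            mb = _fit_m(pb, fb, inp.N, inp.d)
            ms[b] = mb
            sst_b = float(((fb - fb.mean()) ** 2).sum())
            r2s[b] = 1.0 - _sse(mb, pb, fb, inp.N, inp.d) / sst_b if sst_b > 0 else np.nan
        lo, hi = np.nanpercentile(ms, [2.5, 97.5])
        ci["m"] = (float(lo), float(hi))
        ci["Nm"] = (float(lo * inp.N), float(hi * inp.N))
        r2lo, r2hi = np.nanpercentile(r2s, [2.5, 97.5])
        ci["r2"] = (float(r2lo), float(r2hi))

    predicted = predict_occurrence(p, m_hat, inp.N, inp.d)
    lower, upper = _wilson_bounds(predicted, inp.n_samples)
    cls = np.where(f > upper, "above", np.where(f < lower, "below", "within"))
    per_taxon = pd.DataFrame(
        {
            "p": p,
            "f": f,
            "predicted": predicted,
            "lower": lower,
            "upper": upper,
            "class": cls,
        },
        index=pd.Index(inp.taxon_ids, name="taxon_id"),
    )
    return NcmFit(
        m_hat=m_hat,
        Nm=m_hat * inp.N,
        r2=r2,
        n_taxa=len(p),
        N=inp.N,
        d=inp.d,
        n_samples=inp.n_samples,
        ci=ci,
        per_taxon=per_taxon,
    )


def prediction_curve(fit: NcmFit, n_points: int = 200) -> pd.DataFrame:
    """Model curve F(p) with Wilson 95% bands over a log-spaced p grid."""
    p_min = max(fit.d / 10, 1e-9)
    grid = np.logspace(np.log10(p_min), 0, n_points, endpoint=False)
    pred = predict_occurrence(grid, fit.m_hat, fit.N, fit.d)
    lower, upper = _wilson_bounds(pred, fit.n_samples)
    return pd.DataFrame({"p": grid, "predicted": pred, "lower": lower, "upper": upper})
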