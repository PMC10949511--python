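"""Alpha diversity, Bray-Curtis dissimilarity and principal coordinates.

Alpha metrics are the standard richness / Shannon / Pielou triple.  PCoA
uses Gower double-centering and reports negative eigenvalues as-is (no
Lingoes/Cailliez correction); coordinate axes are restricted to positive
eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .tables import OtuTable, ValidationError, relative_abundance


def alpha_diversity(table: OtuTable) -> pd.DataFrame:
    """Per-sample richness, Shannon H (nats) and Pielou evenness.

    Evenness is H / ln(richness); for single-taxon samples it is
    undefined and reported as NaN.
    """
    rel = relative_abundance(table).to_numpy()
    richness = (rel > 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(rel > 0, rel * np.log(rel), 0.0)
        shannon = -plogp.sum(axis=0)
        evenness = np.where(richness > 1, shannon / np.log(richness), np.nan)
    return pd.DataFrame(
        {"richness": richness, "shannon": shannon, "pielou_evenness": evenness},
        index=pd.Index(table.sample_ids, name="sample_id"),
    )


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples.

    Computed on relative abundances, which after rarefaction coincides
    with the count-based definition.
    """
    if table.n_samples < 2:
        raise ValidationError("Bray-Curtis needs at least 2 samples")
    rel = relative_abundance(table).to_numpy().T  # samples x taxa
    condensed = pdist(rel, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


@dataclass
class OrdinationResult:
    """PCoA output: sample coordinates on positive axes plus the full
    eigenvalue spectrum (negative eigenvalues included, uncorrected)."""

    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    proportion_explained: np.ndarray  # per retained axis


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinates analysis of a distance matrix.

    Gower centering of -D^2/2 followed by symmetric eigendecomposition.
    Axes are the eigenvectors of positive eigenvalues scaled by sqrt(λ);
    ``n_axes`` caps how many are returned.  Proportion explained divides
    by the sum of positive eigenvalues.
    """
    if n_axes is not None and n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    d = dm.data
    n = d.shape[0]
    a = -0.5 * d**2
    centerer = np.eye(n) - np.ones((n, n)) / n
    g = centerer @ a @ centerer
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-10, 1e-10 * abs(eigvals[0])) if n else 0.0
    positive = eigvals > tol
    k = int(positive.sum())
    if n_axes is not None:
        k = min(k, n_axes)
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    pos_sum = eigvals[positive].sum()
    prop = eigvals[:k] / pos_sum if pos_sum > 0 else np.zeros(k)
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords,
            index=pd.Index(list(dm.ids), name="sample_id"),
            columns=[f"PCo{i + 1}" for i in range(k)],
        ),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )
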