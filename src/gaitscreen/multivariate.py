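"""PCA utilities: coordination components and the body-size score.

Two uses of principal component analysis in the workflow:

* the 96 coordination variables per stride are reduced to the first 12
  coordination components (CC) for statistical analysis;
* subject size is the first principal component of stride-mean skeleton
  segment lengths ("size PCA"), sign-fixed so larger animals score higher.

Columns are not standardized: coordination inputs are already
amplitude-normalized and dimensionless, and segment lengths share the
meter scale, so raw covariance PCA preserves their relative weighting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

N_COORDINATION_COMPONENTS = 12


@dataclass
class PCAModel:
    """A fitted, centered PCA with a deterministic sign convention.

    The sign of each loading vector is fixed so its largest-magnitude
    entry is positive, making scores reproducible across fits.
    """

    center: np.ndarray
    loadings: np.ndarray  # (n_components, n_features), orthonormal rows
    explained_variance_ratio: np.ndarray  # over all fitted components
    n_components: int
    feature_names: list[str] = field(default_factory=list)

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.center) @ self.loadings[: self.n_components].T

    def inverse_transform(self, scores) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        k = scores.shape[-1]
        return scores @ self.loadings[:k] + self.center

    def save(self, path) -> None:
        payload = {
            "center": self.center.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "n_components": self.n_components,
            "feature_names": self.feature_names,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "PCAModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            center=np.asarray(payload["center"]),
            loadings=np.asarray(payload["loadings"]),
            explained_variance_ratio=np.asarray(payload["explained_variance_ratio"]),
            n_components=int(payload["n_components"]),
            feature_names=list(payload["feature_names"]),
        )


def fit_pca(matrix, n_components: int, feature_names: list[str] | None = None) -> PCAModel:
    """Centered PCA of a (n_observations, n_features) matrix.

    All components are fitted (so explained-variance fractions sum to 1);
    ``n_components`` only sets how many are used by ``transform``.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 observations")
    if not np.any(X.std(axis=0) > 0):
        raise ValueError("zero-variance matrix: PCA undefined")
    pca = PCA(n_components=min(X.shape), svd_solver="full")
    pca.fit(X)
    loadings = pca.components_.copy()
    for i, row in enumerate(loadings):  # deterministic sign convention
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            loadings[i] = -row
    return PCAModel(
        center=pca.mean_,
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_components=n_components,
        feature_names=feature_names or [],
    )


def coordination_pca(
    coordination_matrix, n_components: int = N_COORDINATION_COMPONENTS
) -> tuple[np.ndarray, PCAModel]:
    """Scores of the first coordination components (default 12).

    ``coordination_matrix`` has one row per stride and 96 columns.  Raises
    when fewer than ``n_components`` components carry variance.
    """
    X = np.asarray(coordination_matrix, dtype=float)
    if X.shape[1] != 96:
        raise ValueError(f"coordination matrix must have 96 columns, got {X.shape[1]}")
    model = fit_pca(X, n_components)
    nonzero = int((model.explained_variance_ratio > 1e-12).sum())
    if nonzero < n_components:
        raise ValueError(f"only {nonzero} non-degenerate components available, need {n_components}")
    return model.transform(X), model


def size_score(segment_length_table: pd.DataFrame) -> tuple[pd.Series, PCAModel]:
    """Body-size score per subject-recording from the size PCA.

    ``segment_length_table`` holds stride-mean skeleton segment lengths
    (meters), one row per subject-recording, one column per segment.  The
    score is the first principal component, sign-fixed so that larger
    animals (larger total segment length) score higher.
    """
    df = segment_length_table
    if df.isna().any().any():
        missing = df.columns[df.isna().any()].tolist()
        raise ValueError(f"missing segment lengths: {missing}")
    model = fit_pca(df.to_numpy(), n_components=1, feature_names=list(df.columns))
    scores = model.transform(df.to_numpy())[:, 0]
    total = df.to_numpy().sum(axis=1)
    if np.std(scores) > 0 and np.corrcoef(scores, total)[0, 1] < 0:
        model.loadings[0] = -model.loadings[0]
        scores = -scores
    return pd.Series(scores, index=df.index, name="size"), model
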