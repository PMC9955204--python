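"""Time-lagged independent component analysis (tICA) with VAMP2 scoring
and residue-level feature-contribution thresholding.

tICA finds the linear combinations of input features with the slowest
decorrelation: after mean removal it solves the symmetrized generalized
eigenproblem ``Cτ v = λ C0 v`` where C0 is the instantaneous and Cτ the
time-lagged covariance.  Eigenvalues close to 1 correspond to slow
collective modes; the associated eigenvectors give per-feature loadings
whose residue-level maxima drive the contribution-threshold selection
(default threshold 0.195, which in the Cas9 analysis is the largest value
that retains the catalytically important residues).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .geometry import FeatureMatrix

__all__ = [
    "TICAModel",
    "estimate_tica",
    "project",
    "feature_contributions",
    "vamp2_score",
    "SingularCovarianceError",
]


class SingularCovarianceError(np.linalg.LinAlgError):
    pass


@dataclass
class TICAModel:
    mean: np.ndarray
    c0: np.ndarray
    ctau: np.ndarray
    lag: int
    eigenvalues: np.ndarray
    components: np.ndarray  # (n_features, n_dims), C0-orthonormal columns
    feature_labels: list
    n_dims: int
    training_projection: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")
        if np.any(np.abs(self.eigenvalues) > 1.0 + 1e-6):
            raise ValueError("tICA eigenvalues must satisfy |λ| ≤ 1 + 1e-6")

    def save(self, path) -> None:
        """Serialize to a self-describing JSON archive (labels included)."""
        import json

        payload = {
            "format": "casdyn.tica/1",
            "lag": int(self.lag),
            "n_dims": int(self.n_dims),
            "mean": self.mean.tolist(),
            "c0": self.c0.tolist(),
            "ctau": self.ctau.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "components": self.components.tolist(),
            "feature_labels": [list(lab) for lab in self.feature_labels],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "TICAModel":
        import json

        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "casdyn.tica/1":
            raise ValueError(f"not a tICA model archive: {path}")
        return cls(
            mean=np.asarray(payload["mean"]),
            c0=np.asarray(payload["c0"]),
            ctau=np.asarray(payload["ctau"]),
            lag=payload["lag"],
            eigenvalues=np.asarray(payload["eigenvalues"]),
            components=np.asarray(payload["components"]),
            feature_labels=[tuple(lab) for lab in payload["feature_labels"]],
            n_dims=payload["n_dims"],
        )


def _lagged_pairs(x: np.ndarray, lag: int) -> tuple[np.ndarray, np.ndarray]:
    if lag < 1:
        raise ValueError("lag must be ≥ 1")
    if x.shape[0] <= lag:
        raise ValueError(f"need more than lag={lag} frames, got {x.shape[0]}")
    return x[:-lag], x[lag:]


def estimate_tica(
    features: FeatureMatrix | np.ndarray,
    lag: int,
    n_dims: int | None = None,
    reg: float = 1e-8,
) -> TICAModel:
    """Fit tICA at integer frame lag ``lag``.

    ``reg`` adds a ridge ``reg·I`` to C0; with exactly collinear features
    and ``reg == 0`` the problem is singular and a
    :class:`SingularCovarianceError` is raised.
    """
    if isinstance(features, FeatureMatrix):
        x = features.values
        labels = features.feature_labels
    else:
        x = np.asarray(features, dtype=float)
        labels = [(j, "feature", "raw") for j in range(x.shape[1])]
    n_feat = x.shape[1]
    if n_dims is None:
        n_dims = n_feat
    if n_dims > n_feat:
        raise ValueError("n_dims cannot exceed the feature count")
    if reg < 0:
        raise ValueError("reg must be ≥ 0")
    x0, xt = _lagged_pairs(x, lag)
    mean = 0.5 * (x0.mean(axis=0) + xt.mean(axis=0))
    a = x0 - mean
    b = xt - mean
    n = a.shape[0]
    c0 = 0.5 * (a.T @ a + b.T @ b) / n
    ctau_raw = a.T @ b / n
    ctau = 0.5 * (ctau_raw + ctau_raw.T)
    c0_reg = c0 + reg * np.eye(n_feat)
    spectrum = np.linalg.eigvalsh(c0_reg)
    if spectrum[0] <= 1e-12 * max(spectrum[-1], 1e-300):
        raise SingularCovarianceError(
            "instantaneous covariance is singular (collinear features); "
            "pass reg > 0 to regularize"
        )
    eigvals, eigvecs = scipy.linalg.eigh(ctau, c0_reg)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order][:n_dims]
    eigvecs = eigvecs[:, order][:, :n_dims]
    # scipy.eigh already returns C0-orthonormal vectors: v.T @ C0 @ v = I
    eigvals = np.clip(eigvals, -1.0 - 1e-6, 1.0 + 1e-6)
    model = TICAModel(
        mean=mean,
        c0=c0,
        ctau=ctau,
        lag=lag,
        eigenvalues=eigvals,
        components=eigvecs,
        feature_labels=list(labels),
        n_dims=n_dims,
    )
    model.training_projection = project(model, x)
    return model


def project(model: TICAModel, features: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Mean-free projection onto the kept components (frames × n_dims).

    With C0-orthonormal components the projected coordinates have unit
    instantaneous variance on the training data (kinetically whitened).
    """
    if isinstance(features, FeatureMatrix):
        if features.feature_labels != model.feature_labels:
            bad = [
                (a, b) for a, b in zip(features.feature_labels, model.feature_labels)
                if a != b
            ]
            raise ValueError(f"feature labels do not match the model: {bad[:5]}")
        x = features.values
    else:
        x = np.asarray(features, dtype=float)
        if x.shape[1] != len(model.feature_labels):
            raise ValueError(
                f"feature count {x.shape[1]} does not match model "
                f"({len(model.feature_labels)})"
            )
    return (x - model.mean) @ model.components


def feature_contributions(
    model: TICAModel,
    threshold: float = 0.195,
) -> tuple[list[int], dict[int, float]]:
    """Residues whose features contribute to the slow modes above threshold.

    Each kept component's loading vector is scaled to unit maximum absolute
    value; a feature's score is the maximum of |normalized loading| over
    components, and sin/cos partners are merged to one residue-level score
    (the maximum over that residue's features).  Residues scoring at or
    above ``threshold`` are selected.

    Returns ``(selected_residues, residue_scores)``.
    """
    loadings = np.abs(model.components)
    maxes = loadings.max(axis=0)
    maxes[maxes == 0] = 1.0
    normalized = loadings / maxes  # each column: unit max-abs
    per_feature = normalized.max(axis=1)
    residue_scores: dict[int, float] = {}
    for score, label in zip(per_feature, model.feature_labels):
        res = int(label[0])
        residue_scores[res] = max(residue_scores.get(res, 0.0), float(score))
    selected = sorted(r for r, s in residue_scores.items() if s >= threshold)
    return selected, residue_scores


def vamp2_score(
    features: FeatureMatrix | np.ndarray,
    lag: int,
    n_dims: int,
    reg: float = 1e-8,
) -> float:
    """VAMP2 score: kinetic variance captured by the top ``n_dims`` modes.

    Sum of the squared top singular values of the half-weighted propagator
    ``C00^{-1/2} C0τ Cττ^{-1/2}`` built on the raw (not mean-removed)
    features augmented with a constant column, so the trivial stationary
    mode contributes 1 and the score is ≥ 1 (n_dims counts it).
    """
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
    x = np.hstack([np.ones((x.shape[0], 1)), x])
    x0, xt = _lagged_pairs(x, lag)
    n = x0.shape[0]
    c00 = x0.T @ x0 / n + reg * np.eye(x.shape[1])
    ctt = xt.T @ xt / n + reg * np.eye(x.shape[1])
    c0t = x0.T @ xt / n
    def inv_sqrt(m):
        w, v = np.linalg.eigh(m)
        w = np.clip(w, 1e-12, None)
        return v @ np.diag(w ** -0.5) @ v.T
    k = inv_sqrt(c00) @ c0t @ inv_sqrt(ctt)
    s = np.linalg.svd(k, compute_uv=False)
    s = np.clip(s, 0.0, 1.0)
    return float(np.sum(s[: n_dims] ** 2))
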