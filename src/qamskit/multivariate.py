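"""Orthogonal projections to latent structures discriminant analysis.

A two-class OPLS-DA implemented from first principles for a single
response: the class membership is coded numerically, the predictive
weight vector is taken from the X'y direction, and ``n_orthogonal``
components orthogonal to that direction (Y-uncorrelated systematic
variation) are stripped from X before the final predictive component is
extracted.  Initialization is deterministic — there is no randomness in
the fit.

Variable influence on projection (VIP) is computed on the predictive
component by default (sum of squared VIPs equals the number of retained
variables exactly); a total variant that folds in the orthogonal
components, weighted by their share of explained X variance, is available
behind a flag.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OplsdaModel",
    "fit_oplsda",
    "vip_scores",
    "marker_selection",
    "class_separation",
    "permutation_null",
]

SCALINGS = ("uv", "center", "pareto")


@dataclass
class OplsdaModel:
    """A fitted two-class OPLS-DA model (one predictive component)."""

    feature_names: list[str]
    sample_names: list[str]
    classes: tuple[str, str]  # (coded -1, coded +1)
    y: np.ndarray  # centered class coding
    scores: np.ndarray  # predictive scores t, per sample
    loadings: np.ndarray  # predictive loadings p, per feature
    weights: np.ndarray  # predictive weights w (unit norm), per feature
    c: float  # y-loading
    orthogonal_scores: np.ndarray  # (n_samples, n_orthogonal)
    orthogonal_loadings: np.ndarray  # (n_features, n_orthogonal)
    orthogonal_weights: np.ndarray  # (n_features, n_orthogonal)
    n_orthogonal: int
    scaling: str
    center: np.ndarray
    scale: np.ndarray
    dropped: list[str] = field(default_factory=list)
    ssx_pred: float = 0.0
    ssx_orth: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def vip(self) -> pd.Series:
        return vip_scores(self)

    def scores_frame(self) -> pd.DataFrame:
        cols = {"t_pred": self.scores}
        for k in range(self.n_orthogonal):
            cols[f"t_orth{k + 1}"] = self.orthogonal_scores[:, k]
        df = pd.DataFrame(cols, index=self.sample_names)
        df["class"] = [self.classes[0] if v < 0 else self.classes[1] for v in self.y]
        return df


def _scale_matrix(
    X: pd.DataFrame, scaling: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], list[str]]:
    if scaling not in SCALINGS:
        raise ValueError(f"unknown scaling {scaling!r}; choose from {SCALINGS}")
    center = X.mean(axis=0).to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1).to_numpy(dtype=float)
    keep = np.ones(len(X.columns), dtype=bool)
    if scaling in ("uv", "pareto"):
        constant = sd == 0
        if constant.any():
            names = [c for c, is_c in zip(X.columns, constant) if is_c]
            warnings.warn(
                f"dropping constant column(s) under {scaling} scaling: {names}",
                stacklevel=3,
            )
            keep = ~constant
    scale = np.ones_like(sd)
    if scaling == "uv":
        scale[keep] = sd[keep]
    elif scaling == "pareto":
        scale[keep] = np.sqrt(sd[keep])
    kept = [c for c, k in zip(X.columns, keep) if k]
    dropped = [c for c, k in zip(X.columns, keep) if not k]
    Xs = (X.to_numpy(dtype=float)[:, keep] - center[keep]) / scale[keep]
    return Xs, center[keep], scale[keep], kept, dropped


def fit_oplsda(
    content_matrix: pd.DataFrame,
    class_labels: Sequence[str] | pd.Series,
    n_orthogonal: int = 1,
    scaling: str = "uv",
) -> OplsdaModel:
    """Fit a two-class OPLS-DA model on a samples-by-analytes matrix.

    Requires exactly two classes with at least two samples each and at
    least two analytes.  ``scaling`` is "uv" (mean-center + unit variance,
    the default), "center", or "pareto".  The fit is fully deterministic.
    """
    X = pd.DataFrame(content_matrix)
    labels = pd.Series(list(class_labels), index=X.index)
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"need exactly two classes, got {uniq}")
    counts = labels.value_counts()
    if counts.min() < 2:
        raise ValueError("each class needs at least two samples")
    if X.shape[1] < 2:
        raise ValueError("need at least two analytes")
    if n_orthogonal < 0:
        raise ValueError("n_orthogonal must be >= 0")
    Xs, center, scale, kept, dropped = _scale_matrix(X, scaling)
    if len(kept) < 2:
        raise ValueError("fewer than two informative analytes after scaling")
    y = np.where(labels.to_numpy() == uniq[1], 1.0, -1.0)
    y = y - y.mean()

    E = Xs.copy()
    # predictive weight direction from the response covariance
    w = E.T @ y
    w = w / np.linalg.norm(w)
    t_orth_all, p_orth_all, w_orth_all, ssx_orth = [], [], [], []
    for _ in range(n_orthogonal):
        t = E @ w
        p = E.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break  # no Y-orthogonal structure left
        w_o = w_o / norm
        t_o = E @ w_o
        p_o = E.T @ t_o / (t_o @ t_o)
        E = E - np.outer(t_o, p_o)
        t_orth_all.append(t_o)
        p_orth_all.append(p_o)
        w_orth_all.append(w_o)
        ssx_orth.append(float((t_o @ t_o) * (p_o @ p_o)))
    t = E @ w
    p = E.T @ t / (t @ t)
    c = float(y @ t / (t @ t))
    k = len(t_orth_all)
    return OplsdaModel(
        feature_names=kept,
        sample_names=list(X.index.astype(str)),
        classes=(str(uniq[0]), str(uniq[1])),
        y=y,
        scores=t,
        loadings=p,
        weights=w,
        c=c,
        orthogonal_scores=np.column_stack(t_orth_all) if k else np.zeros((len(y), 0)),
        orthogonal_loadings=np.column_stack(p_orth_all) if k else np.zeros((len(kept), 0)),
        orthogonal_weights=np.column_stack(w_orth_all) if k else np.zeros((len(kept), 0)),
        n_orthogonal=k,
        scaling=scaling,
        center=center,
        scale=scale,
        dropped=dropped,
        ssx_pred=float((t @ t) * (p @ p)),
        ssx_orth=np.asarray(ssx_orth),
    )


def vip_scores(model: OplsdaModel, total: bool = False) -> pd.Series:
    """Per-analyte variable influence on projection.

    Default: predictive component only, VIP_j = sqrt(J w_j^2 / sum w^2),
    so the squared VIPs average to exactly 1.  With ``total=True`` the
    orthogonal weight vectors are folded in, each component weighted by
    its share of modelled X variance (the squared VIPs still average 1).
    """
    if model.weights.size == 0:
        raise ValueError("model is not fitted")
    J = len(model.feature_names)
    if not total or model.n_orthogonal == 0:
        w2 = model.weights**2
        vip = np.sqrt(J * w2 / w2.sum())
    else:
        comps = [model.weights] + [
            model.orthogonal_weights[:, k] for k in range(model.n_orthogonal)
        ]
        ss = np.concatenate(([model.ssx_pred], model.ssx_orth))
        num = np.zeros(J)
        for wv, s in zip(comps, ss):
            num += s * (wv / np.linalg.norm(wv)) ** 2
        vip = np.sqrt(J * num / ss.sum())
    return pd.Series(vip, index=model.feature_names, name="vip")


def marker_selection(vip: pd.Series, threshold: float = 1.0) -> list[str]:
    """Analytes whose VIP strictly exceeds the threshold, best first."""
    sel = vip[vip > threshold].sort_values(ascending=False)
    return list(sel.index)


def class_separation(model: OplsdaModel) -> float:
    """Standardized distance between class score means on the predictive axis.

    |mean(t | class 1) - mean(t | class 0)| / pooled SD; 0 means no
    separation, values >> 1 mean the classes are split on the predictive
    component.
    """
    t = model.scores
    g1 = t[model.y > 0]
    g0 = t[model.y < 0]
    n1, n0 = g1.size, g0.size
    pooled = np.sqrt(
        ((n1 - 1) * g1.var(ddof=1) + (n0 - 1) * g0.var(ddof=1)) / (n1 + n0 - 2)
    )
    if pooled == 0:
        return float("inf") if g1.mean() != g0.mean() else 0.0
    return float(abs(g1.mean() - g0.mean()) / pooled)


def permutation_null(
    content_matrix: pd.DataFrame,
    class_labels: Sequence[str] | pd.Series,
    n_permutations: int = 199,
    seed: int = 0,
    n_orthogonal: int = 1,
    scaling: str = "uv",
) -> dict[str, object]:
    """Label-permutation reference distribution for the separation statistic.

    Refits the model on randomly permuted class labels and returns the
    observed statistic, the null sample, and the permutation p-value
    (add-one correction).  Large p flags an unstable, signal-free model.
    """
    labels = pd.Series(list(class_labels))
    observed_model = fit_oplsda(content_matrix, labels, n_orthogonal, scaling)
    observed = class_separation(observed_model)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    lab = labels.to_numpy()
    for i in range(n_permutations):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            null[i] = class_separation(
                fit_oplsda(content_matrix, rng.permutation(lab), n_orthogonal, scaling)
            )
    p = (1.0 + np.sum(null >= observed)) / (n_permutations + 1.0)
    return {"observed": observed, "null": null, "p_value": float(p)}
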