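"""Common Spatial Patterns: filters, log-variance features, and OVR.

CSP finds spatial filters ``w`` maximizing the variance ratio between two
classes: generalized eigenvectors of ``Sigma_a w = lambda (Sigma_a +
Sigma_b) w``.  Under the composite normalization the eigenvalues lie in
[0, 1]; filters at both extremes (large lambda: class-a variance high,
small lambda: class-b variance high) are the discriminative ones.  The
solve goes through whitening of the composite covariance followed by a
symmetric eigendecomposition, which is numerically stabler than a direct
generalized solve and guarantees ``W (Sigma_a + Sigma_b) W' = I``.

Features are normalized log-variances of the projected components
(ratio-based, hence scale invariant):

    f_q = log( var(s_q) / mean_i var(s_i) ),   i over the selected rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .containers import EpochSet

__all__ = [
    "CSPModel",
    "FeatureBlock",
    "class_covariance",
    "fit_csp",
    "fit_csp_from_cov",
    "csp_features",
    "fit_csp_ovr",
    "csp_features_ovr",
    "patterns_frame",
]


@dataclass
class CSPModel:
    """Fitted spatial filters for one class pair (or one-vs-rest).

    ``W`` rows are spatial filters sorted by eigenvalue descending;
    ``patterns`` columns (``W^-1``, pseudoinverse when the data are
    rank-deficient and ``W`` is rectangular) are the corresponding scalp
    patterns.  ``selected`` indexes the retained filters (first/last
    ``m_pairs`` for a plain two-class fit; top ``m_top`` for
    one-vs-rest).
    """

    W: np.ndarray
    eigvals: np.ndarray
    m_pairs: int
    selected: tuple[int, ...]
    patterns: np.ndarray
    class_pair: tuple
    channel_labels: tuple[str, ...] = ()


@dataclass
class FeatureBlock:
    """Trial-by-feature matrix with provenance and class labels."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    classes: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.classes = np.asarray(self.classes, dtype=int)
        if self.values.shape != (len(self.classes), len(self.feature_names)):
            raise ValueError("feature block shape mismatch")


def class_covariance(epochs: EpochSet, class_id: int) -> np.ndarray:
    """Average trace-normalized per-trial channel covariance of one class.

    Each trial's covariance is normalized by its trace before averaging —
    classical CSP practice that makes the estimate robust to per-trial
    amplitude differences.  The result is symmetric PSD with trace 1.
    """
    mask = epochs.classes == class_id
    if mask.sum() < 1:
        raise ValueError(f"no trials of class {class_id}")
    covs = []
    for trial in epochs.data[mask]:
        x = trial - trial.mean(axis=1, keepdims=True)
        cov = x @ x.T
        tr = np.trace(cov)
        if tr <= 0:
            raise ValueError("trial with zero total variance")
        covs.append(cov / tr)
    return np.mean(covs, axis=0)


def _whiten(composite: np.ndarray) -> np.ndarray:
    """Whitening matrix ``P`` (rank x n) with ``P composite P' = I_rank``.

    Rank-deficient composites (e.g. covariances of reconstructed
    channels, whose rank cannot exceed the delay-embedded input
    dimension) are whitened inside their signal subspace: eigendirections
    with relative eigenvalue below 1e-10 are dropped rather than shrunk,
    because filters in the null space carry no variance and their
    "discriminability" is numerical noise.
    """
    evals, evecs = linalg.eigh(composite)
    if evals.max() <= 0:
        raise np.linalg.LinAlgError("composite covariance is not PSD")
    keep = evals > evals.max() * 1e-10
    if not keep.all():
        warnings.warn(
            f"rank-deficient composite covariance; restricting CSP to its "
            f"{int(keep.sum())}-dimensional signal subspace",
            RuntimeWarning, stacklevel=3)
    return (evecs[:, keep] / np.sqrt(evals[keep])).T


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Make each filter's largest-magnitude entry positive (ties: lowest
    channel index, which is what argmax returns)."""
    W = W.copy()
    for r in range(W.shape[0]):
        j = int(np.argmax(np.abs(W[r])))
        if W[r, j] < 0:
            W[r] = -W[r]
    return W


def fit_csp_from_cov(cov_a: np.ndarray, cov_b: np.ndarray, m_pairs: int,
                     class_pair: tuple = (0, 1),
                     channel_labels: tuple[str, ...] = ()) -> CSPModel:
    """CSP from two class covariance matrices."""
    cov_a = np.asarray(cov_a, dtype=float)
    cov_b = np.asarray(cov_b, dtype=float)
    n = cov_a.shape[0]
    if cov_a.shape != (n, n) or cov_b.shape != (n, n):
        raise ValueError("covariance matrices must be square and congruent")
    if 2 * m_pairs > n:
        raise ValueError("2*m_pairs must not exceed the channel count")
    P = _whiten(cov_a + cov_b)
    rank = P.shape[0]
    if 2 * m_pairs > rank:
        raise ValueError(
            f"composite covariance rank {rank} too low for "
            f"2*m_pairs={2 * m_pairs} filters")
    M = P @ cov_a @ P.T
    M = (M + M.T) / 2
    evals, evecs = linalg.eigh(M)
    order = np.argsort(evals)[::-1]
    eigvals = evals[order]
    W = _fix_signs(evecs[:, order].T @ P)
    patterns = np.linalg.pinv(W)
    selected = tuple(range(m_pairs)) + tuple(range(rank - m_pairs, rank))
    return CSPModel(W=W, eigvals=eigvals, m_pairs=m_pairs,
                    selected=selected, patterns=patterns,
                    class_pair=class_pair, channel_labels=channel_labels)


def fit_csp(epochs: EpochSet, class_a: int, class_b: int,
            m_pairs: int = 3) -> CSPModel:
    """Two-class CSP from labelled epochs.

    The default ``m_pairs=3`` keeps six components (three per extreme),
    the configuration used for the binary left-vs-right pipeline.
    """
    for cid in (class_a, class_b):
        if (epochs.classes == cid).sum() < 2:
            raise ValueError(f"need >= 2 trials of class {cid}")
    cov_a = class_covariance(epochs, class_a)
    cov_b = class_covariance(epochs, class_b)
    return fit_csp_from_cov(cov_a, cov_b, m_pairs,
                            class_pair=(class_a, class_b),
                            channel_labels=epochs.labels)


def csp_features(model: CSPModel, epochs: EpochSet) -> FeatureBlock:
    """Normalized log-variance features of the selected CSP components.

    The normalization is the mean variance over the selected components,
    so ``sum_q exp(f_q)`` equals the number of selected components for
    every trial (an exact algebraic identity used as a self-check).
    """
    if model.channel_labels and epochs.labels != model.channel_labels:
        raise ValueError("epoch channel order does not match the CSP fit")
    sel = list(model.selected)
    Wsel = model.W[sel]
    proj = np.einsum("fc,tcs->tfs", Wsel, epochs.data)
    variances = proj.var(axis=2)
    floor = np.finfo(float).tiny
    if (variances <= 0).any():
        warnings.warn("zero-variance projected component; ratio floored",
                      RuntimeWarning, stacklevel=2)
        variances = np.maximum(variances, floor)
    ratios = variances / variances.mean(axis=1, keepdims=True)
    values = np.log(np.maximum(ratios, floor))
    names = tuple(f"csp{idx}" for idx in sel)
    return FeatureBlock(values=values, feature_names=names,
                        classes=epochs.classes.copy())


def fit_csp_ovr(epochs: EpochSet, m_top: int = 2) -> list[CSPModel]:
    """One-versus-rest CSP: one model per class against the pooled rest.

    Each model keeps only its top ``m_top`` filters (the components whose
    variance is maximal for the target class), so a 4-class problem at the
    default yields 4 x 2 = 8 features after concatenation.
    """
    class_ids = sorted(int(c) for c in np.unique(epochs.classes))
    if len(class_ids) < 2:
        raise ValueError("one-versus-rest needs at least 2 classes")
    models = []
    for cid in class_ids:
        if (epochs.classes == cid).sum() < 2:
            raise ValueError(f"class {cid} has fewer than 2 trials")
        rest_mask = epochs.classes != cid
        if rest_mask.sum() < 2:
            raise ValueError(f"rest pool for class {cid} is too small")
        cov_a = class_covariance(epochs, cid)
        rest = EpochSet(data=epochs.data[rest_mask], fs=epochs.fs,
                        labels=epochs.labels,
                        classes=np.zeros(int(rest_mask.sum()), dtype=int),
                        class_names={0: "rest"})
        cov_b = class_covariance(rest, 0)
        model = fit_csp_from_cov(cov_a, cov_b, m_pairs=m_top,
                                 class_pair=(cid, "rest"),
                                 channel_labels=epochs.labels)
        model.selected = tuple(range(m_top))
        models.append(model)
    return models


def csp_features_ovr(models: list[CSPModel],
                     epochs: EpochSet) -> FeatureBlock:
    """Concatenate per-class OVR feature blocks column-wise."""
    blocks = [csp_features(m, epochs) for m in models]
    values = np.concatenate([b.values for b in blocks], axis=1)
    names = tuple(f"class{m.class_pair[0]}_{n}"
                  for m, b in zip(models, blocks) for n in b.feature_names)
    return FeatureBlock(values=values, feature_names=names,
                        classes=epochs.classes.copy())


def patterns_frame(model: CSPModel) -> pd.DataFrame:
    """Spatial patterns as a labeled channel x component table (CSV-ready)."""
    labels = list(model.channel_labels) or \
        [f"ch{i}" for i in range(model.W.shape[0])]
    cols = [f"CSP{i}" for i in range(model.patterns.shape[1])]
    return pd.DataFrame(model.patterns, index=labels, columns=cols)
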