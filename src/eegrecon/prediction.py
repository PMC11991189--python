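"""Full-montage EEG reconstruction from a reduced channel subset.

The model is a per-channel penalized linear regression on a time-delay
embedding: each of the ``v`` montage channels is predicted from the ``u``
recorded channels at time ``t`` together with their copies at ``t + tau``
(``tau`` in samples, default 1).  Trials are concatenated column-wise, so
with ``n`` trials of ``m`` samples the regressor matrix is
``2u x n(m - tau)`` and the target matrix ``v x n(m - tau)``; no column
mixes samples from two trials.

The elastic net combines an l1 penalty (sparsity across the delayed
channel copies) with an l2 penalty (stability under the strong
inter-channel correlation of EEG).  The objective follows the common
scaled convention

    (1/(2N)) * ||y - X'b||^2 + alpha*rho*||b||_1 + (alpha*(1-rho)/2)*||b||_2^2

with centered predictors and response.  Predictors stay on their
recorded microvolt scale by default (the convention under which the
default ``alpha=1, rho=0.5`` are meaningful; unit-variance rescaling is
available via ``scale=True``).  The solver is cyclic coordinate descent
with soft-thresholding — fully deterministic given the row order of
``X``.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EpochSet, Montage, select_channels

__all__ = [
    "DelayDesign",
    "PenaltySpec",
    "EnetFit",
    "ChannelPredictor",
    "R2Result",
    "build_delay_design",
    "delay_embed_trials",
    "fit_elastic_net",
    "fit_ridge",
    "fit_predictor",
    "predict_channels",
    "score_r2",
    "elastic_net_objective",
]


@dataclass
class DelayDesign:
    """Time-delay regressor/target matrices with column alignment metadata.

    ``X`` has ``2u`` rows: rows ``0..u-1`` hold samples ``t`` and rows
    ``u..2u-1`` hold samples ``t + tau`` of the same trial.  ``Y`` holds
    samples ``t`` of the ``v``-channel trials.  ``column_trial[k]`` gives
    the trial index of column ``k``.
    """

    X: np.ndarray
    Y: np.ndarray
    tau: int
    u: int
    v: int
    n: int
    m: int
    column_trial: np.ndarray


@dataclass(frozen=True)
class PenaltySpec:
    """Elastic-net hyperparameters (defaults follow the scaled convention)."""

    alpha: float = 1.0
    l1_ratio: float = 0.5
    max_iter: int = 1000
    tol: float = 1e-8
    seed: int = 42

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0 <= self.l1_ratio <= 1:
            raise ValueError("l1_ratio must be in [0, 1]")


def delay_embed_trials(data: np.ndarray, tau: int) -> np.ndarray:
    """Stack each trial's samples ``t`` over samples ``t + tau``.

    ``data`` is (n, u, m); returns (2u, n*(m - tau)) with trials
    concatenated along columns in trial order.
    """
    n, u, m = data.shape
    if not 1 <= tau < m:
        raise ValueError(f"tau must satisfy 1 <= tau < m (got {tau}, m={m})")
    blocks = np.concatenate([data[:, :, : m - tau], data[:, :, tau:]], axis=1)
    return np.concatenate(list(blocks), axis=1)


def build_delay_design(epochs_u: EpochSet, epochs_v: EpochSet,
                       tau: int) -> DelayDesign:
    """Assemble the delay-embedded regressors and aligned targets."""
    if epochs_u.n_trials != epochs_v.n_trials:
        raise ValueError("trial count mismatch between input and target sets")
    if epochs_u.n_samples != epochs_v.n_samples:
        raise ValueError("sample count mismatch between input and target sets")
    n, u, m = epochs_u.data.shape
    v = epochs_v.n_channels
    X = delay_embed_trials(epochs_u.data, tau)
    Y = np.concatenate(list(epochs_v.data[:, :, : m - tau]), axis=1)
    column_trial = np.repeat(np.arange(n), m - tau)
    return DelayDesign(X=X, Y=Y, tau=tau, u=u, v=v, n=n, m=m,
                       column_trial=column_trial)


def _soft(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


def elastic_net_objective(X: np.ndarray, y: np.ndarray, beta: np.ndarray,
                          alpha: float, l1_ratio: float) -> float:
    """Scaled elastic-net objective; ``X`` is predictors x observations."""
    N = X.shape[1]
    resid = y - beta @ X
    return (float(resid @ resid) / (2 * N)
            + alpha * l1_ratio * float(np.abs(beta).sum())
            + 0.5 * alpha * (1 - l1_ratio) * float(beta @ beta))


def _cd_elastic_net(G: np.ndarray, c: np.ndarray, yty: float, N: int,
                    spec: PenaltySpec, beta0: np.ndarray | None = None,
                    ) -> tuple[np.ndarray, int, bool, list[float]]:
    """Cyclic coordinate descent on precomputed Gram quantities.

    Minimizes ``(1/(2N)) (y'y - 2 b.c + b'Gb) + l1 ||b||_1 + (l2/2) ||b||_2^2``
    with ``G = X X'``, ``c = X y``.  Returns ``(beta, sweeps, converged,
    objective_history)``; the history is one value per sweep and is
    non-increasing for a correct implementation.
    """
    p = len(c)
    l1 = spec.alpha * spec.l1_ratio
    l2 = spec.alpha * (1 - spec.l1_ratio)
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, float).copy()
    Gb = G @ beta
    diag = np.diag(G)
    denom = diag / N + l2

    def objective() -> float:
        return (yty - 2 * beta @ c + beta @ Gb) / (2 * N) \
            + l1 * np.abs(beta).sum() + 0.5 * l2 * beta @ beta

    history: list[float] = []
    converged = False
    sweeps = 0
    for sweeps in range(1, spec.max_iter + 1):
        max_delta = 0.0
        for j in range(p):
            bj_old = beta[j]
            rho_j = (c[j] - Gb[j] + diag[j] * bj_old) / N
            bj = _soft(rho_j, l1) / denom[j] if denom[j] > 0 else 0.0
            if bj != bj_old:
                Gb += G[:, j] * (bj - bj_old)
                beta[j] = bj
                max_delta = max(max_delta, abs(bj - bj_old))
        history.append(float(objective()))
        if max_delta < spec.tol:
            converged = True
            break
    return beta, sweeps, converged, history


def _warm_start(G: np.ndarray, c: np.ndarray, N: int,
                spec: PenaltySpec) -> np.ndarray | None:
    """Closed-form minimizer of the smooth (ridge) part of the objective.

    Solving ``(G + N alpha (1-rho) I) b = c`` gives a start near the
    elastic-net optimum whenever the l1 weight is small relative to the
    data scale; coordinate descent then only applies the sparsity
    correction.  Skipped (cold start) when the l2 part is absent.
    """
    l2 = spec.alpha * (1 - spec.l1_ratio)
    if l2 <= 0:
        return None
    p = len(c)
    try:
        return np.linalg.solve(G + N * l2 * np.eye(p), c)
    except np.linalg.LinAlgError:
        return None


@dataclass
class EnetFit:
    """A single-response elastic-net fit in standardized coordinates."""

    coef: np.ndarray
    intercept: float
    x_center: np.ndarray
    x_scale: np.ndarray
    n_sweeps: int
    converged: bool
    objective_history: list[float] = field(repr=False, default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (X - self.x_center[:, None]) / self.x_scale[:, None]
        return self.coef @ Xs + self.intercept


def _center_rows(X: np.ndarray, scale: bool = False
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center each predictor row; optionally scale to unit variance.

    The default keeps predictors on their recorded (microvolt) scale,
    matching the convention under which the printed hyperparameters
    ``alpha=1, l1_ratio=0.5`` were chosen: the penalty then acts on the
    data's own units rather than being inflated by rescaling.  Zero-
    variance rows get scale 1 (their coefficient stays 0 because the
    centered row is identically zero)."""
    center = X.mean(axis=1)
    centered = X - center[:, None]
    if not scale:
        return centered, center, np.ones(X.shape[0])
    scl = centered.std(axis=1)
    zero = scl == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance regressor row(s); "
                      "coefficient fixed at 0", RuntimeWarning, stacklevel=3)
        scl[zero] = 1.0
    return centered / scl[:, None], center, scl


def fit_elastic_net(X: np.ndarray, y: np.ndarray,
                    spec: PenaltySpec = PenaltySpec(),
                    scale: bool = False) -> EnetFit:
    """Fit one elastic-net regression of ``y`` on the rows of ``X``.

    ``X`` is predictors x observations (matching :class:`DelayDesign`).
    Predictors are centered (and, with ``scale=True``, rescaled to unit
    variance) and the response centered; the returned coefficients live
    in the transformed coordinates and :meth:`EnetFit.predict` replays
    the stored transform.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in regression inputs")
    Xs, center, scale_vec = _center_rows(X, scale=scale)
    y_mean = float(y.mean())
    yc = y - y_mean
    N = X.shape[1]
    G = Xs @ Xs.T
    c = Xs @ yc
    beta, sweeps, converged, hist = _cd_elastic_net(
        G, c, float(yc @ yc), N, spec, beta0=_warm_start(G, c, N, spec))
    if not converged:
        warnings.warn(
            f"coordinate descent hit max_iter={spec.max_iter} "
            f"(last objective {hist[-1]:.6g})", RuntimeWarning, stacklevel=2)
    return EnetFit(coef=beta, intercept=y_mean, x_center=center,
                   x_scale=scale_vec, n_sweeps=sweeps, converged=converged,
                   objective_history=hist)


def fit_ridge(X: np.ndarray, y: np.ndarray, lambda2: float) -> np.ndarray:
    """Closed-form ridge solution ``(XX' + lambda2 I)^-1 X y``.

    ``X`` is predictors x observations; no standardization is applied
    (callers standardize first).  Uses the unnormalized residual-sum-of-
    squares convention, so the scaled elastic net with ``l1_ratio=0``
    corresponds to ``lambda2 = N * alpha``.  A singular system at
    ``lambda2 = 0`` falls back to the pseudoinverse with a warning.
    """
    if lambda2 < 0:
        raise ValueError("lambda2 must be >= 0")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[0]
    A = X @ X.T + lambda2 * np.eye(p)
    b = X @ y
    if lambda2 == 0 and np.linalg.matrix_rank(A) < p:
        warnings.warn("singular normal equations at lambda2=0; "
                      "using pseudoinverse", RuntimeWarning, stacklevel=2)
        return np.linalg.pinv(A) @ b
    return np.linalg.solve(A, b)


@dataclass
class ChannelPredictor:
    """Per-channel regression coefficients plus replayable transforms.

    ``coef`` (v x 2u) lives in standardized regressor coordinates;
    predictions are de-standardized back to microvolts by adding
    ``intercepts`` (the training means of each target channel, equal to
    ``y_center``).
    """

    coef: np.ndarray
    intercepts: np.ndarray
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: np.ndarray
    tau: int
    input_labels: tuple[str, ...]
    output_labels: tuple[str, ...]
    n_sweeps: np.ndarray | None = None
    converged: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if not np.isfinite(self.coef).all():
            raise ValueError("non-finite coefficients")
        if not (self.input_labels and self.output_labels):
            raise ValueError("empty label lists")

    # -- serialization: labeled CSV with a commented transform header -----
    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        cols = [f"{c}@t" for c in self.input_labels] + \
               [f"{c}@t+{self.tau}" for c in self.input_labels]
        with path.open("w") as fh:
            fh.write(f"# tau: {self.tau}\n")
            fh.write("# input_labels: " + " ".join(self.input_labels) + "\n")
            fh.write("# x_center: " +
                     " ".join(repr(float(v)) for v in self.x_center) + "\n")
            fh.write("# x_scale: " +
                     " ".join(repr(float(v)) for v in self.x_scale) + "\n")
            fh.write("# y_center: " +
                     " ".join(repr(float(v)) for v in self.y_center) + "\n")
            frame = pd.DataFrame(self.coef, index=list(self.output_labels),
                                 columns=cols)
            frame.insert(0, "intercept", self.intercepts)
            frame.to_csv(fh, float_format="%.17g", index_label="channel")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "ChannelPredictor":
        path = Path(path)
        meta: dict[str, str] = {}
        body: list[str] = []
        for ln in path.read_text().splitlines():
            if ln.startswith("# "):
                key, _, val = ln[2:].partition(":")
                meta[key.strip()] = val.strip()
            else:
                body.append(ln)
        frame = pd.read_csv(io.StringIO("\n".join(body)), index_col=0,
                            float_precision="round_trip")
        tau = int(meta["tau"])
        return cls(
            coef=frame.drop(columns="intercept").to_numpy(),
            intercepts=frame["intercept"].to_numpy(),
            x_center=np.array([float(v) for v in meta["x_center"].split()]),
            x_scale=np.array([float(v) for v in meta["x_scale"].split()]),
            y_center=np.array([float(v) for v in meta["y_center"].split()]),
            tau=tau,
            input_labels=tuple(meta["input_labels"].split()),
            output_labels=tuple(frame.index),
        )


def fit_predictor(epochs_train: EpochSet, montage: Montage, tau: int = 1,
                  spec: PenaltySpec = PenaltySpec()) -> ChannelPredictor:
    """Fit one elastic net per montage channel from the reduced subset.

    All output channels share the same delay-embedded design, so the Gram
    matrix is computed once; the v single-response fits are independent.
    """
    missing = [c for c in montage.input_subset if c not in epochs_train.labels]
    if missing:
        raise KeyError(f"input channels missing from training set: {missing}")
    epochs_u = select_channels(epochs_train, montage.input_subset)
    design = build_delay_design(epochs_u, epochs_train, tau)
    Xs, x_center, x_scale = _center_rows(design.X)
    N = Xs.shape[1]
    G = Xs @ Xs.T
    y_center = design.Y.mean(axis=1)
    Yc = design.Y - y_center[:, None]
    coef = np.empty((design.v, 2 * design.u))
    sweeps = np.empty(design.v, dtype=int)
    converged = np.empty(design.v, dtype=bool)
    for j in range(design.v):
        c = Xs @ Yc[j]
        coef[j], sweeps[j], converged[j], _ = _cd_elastic_net(
            G, c, float(Yc[j] @ Yc[j]), N, spec,
            beta0=_warm_start(G, c, N, spec))
    if not converged.all():
        warnings.warn(
            f"{int((~converged).sum())} channel fit(s) hit max_iter",
            RuntimeWarning, stacklevel=2)
    return ChannelPredictor(
        coef=coef, intercepts=y_center.copy(), x_center=x_center,
        x_scale=x_scale, y_center=y_center, tau=tau,
        input_labels=tuple(montage.input_subset),
        output_labels=tuple(epochs_train.labels),
        n_sweeps=sweeps, converged=converged)


def predict_channels(pred: ChannelPredictor, epochs_u: EpochSet) -> EpochSet:
    """Reconstruct the full montage from reduced-subset epochs.

    Each output trial has ``m - tau`` samples (the delay embedding trims
    the trailing ``tau`` samples); class labels are copied trial-for-trial.
    """
    epochs_u = select_channels(epochs_u, pred.input_labels)
    n, u, m = epochs_u.data.shape
    if m <= pred.tau:
        raise ValueError("sample count must exceed tau")
    X = delay_embed_trials(epochs_u.data, pred.tau)
    Xs = (X - pred.x_center[:, None]) / pred.x_scale[:, None]
    Yhat = pred.coef @ Xs + pred.intercepts[:, None]
    data = np.stack(np.split(Yhat, n, axis=1))
    return EpochSet(data=data, fs=epochs_u.fs, labels=pred.output_labels,
                    classes=epochs_u.classes.copy(),
                    class_names=dict(epochs_u.class_names))


@dataclass
class R2Result:
    """Coefficient of determination per channel, plus summaries.

    ``per_channel[j]`` pools squared errors over all trials and samples of
    channel ``j``; ``mean`` averages the defined per-channel values and
    ``pooled`` pools over everything.  Channels with zero total variance
    are reported as NaN (undefined).
    """

    labels: tuple[str, ...]
    per_channel: np.ndarray
    mean: float
    pooled: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"channel": list(self.labels),
                             "r2": self.per_channel})


def score_r2(actual: EpochSet, predicted: EpochSet) -> R2Result:
    """Pooled per-channel r^2 between recorded and reconstructed signals.

    ``actual`` is trimmed to the predicted sample count (delay trimming)
    and its channels are matched to ``predicted.labels`` by name.
    """
    act = select_channels(actual, predicted.labels)
    m = predicted.n_samples
    if act.n_samples < m or act.n_trials != predicted.n_trials:
        raise ValueError("shape mismatch between actual and predicted sets")
    a = act.data[:, :, :m]
    p = predicted.data
    sse = ((a - p) ** 2).sum(axis=(0, 2))
    mean_per_ch = a.mean(axis=(0, 2))
    sst = ((a - mean_per_ch[None, :, None]) ** 2).sum(axis=(0, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sst > 0, 1.0 - sse / sst, np.nan)
    defined = np.isfinite(r2)
    mean = float(r2[defined].mean()) if defined.any() else float("nan")
    pooled = float(1.0 - sse.sum() / sst.sum()) if sst.sum() > 0 \
        else float("nan")
    return R2Result(labels=predicted.labels, per_channel=r2,
                    mean=mean, pooled=pooled)
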