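"""End-to-end orchestration: preprocess -> reconstruct -> CSP -> classify.

Three modes share identical splits and evaluation machinery:

``full_channel``
    CSP + SVM on all recorded channels (dense-montage baseline).
``few_channel``
    CSP + SVM directly on the reduced central subset (the traditional
    few-electrode approach).
``predicted_channel``
    The reconstruction method: fit the elastic-net channel predictor on
    the training split, replace the montage with its reconstruction from
    the reduced subset (train and test alike), then CSP + SVM.

The predictor, CSP filters and classifier are fit on the training split
only; test-split data only ever pass through stored transforms.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (EpochSet, Montage, read_epochs, select_channels,
                         select_trials, standard_montage_22,
                         INPUT_CHANNELS_8)
from .preprocess import FilterSpec, WindowSpec, bandpass
from .prediction import (ChannelPredictor, PenaltySpec, R2Result,
                         fit_predictor, predict_channels, score_r2)
from .csp import CSPModel, fit_csp, csp_features, patterns_frame
from .classify import (EvalReport, MarginClassifier, evaluate, predict,
                       stratified_split_indices, train_margin_classifier)

__all__ = ["RunConfig", "PipelineResult", "FittedStages", "fit_stages",
           "apply_stages", "run_pipeline", "compare_modes", "MODES"]

log = logging.getLogger(__name__)

MODES = ("full_channel", "predicted_channel", "few_channel")


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one pipeline run."""

    mode: str = "predicted_channel"
    input_path: str | None = None
    out_dir: str | None = None
    input_channels: tuple[str, ...] = INPUT_CHANNELS_8
    filter: FilterSpec = field(default_factory=FilterSpec)
    window: WindowSpec = field(default_factory=WindowSpec)
    tau: int = 1
    penalty: PenaltySpec = field(default_factory=PenaltySpec)
    m_pairs: int = 3
    C: float = 1.0
    split_ratio: float = 0.7
    seed: int = 42
    keep_recorded_inputs: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.tau < 1:
            raise ValueError("tau must be a positive integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "filter" in kwargs:
            kwargs["filter"] = FilterSpec(**kwargs["filter"])
        if "window" in kwargs:
            kwargs["window"] = WindowSpec(**kwargs["window"])
        if "penalty" in kwargs:
            kwargs["penalty"] = PenaltySpec(**kwargs["penalty"])
        if "input_channels" in kwargs:
            kwargs["input_channels"] = tuple(kwargs["input_channels"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        raw = asdict(self)
        raw["input_channels"] = list(self.input_channels)
        path.write_text(yaml.safe_dump(raw, sort_keys=True))
        return path


@dataclass
class FittedStages:
    """Everything fit on the training split."""

    predictor: ChannelPredictor | None
    csp: CSPModel
    classifier: MarginClassifier
    class_pair: tuple[int, int]


@dataclass
class PipelineResult:
    mode: str
    report: EvalReport
    r2: R2Result | None
    stages: FittedStages
    test_indices: np.ndarray


def _montage_for(epochs: EpochSet, config: RunConfig) -> Montage:
    std = standard_montage_22()
    if tuple(epochs.labels) == std.labels and \
            config.input_channels == std.input_subset:
        return std
    # generic montage: schematic positions unavailable -> zeros
    return Montage(labels=epochs.labels,
                   positions=np.zeros((epochs.n_channels, 2)),
                   input_subset=tuple(config.input_channels))


def _stage_channels(epochs: EpochSet, config: RunConfig,
                    predictor: ChannelPredictor | None) -> EpochSet:
    """Channel representation each mode feeds to CSP."""
    if config.mode == "few_channel":
        return select_channels(epochs, config.input_channels)
    if config.mode == "full_channel":
        return epochs
    reduced = select_channels(epochs, config.input_channels)
    recon = predict_channels(predictor, reduced)
    if config.keep_recorded_inputs:
        m = recon.n_samples
        for lab in config.input_channels:
            recon.data[:, recon.labels.index(lab), :] = \
                epochs.data[:, epochs.labels.index(lab), :m]
    return recon


def fit_stages(train: EpochSet, config: RunConfig) -> FittedStages:
    """Fit predictor (mode-dependent), CSP, and classifier on training data."""
    montage = _montage_for(train, config)
    predictor = None
    if config.mode == "predicted_channel":
        t0 = time.perf_counter()
        predictor = fit_predictor(train, montage, config.tau, config.penalty)
        log.info("stage fit_predictor: %.2fs, %d/%d fits converged",
                 time.perf_counter() - t0,
                 int(predictor.converged.sum()), len(predictor.converged))
    staged = _stage_channels(train, config, predictor)
    class_ids = sorted(int(c) for c in np.unique(train.classes))
    if len(class_ids) != 2:
        raise ValueError("the binary pipeline needs exactly 2 classes")
    t0 = time.perf_counter()
    csp = fit_csp(staged, class_ids[0], class_ids[1], config.m_pairs)
    log.info("stage fit_csp: %.2fs", time.perf_counter() - t0)
    feats = csp_features(csp, staged)
    t0 = time.perf_counter()
    clf = train_margin_classifier(feats, C=config.C)
    log.info("stage train_classifier: %.2fs, %d support vectors",
             time.perf_counter() - t0, len(clf.sv_indices))
    return FittedStages(predictor=predictor, csp=csp, classifier=clf,
                        class_pair=(class_ids[0], class_ids[1]))


def apply_stages(stages: FittedStages, test: EpochSet,
                 config: RunConfig) -> tuple[EvalReport, R2Result | None]:
    """Replay stored transforms on held-out data and evaluate."""
    staged = _stage_channels(test, config, stages.predictor)
    r2 = None
    if config.mode == "predicted_channel":
        # always score the pure reconstruction, even when recorded input
        # channels are spliced back in for classification
        reduced = select_channels(test, config.input_channels)
        r2 = score_r2(test, predict_channels(stages.predictor, reduced))
    feats = csp_features(stages.csp, staged)
    preds = predict(stages.classifier, feats)
    report = evaluate(test.classes, preds, class_ids=stages.class_pair)
    return report, r2


def _write_artifacts(result: PipelineResult, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    result.report.metrics_frame().to_csv(out / "metrics.csv", index=False)
    result.report.confusion_frame().to_csv(out / "confusion.csv")
    result.report.per_class.to_csv(out / "per_class.csv", index=False)
    patterns_frame(result.stages.csp).to_csv(out / "csp_patterns.csv",
                                             index_label="channel")
    pd.DataFrame(result.stages.csp.W,
                 columns=list(result.stages.csp.channel_labels) or None) \
        .to_csv(out / "csp_filters.csv", index_label="filter")
    if result.r2 is not None:
        result.r2.to_frame().to_csv(out / "r2.csv", index=False)
    if result.stages.predictor is not None:
        result.stages.predictor.to_csv(out / "predictor.csv")
    np.savetxt(out / "test_indices.txt", result.test_indices, fmt="%d")


def run_pipeline(config: RunConfig, epochs: EpochSet | None = None,
                 split: tuple[np.ndarray, np.ndarray] | None = None
                 ) -> PipelineResult:
    """Execute one mode end-to-end; optionally write artifacts.

    ``split`` overrides the internal stratified split (used by
    :func:`compare_modes` to share test trials across modes).
    """
    if epochs is None:
        if config.input_path is None:
            raise ValueError("either epochs or config.input_path is required")
        epochs = read_epochs(config.input_path)
    t0 = time.perf_counter()
    filtered = bandpass(epochs, config.filter)
    log.info("stage bandpass: %.2fs", time.perf_counter() - t0)
    if split is None:
        split = stratified_split_indices(filtered.classes,
                                         config.split_ratio, config.seed)
    train_idx, test_idx = split
    train = select_trials(filtered, train_idx)
    test = select_trials(filtered, test_idx)
    stages = fit_stages(train, config)
    report, r2 = apply_stages(stages, test, config)
    result = PipelineResult(mode=config.mode, report=report, r2=r2,
                            stages=stages, test_indices=np.asarray(test_idx))
    log.info("mode %s: accuracy %.4f, kappa %s", config.mode,
             report.accuracy, report.kappa)
    if config.out_dir is not None:
        _write_artifacts(result, config)
    return result


def compare_modes(config: RunConfig, epochs: EpochSet | None = None
                  ) -> tuple[dict[str, PipelineResult], pd.DataFrame]:
    """Run all three modes on identical splits; return a side-by-side table."""
    if epochs is None:
        if config.input_path is None:
            raise ValueError("either epochs or config.input_path is required")
        epochs = read_epochs(config.input_path)
    split = stratified_split_indices(epochs.classes, config.split_ratio,
                                     config.seed)
    results: dict[str, PipelineResult] = {}
    rows = []
    for mode in MODES:
        sub_out = None
        if config.out_dir is not None:
            sub_out = str(Path(config.out_dir) / mode)
        mode_cfg = RunConfig(**{**asdict_flat(config), "mode": mode,
                                "out_dir": sub_out})
        results[mode] = run_pipeline(mode_cfg, epochs=epochs, split=split)
        rep = results[mode].report
        rows.append({"mode": mode, "Accuracy %": 100.0 * rep.accuracy,
                     "Kappa": rep.kappa})
    table = pd.DataFrame(rows)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "comparison.csv", index=False)
    return results, table


def asdict_flat(config: RunConfig) -> dict:
    """RunConfig -> kwargs dict preserving nested spec objects."""
    return {
        "mode": config.mode, "input_path": config.input_path,
        "out_dir": config.out_dir, "input_channels": config.input_channels,
        "filter": config.filter, "window": config.window, "tau": config.tau,
        "penalty": config.penalty, "m_pairs": config.m_pairs, "C": config.C,
        "split_ratio": config.split_ratio, "seed": config.seed,
        "keep_recorded_inputs": config.keep_recorded_inputs,
    }
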