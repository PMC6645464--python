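"""Scoring, blocked permutation nulls, FDR control, and the pipeline driver.

Classifier quality is the area under the ROC curve (AUC) on held-out
samples. Because consecutive samples are strongly dependent, chance level is
assessed with a *blocked* label permutation: the training timeline is cut
into non-overlapping 10-minute segments, segment labels are shuffled, the
classifier is retrained on the shuffled training set, and the untouched test
set is re-scored. N such surrogates give an AUC null distribution, and

    p = (1 + #{AUC* > AUC}) / (1 + N)

is the empirical p-value (strict inequality; an optional conservative mode
counts ties). Benjamini-Hochberg FDR control is applied over the family of
(recording, feature-group) tests at target levels 0.05 and 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from . import dataset as ds
from . import features as ft
from . import models as md
from .dataset import (
    CVFold,
    LabelingConfig,
    WindowTimeline,
    build_timeline_labels,
    class_weights,
    loso_folds,
    make_samples,
    make_timeline,
    shuffled_window_cv,
)
from .preprocess import BroadbandRecording, preprocess_recording
from .synth import SynthConfig, simulate_recording

__all__ = [
    "roc_auc",
    "NullDistribution",
    "empirical_pvalue",
    "permute_labels_blockwise",
    "surrogate_null_auc",
    "FdrResult",
    "fdr_flags",
    "PipelineConfig",
    "evaluate_timeline",
    "run_pipeline",
]

SURROGATE_BLOCK_S = 600.0  # 10-minute permutation blocks
DEFAULT_N_SURROGATES = 200


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC: probability a random preictal sample outscores a random interictal one.

    Ties count one half; equals the trapezoidal area under the ROC curve.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("AUC undefined: test trace contains a single class")
    return float(roc_auc_score(labels, np.asarray(scores)))


@dataclass
class NullDistribution:
    auc_star: np.ndarray  # N surrogate AUCs
    auc_obs: float
    seed: int = 0

    @property
    def n(self) -> int:
        return self.auc_star.size

    @property
    def p(self) -> float:
        return empirical_pvalue(self)


def empirical_pvalue(null: NullDistribution, conservative: bool = False) -> float:
    """p = (1 + #{AUC* > AUC}) / (1 + N); ``conservative`` counts ties as exceedances."""
    if null.n < 1:
        raise ValueError("need at least one surrogate")
    if conservative:
        k = int((null.auc_star >= null.auc_obs).sum())
    else:
        k = int((null.auc_star > null.auc_obs).sum())
    return (1 + k) / (1 + null.n)


@dataclass
class FdrResult:
    table: pd.DataFrame  # index: test id; columns p, reject at each alpha

    def n_rejected(self, alpha: float) -> int:
        return int(self.table[f"reject_{alpha:g}"].sum())


def fdr_flags(pvals, alphas=(0.05, 0.01)) -> FdrResult:
    """Benjamini-Hochberg step-up over the pooled test family."""
    s = pd.Series(pvals, dtype=float)
    if s.empty:
        raise ValueError("no p-values to correct")
    out = pd.DataFrame({"p": s})
    for a in alphas:
        rej, _, _, _ = multipletests(s.values, alpha=a, method="fdr_bh")
        out[f"reject_{a:g}"] = rej
    return FdrResult(out)


# ---------------------------------------------------------------------------
# fitting and scoring


def _fit(
    timeline: WindowTimeline,
    samples: ds.SampleSet,
    classifier: str,
    seed: int,
    lstm_cfg: md.LstmConfig,
    gbt_cfg: md.GbtConfig,
):
    X = samples.tensor(timeline)
    y = samples.label.astype(int)
    cw = class_weights(y)
    if classifier == "lstm":
        # standardize per feature with training-fold statistics: raw feature
        # scales span orders of magnitude (counts vs band powers) and would
        # otherwise saturate the gate nonlinearities
        mu = X.mean(axis=(0, 1))
        sd = X.std(axis=(0, 1))
        sd[sd == 0] = 1.0
        params, _ = md.train_lstm((X - mu) / sd, y, cw, replace(lstm_cfg, seed=seed))
        return ("lstm", params, (mu, sd))
    if classifier == "gbt":
        Xf, names = md.flatten_samples(X, timeline.columns)
        booster, _ = md.train_gbt(Xf, y, names, replace(gbt_cfg, seed=seed))
        return ("gbt", booster, names)
    raise ValueError("classifier must be 'lstm' or 'gbt'")


def _score(model, timeline: WindowTimeline, samples: ds.SampleSet) -> np.ndarray:
    kind, obj, meta = model
    X = samples.tensor(timeline)
    if kind == "lstm":
        mu, sd = meta
        return md.predict_proba(obj, (X - mu) / sd)
    Xf, _ = md.flatten_samples(X, timeline.columns)
    return md.gbt_predict(obj, Xf, meta)


def _fold_auc(fold: CVFold, classifier, seed, lstm_cfg, gbt_cfg) -> float:
    model = _fit(fold.train_timeline, fold.train, classifier, seed, lstm_cfg, gbt_cfg)
    scores = _score(model, fold.test_timeline, fold.test)
    return roc_auc(scores, fold.test.label)


def _permute_blocks(timeline: WindowTimeline, rng: np.random.Generator, block_s: float):
    """Shuffle the label sequence of a training timeline in 10-minute blocks."""
    labeled_idx = np.flatnonzero(timeline.label >= 0)
    labels = timeline.label[labeled_idx]
    block_len = max(1, int(round(block_s / ds.STEP_S)))
    n_blocks = int(np.ceil(labels.size / block_len))
    blocks = [labels[k * block_len : (k + 1) * block_len] for k in range(n_blocks)]
    majority = [int(np.round(b.mean())) for b in blocks]
    if min(sum(1 for m in majority if m == v) for v in (0, 1)) < 2:
        raise ValueError("need at least two 10-minute segments per class to permute")
    perm = rng.permutation(n_blocks)
    # reassign whole blocks of labels to new positions (lengths permute with them)
    new_labels = np.concatenate([blocks[k] for k in perm])[: labels.size]
    label = timeline.label.copy()
    label[labeled_idx] = new_labels
    # one synthetic seizure id per contiguous preictal run after the shuffle
    seizure = np.full(label.size, -1, dtype=np.int32)
    pre = label == ds.PREICTAL
    runs = np.flatnonzero(np.diff(np.concatenate([[0], pre.view(np.int8)])) == 1)
    for sid, start in enumerate(runs):
        stop = start
        while stop < label.size and pre[stop]:
            stop += 1
        seizure[start:stop] = sid
    return WindowTimeline(timeline.t, timeline.X, label, seizure, timeline.columns)


def permute_labels_blockwise(
    timeline: WindowTimeline, seed: int, block_s: float = SURROGATE_BLOCK_S
) -> WindowTimeline:
    """Shuffle a timeline's labels in non-overlapping 10-minute blocks.

    The feature matrix is untouched; only the label sequence moves, in whole
    blocks, preserving temporal dependence within each block.
    """
    return _permute_blocks(timeline, np.random.default_rng(seed), block_s)


def surrogate_null_auc(
    fold: CVFold,
    classifier: str = "gbt",
    n_surrogates: int = DEFAULT_N_SURROGATES,
    seed: int = 0,
    block_s: float = SURROGATE_BLOCK_S,
    lstm_cfg: md.LstmConfig = md.LstmConfig(),
    gbt_cfg: md.GbtConfig = md.GbtConfig(),
) -> NullDistribution:
    """Chance-level AUC distribution for one fold by blocked label permutation.

    Every replicate shuffles the training labels in 10-minute blocks, rebuilds
    the training samples, retrains from scratch and scores the untouched test
    set.
    """
    rng = np.random.default_rng(seed)
    auc_obs = _fold_auc(fold, classifier, seed, lstm_cfg, gbt_cfg)
    stars = np.empty(n_surrogates)
    for r in range(n_surrogates):
        tl = _permute_blocks(fold.train_timeline, rng, block_s)
        samples = make_samples(tl, fold.train.n, "train")
        if np.unique(samples.label).size < 2:
            stars[r] = 0.5
            continue
        model = _fit(tl, samples, classifier, seed + r + 1, lstm_cfg, gbt_cfg)
        scores = _score(model, fold.test_timeline, fold.test)
        stars[r] = roc_auc(scores, fold.test.label)
    return NullDistribution(stars, auc_obs, seed)


# ---------------------------------------------------------------------------
# the full pipeline


@dataclass
class PipelineConfig:
    """End-to-end run: recording -> streams -> features -> folds -> AUC (+null)."""

    synth: SynthConfig | None = None
    recording: BroadbandRecording | None = None
    onsets: tuple[float, ...] | None = None
    labeling: LabelingConfig = field(default_factory=LabelingConfig)
    history: int = 10
    classifier: str = "lstm"
    feature_set: str = "groups"  # 'groups' (each separately), 'reduced', or 'full'
    cv: str = "loso"
    zscore: bool = False
    n_surrogates: int = 0
    surrogate_classifier: str = "gbt"
    alphas: tuple[float, ...] = (0.05, 0.01)
    seed: int = 0
    lstm: md.LstmConfig = field(default_factory=md.LstmConfig)
    gbt: md.GbtConfig = field(default_factory=md.GbtConfig)


def evaluate_timeline(
    timeline: WindowTimeline,
    history: int,
    classifier: str = "lstm",
    cv: str = "loso",
    seed: int = 0,
    n_surrogates: int = 0,
    surrogate_classifier: str = "gbt",
    lstm_cfg: md.LstmConfig = md.LstmConfig(),
    gbt_cfg: md.GbtConfig = md.GbtConfig(),
) -> dict:
    """Cross-validated AUC (and optional permutation p-value) for one timeline."""
    if cv == "loso":
        folds = loso_folds(timeline, history)
    elif cv == "shuffled":
        folds = shuffled_window_cv(timeline, history, seed)
    else:
        raise ValueError("cv must be 'loso' or 'shuffled'")
    fold_rows = []
    for k, fold in enumerate(folds):
        auc = _fold_auc(fold, classifier, seed + 1000 * k, lstm_cfg, gbt_cfg)
        fold_rows.append(
            {"seizure": fold.held_out_seizure, "auc": auc, "n_test": fold.test.n_samples}
        )
    mean_auc = float(np.mean([r["auc"] for r in fold_rows]))
    out = {"folds": fold_rows, "mean_auc": mean_auc}
    if n_surrogates > 0:
        rng = np.random.default_rng(seed + 7)
        stars = np.zeros(n_surrogates)
        for k, fold in enumerate(folds):
            null_k = surrogate_null_auc(
                fold,
                surrogate_classifier,
                n_surrogates,
                int(rng.integers(2**31 - 1)),
                lstm_cfg=lstm_cfg,
                gbt_cfg=gbt_cfg,
            )
            stars += null_k.auc_star / len(folds)
        # null of the across-fold mean AUC, compared with the observed mean
        obs = (
            mean_auc
            if surrogate_classifier == classifier
            else float(
                np.mean(
                    [
                        _fold_auc(f, surrogate_classifier, seed + 1000 * k, lstm_cfg, gbt_cfg)
                        for k, f in enumerate(folds)
                    ]
                )
            )
        )
        null = NullDistribution(stars, obs, seed)
        out["null"] = null
        out["p"] = null.p
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the complete analysis and return a nested report.

    Feature units are the four groups (``feature_set='groups'``), the reduced
    subset, or the full concatenation; each unit is trained and scored under
    the chosen cross-validation, with optional blocked-permutation p-values
    and pooled FDR flags across units.
    """
    if cfg.recording is not None:
        rec = cfg.recording
        onsets = list(cfg.onsets or ())
        artifacts_extra: list[tuple[float, float]] = []
    elif cfg.synth is not None:
        rec, gt = simulate_recording(cfg.synth)
        onsets = list(cfg.onsets or cfg.synth.seizure_times or ())
        artifacts_extra = []
    else:
        raise ValueError("PipelineConfig needs a recording or a SynthConfig")
    streams = preprocess_recording(rec, zscore=cfg.zscore)
    frames = ft.extract_features(streams)
    intervals, excluded = build_timeline_labels(
        onsets, rec.duration, streams.artifact_intervals + artifacts_extra, cfg.labeling
    )
    full = ft.combine_groups(frames)
    if cfg.feature_set == "groups":
        units = {g: frames[g] for g in ft.GROUPS}
    elif cfg.feature_set == "reduced":
        units = {"reduced": full[md.select_reduced_features(list(full.columns))]}
    elif cfg.feature_set == "full":
        units = {"full": full}
    else:
        raise ValueError("feature_set must be 'groups', 'reduced' or 'full'")
    report: dict = {"excluded_seizures": excluded, "units": {}}
    pvals = {}
    for name, df in units.items():
        tl = make_timeline(df, intervals)
        res = evaluate_timeline(
            tl,
            cfg.history,
            cfg.classifier,
            cfg.cv,
            cfg.seed,
            cfg.n_surrogates,
            cfg.surrogate_classifier,
            cfg.lstm,
            cfg.gbt,
        )
        report["units"][name] = res
        if "p" in res:
            pvals[name] = res["p"]
    if pvals:
        fdr = fdr_flags(pvals, cfg.alphas)
        report["fdr"] = fdr
    return report
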