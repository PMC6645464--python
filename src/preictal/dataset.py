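"""Labeling, sample construction and leave-one-seizure-out cross-validation.

The classification task contrasts two states of a long recording:

* **preictal** -- the hour ending five minutes before a seizure onset
  (``[onset - 65 min, onset - 5 min]`` by default; the 5-minute guard absorbs
  uncertainty in clinically determined onset times);
* **interictal** -- baseline at least four hours away from every onset.

Feature windows (4 s long, 2 s steps) falling inside labeled intervals are
assembled into ordered histories of ``n`` consecutive windows
(n in {2, 3, 5, 10, 15, 25}, spanning 6..52 s). Training samples are
oversampled with a one-window stride, so consecutive samples overlap by
(n-1)/n; test samples tile each interval in non-overlapping blocks of ``n``
windows. Folds hold out one seizure's preictal data together with the
interictal block nearest in time to that seizure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WINDOW_S",
    "STEP_S",
    "HISTORY_LENGTHS",
    "LabelingConfig",
    "LabeledInterval",
    "WindowTimeline",
    "SampleSet",
    "CVFold",
    "history_span_s",
    "train_overlap_fraction",
    "build_timeline_labels",
    "label_windows",
    "make_timeline",
    "make_samples",
    "loso_folds",
    "shuffled_window_cv",
    "class_weights",
]

WINDOW_S = 4.0
STEP_S = 2.0
HISTORY_LENGTHS = (2, 3, 5, 10, 15, 25)

INTERICTAL, PREICTAL, UNLABELED = 0, 1, -1


def history_span_s(n: int) -> float:
    """Seconds of signal covered by n consecutive 4-s windows at 50% overlap."""
    return (n - 1) * STEP_S + WINDOW_S


def train_overlap_fraction(n: int) -> float:
    """Window-share between consecutive (one-window-stride) training samples."""
    return (n - 1) / n


@dataclass(frozen=True)
class LabelingConfig:
    """Timing rules tying labels to seizure onsets (seconds).

    Defaults are the clinical-scale rules; :meth:`scaled` shrinks all three
    proportionally for compact synthetic recordings.
    """

    preictal_start_s: float = 65 * 60.0
    preictal_gap_s: float = 5 * 60.0
    interictal_margin_s: float = 4 * 3600.0

    def scaled(self, factor: float) -> "LabelingConfig":
        return LabelingConfig(
            self.preictal_start_s * factor,
            self.preictal_gap_s * factor,
            self.interictal_margin_s * factor,
        )


@dataclass(frozen=True)
class LabeledInterval:
    t_start: float
    t_end: float
    label: int  # INTERICTAL or PREICTAL
    seizure_id: int | None = None

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def _subtract(intervals: list[tuple[float, float]], holes: list[tuple[float, float]]):
    out = list(intervals)
    for h0, h1 in holes:
        nxt = []
        for a, b in out:
            if h1 <= a or h0 >= b:
                nxt.append((a, b))
                continue
            if a < h0:
                nxt.append((a, h0))
            if h1 < b:
                nxt.append((h1, b))
        out = nxt
    return [(a, b) for a, b in out if b - a > 1e-9]


def build_timeline_labels(
    onsets,
    extent: float,
    artifacts: list[tuple[float, float]] = (),
    cfg: LabelingConfig = LabelingConfig(),
) -> tuple[list[LabeledInterval], list[int]]:
    """Label a recording from its seizure onsets.

    Returns (intervals, excluded) where ``excluded`` lists indices of seizures
    dropped because another onset fell inside their preictal span or because
    clipping (recording start, artifacts, earlier onsets) emptied it.
    """
    onsets = sorted(float(o) for o in onsets)
    if any(o < 0 or o > extent for o in onsets):
        raise ValueError("seizure onsets must lie within the recording extent")
    intervals: list[LabeledInterval] = []
    excluded: list[int] = []
    sid = 0
    for k, onset in enumerate(onsets):
        lo = max(0.0, onset - cfg.preictal_start_s)
        hi = onset - cfg.preictal_gap_s
        if hi <= lo:
            excluded.append(k)
            continue
        if any(lo <= o <= onset for j, o in enumerate(onsets) if j != k):
            # another seizure's ictal time inside this preictal+gap span
            excluded.append(k)
            warnings.warn(f"seizure {k} excluded: another onset inside its preictal span")
            continue
        pieces = _subtract([(lo, hi)], [(0.0, 0.0)] + list(artifacts))
        # clip at any earlier seizure's ictal time (point onset)
        pieces = [(max(a, max((o for o in onsets if o < onset), default=0.0)), b) for a, b in pieces]
        pieces = [(a, b) for a, b in pieces if b - a > 1e-9]
        if not pieces:
            excluded.append(k)
            warnings.warn(f"seizure {k} excluded: empty preictal interval after clipping")
            continue
        for a, b in pieces:
            intervals.append(LabeledInterval(a, b, PREICTAL, sid))
        sid += 1
    holes = [(o - cfg.interictal_margin_s, o + cfg.interictal_margin_s) for o in onsets]
    for a, b in _subtract([(0.0, extent)], holes + list(artifacts)):
        intervals.append(LabeledInterval(a, b, INTERICTAL))
    intervals.sort(key=lambda iv: iv.t_start)
    return intervals, excluded


@dataclass
class WindowTimeline:
    """Per-window feature matrix with labels on the 2-s window grid.

    ``label`` is -1 for unlabeled/excluded windows; ``seizure`` is the id of
    the seizure a preictal window precedes (-1 otherwise).
    """

    t: np.ndarray  # window start times, seconds
    X: np.ndarray  # n_windows x n_features
    label: np.ndarray  # int8
    seizure: np.ndarray  # int32
    columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.X = np.asarray(self.X)
        self.label = np.asarray(self.label, dtype=np.int8)
        self.seizure = np.asarray(self.seizure, dtype=np.int32)
        if not self.columns:
            self.columns = [f"f{i}" for i in range(self.X.shape[1])]

    @property
    def n_windows(self) -> int:
        return self.t.size

    def restrict(self, mask: np.ndarray) -> "WindowTimeline":
        return WindowTimeline(self.t[mask], self.X[mask], self.label[mask], self.seizure[mask], self.columns)

    def select_columns(self, names: list[str]) -> "WindowTimeline":
        idx = [self.columns.index(c) for c in names]
        return WindowTimeline(self.t, self.X[:, idx], self.label, self.seizure, list(names))


def label_windows(times: np.ndarray, intervals: list[LabeledInterval]):
    """Assign each 4-s window the label of the interval fully containing it."""
    times = np.asarray(times, dtype=float)
    label = np.full(times.size, UNLABELED, dtype=np.int8)
    seizure = np.full(times.size, -1, dtype=np.int32)
    for iv in intervals:
        m = (times >= iv.t_start - 1e-9) & (times + WINDOW_S <= iv.t_end + 1e-9)
        label[m] = iv.label
        if iv.label == PREICTAL:
            seizure[m] = iv.seizure_id
    return label, seizure


def make_timeline(features: pd.DataFrame, intervals: list[LabeledInterval]) -> WindowTimeline:
    """Build a labeled timeline from a window-indexed feature table."""
    t = features.index.to_numpy(dtype=float)
    label, seizure = label_windows(t, intervals)
    return WindowTimeline(t, features.to_numpy(), label, seizure, list(features.columns))


@dataclass
class SampleSet:
    """Ordered histories of ``n`` consecutive windows, referenced by start index."""

    starts: np.ndarray  # index into the timeline of each sample's first window
    n: int
    label: np.ndarray
    seizure: np.ndarray
    t_start: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.starts.size

    def tensor(self, timeline: WindowTimeline) -> np.ndarray:
        """Stack samples into (n_samples, n, n_features)."""
        idx = self.starts[:, None] + np.arange(self.n)[None, :]
        return timeline.X[idx]

    def span_s(self) -> float:
        return history_span_s(self.n)


def _runs(timeline: WindowTimeline):
    """Maximal runs of consecutive windows with one label and seizure id."""
    t, lab, sz = timeline.t, timeline.label, timeline.seizure
    n = t.size
    runs = []
    i = 0
    while i < n:
        if lab[i] < 0:
            i += 1
            continue
        j = i + 1
        while (
            j < n
            and lab[j] == lab[i]
            and sz[j] == sz[i]
            and abs(t[j] - t[j - 1] - STEP_S) < 1e-6
        ):
            j += 1
        runs.append((i, j))
        i = j
    return runs


def make_samples(timeline: WindowTimeline, n: int, role: str = "train") -> SampleSet:
    """Slice labeled runs into histories of ``n`` windows.

    ``role='train'`` strides by one window (oversampling: consecutive samples
    share (n-1)/n of their windows); ``role='test'`` tiles each run in
    non-overlapping blocks of ``n`` windows.
    """
    if n not in HISTORY_LENGTHS:
        raise ValueError(f"history length must be one of {HISTORY_LENGTHS}")
    if role not in ("train", "test"):
        raise ValueError("role must be 'train' or 'test'")
    stride = 1 if role == "train" else n
    starts = []
    for i, j in _runs(timeline):
        starts.extend(range(i, j - n + 1, stride))
    starts = np.asarray(starts, dtype=np.int64)
    return SampleSet(
        starts,
        n,
        timeline.label[starts] if starts.size else np.empty(0, dtype=np.int8),
        timeline.seizure[starts] if starts.size else np.empty(0, dtype=np.int32),
        timeline.t[starts] if starts.size else np.empty(0),
    )


@dataclass
class CVFold:
    held_out_seizure: int
    train_timeline: WindowTimeline
    test_timeline: WindowTimeline
    train: SampleSet
    test: SampleSet


def _seizure_anchors(timeline: WindowTimeline) -> dict[int, float]:
    """Anchor time per seizure: end of its last preictal window (~ onset)."""
    anchors = {}
    pre = timeline.label == PREICTAL
    for sid in np.unique(timeline.seizure[pre]):
        anchors[int(sid)] = float(timeline.t[pre & (timeline.seizure == sid)].max() + WINDOW_S)
    return anchors


def loso_folds(timeline: WindowTimeline, n: int, test_overlap: bool = False) -> list[CVFold]:
    """Leave-one-seizure-out folds.

    Each fold's test set holds the target seizure's preictal windows plus the
    interictal windows nearest in time to that seizure (contiguous block
    assignment: every interictal window goes to the fold of its closest
    seizure anchor). Training samples use the one-window oversampling stride;
    test samples are non-overlapping unless ``test_overlap``.
    """
    anchors = _seizure_anchors(timeline)
    sids = sorted(anchors)
    if len(sids) < 2:
        raise ValueError("leave-one-seizure-out needs at least 2 seizures")
    anchor_arr = np.array([anchors[s] for s in sids])
    mid = timeline.t + WINDOW_S / 2
    nearest = np.asarray(sids)[np.argmin(np.abs(mid[:, None] - anchor_arr[None, :]), axis=1)]
    folds = []
    for sid in sids:
        is_pre_target = (timeline.label == PREICTAL) & (timeline.seizure == sid)
        is_int_target = (timeline.label == INTERICTAL) & (nearest == sid)
        test_mask = is_pre_target | is_int_target
        train_mask = (timeline.label >= 0) & ~test_mask
        tl_tr = timeline.restrict(train_mask)
        tl_te = timeline.restrict(test_mask)
        folds.append(
            CVFold(
                held_out_seizure=sid,
                train_timeline=tl_tr,
                test_timeline=tl_te,
                train=make_samples(tl_tr, n, "train"),
                test=make_samples(tl_te, n, "train" if test_overlap else "test"),
            )
        )
    return folds


def shuffled_window_cv(timeline: WindowTimeline, n: int, seed: int) -> list[CVFold]:
    """Control variant: permute sample order before fold assignment.

    Histories are built on the original window order, then randomly assigned
    to as many folds as there are seizures. Temporal contiguity between train
    and test is deliberately broken; predictive scores under this scheme
    overestimate prospective performance.
    """
    anchors = _seizure_anchors(timeline)
    k = len(anchors)
    if k < 2:
        raise ValueError("need at least 2 seizures' worth of folds")
    labeled = timeline.restrict(timeline.label >= 0)
    samples = make_samples(labeled, n, "train")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(samples.n_samples)
    fold_of = np.empty(samples.n_samples, dtype=int)
    fold_of[perm] = np.arange(samples.n_samples) % k
    folds = []
    for f in range(k):
        te = fold_of == f
        folds.append(
            CVFold(
                held_out_seizure=f,
                train_timeline=labeled,
                test_timeline=labeled,
                train=SampleSet(samples.starts[~te], n, samples.label[~te], samples.seizure[~te], samples.t_start[~te]),
                test=SampleSet(samples.starts[te], n, samples.label[te], samples.seizure[te], samples.t_start[te]),
            )
        )
    return folds


def class_weights(labels: np.ndarray) -> dict[int, float]:
    """Cost-sensitive weights: w(preictal)/w(interictal) = n_inter/n_pre."""
    labels = np.asarray(labels)
    n0 = int((labels == INTERICTAL).sum())
    n1 = int((labels == PREICTAL).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present to derive class weights")
    return {INTERICTAL: 1.0, PREICTAL: n0 / n1}
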