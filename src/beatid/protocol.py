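"""Health-state-aware identification protocol.

The question the protocol answers: how well can a person be identified
from beats whose health state differs from the beats they enrolled with?
Four scenarios cover the combinations: ``N_vs_N`` (train and test on
normal beats, a stratified within-pool split), ``N_vs_A`` (train on all of
a subject's normal beats, test on their arrhythmic beats — optionally one
arrhythmia type), ``A_vs_N`` (reversed) and ``A_vs_A`` (within-pool split
of arrhythmic beats).  Train and test beats are always disjoint, and a
subject enters a scenario only with enough beats in both required pools.

Evaluation reports the confusion matrix; per-class one-vs-rest accuracy,
specificity, recall, precision and F1 with macro averages; FAR/FRR curves
per enrolled identity swept over score thresholds; and the empirical CDF
of the score assigned to the true identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ArchitectureSpec, build_model
from .nn import Adam, Sequential, softmax_cross_entropy
from .recordio import BeatDataset
from .scalogram import ScalogramConfig, segment_to_image
from .segment import DEFAULT_WINDOW_LEN, r_offset_fraction, segment_beats

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "make_split",
    "images_from_segments",
    "IdentifierModel",
    "train_identifier",
    "EvalReport",
    "evaluate",
    "roc_curves",
    "cdf_curve",
    "scenario_report",
]

SCENARIOS = ("N_vs_N", "N_vs_A", "A_vs_N", "A_vs_A")


@dataclass(frozen=True)
class SplitSpec:
    scenario: str
    arrhythmia_filter: str = "all"  # "all" or one symbol
    train_fraction: float = 0.7
    min_beats: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class SplitResult:
    train_idx: np.ndarray
    test_idx: np.ndarray
    subjects: list[str]  # label space, sorted
    excluded: dict[str, str]  # subject -> reason


def _pool_masks(ds: BeatDataset, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """(train-pool mask, test-pool mask) before eligibility filtering."""
    is_n = ds.labels == "N"
    if spec.arrhythmia_filter == "all":
        is_a = ~is_n
    else:
        is_a = ds.labels == spec.arrhythmia_filter
    pools = {
        "N_vs_N": (is_n, is_n),
        "N_vs_A": (is_n, is_a),
        "A_vs_N": (is_a, is_n),
        "A_vs_A": (is_a, is_a),
    }
    return pools[spec.scenario]


def make_split(ds: BeatDataset, spec: SplitSpec) -> SplitResult:
    """Build disjoint train/test index sets under the scenario's rules.

    Cross-pool scenarios (N_vs_A, A_vs_N) use the full pools; within-pool
    scenarios split each subject's pool at ``train_fraction`` with a seeded
    shuffle (train size = round(fraction * n), at least 1 each side).
    Subjects lacking ``min_beats`` in a required pool are excluded and
    reported with the reason.
    """
    train_pool, test_pool = _pool_masks(ds, spec)
    within = spec.scenario in ("N_vs_N", "A_vs_A")
    rng = np.random.default_rng(spec.seed)

    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    subjects: list[str] = []
    excluded: dict[str, str] = {}
    for subj in sorted(set(ds.subjects.tolist())):
        mine = ds.subjects == subj
        tr = np.flatnonzero(mine & train_pool)
        te = np.flatnonzero(mine & test_pool)
        if within:
            if tr.size < max(2 * spec.min_beats, 2):
                excluded[subj] = (
                    f"only {tr.size} beats in the shared pool "
                    f"(needs {max(2 * spec.min_beats, 2)})"
                )
                continue
            perm = rng.permutation(tr)
            n_train = int(round(spec.train_fraction * tr.size))
            n_train = min(max(n_train, 1), tr.size - 1)
            train_idx.append(perm[:n_train])
            test_idx.append(perm[n_train:])
        else:
            if tr.size < spec.min_beats or te.size < spec.min_beats:
                excluded[subj] = (
                    f"train pool {tr.size}, test pool {te.size} "
                    f"(needs {spec.min_beats} each)"
                )
                continue
            train_idx.append(tr)
            test_idx.append(te)
        subjects.append(subj)
    if not subjects:
        raise ValueError(
            f"no eligible subjects for scenario {spec.scenario} "
            f"(filter {spec.arrhythmia_filter!r})"
        )
    return SplitResult(
        train_idx=np.sort(np.concatenate(train_idx)),
        test_idx=np.sort(np.concatenate(test_idx)),
        subjects=subjects,
        excluded=excluded,
    )


def dataset_from_records(
    records,
    window_len: int = DEFAULT_WINDOW_LEN,
    r_frac: float | None = None,
) -> BeatDataset:
    """Segment a list of (synthetic or WFDB-derived) records into a dataset.

    Accepts any objects exposing ``signal`` (1-D), ``fs``, ``ann_samples``,
    ``ann_symbols`` and ``subject_id``; beats at record boundaries are
    silently discarded, as in :func:`beatid.segment.segment_beats`.
    """
    if r_frac is None:
        r_frac = r_offset_fraction()
    windows, labels, subjects = [], [], []
    fs = None
    for rec in records:
        fs = rec.fs
        sig = rec.signal if rec.signal.ndim == 1 else rec.signal[:, 0]
        result = segment_beats(
            sig, rec.ann_samples, rec.ann_symbols, rec.subject_id,
            window_len=window_len, r_frac=r_frac,
        )
        for seg in result.segments:
            windows.append(seg.window)
            labels.append(seg.label)
            subjects.append(seg.subject_id)
    return BeatDataset(
        X=np.asarray(windows, dtype=np.float32),
        labels=np.asarray(labels),
        subjects=np.asarray(subjects),
        fs=float(fs),
        kind="segments",
        r_index=int(np.floor(r_frac * window_len)),
        config={"window_len": window_len, "r_frac": r_frac},
    )


def images_from_segments(
    ds: BeatDataset, config: ScalogramConfig = ScalogramConfig()
) -> BeatDataset:
    """Map every beat window in a segment dataset to its scalogram image."""
    if ds.kind != "segments":
        raise ValueError("expected a segment dataset")
    imgs = np.stack(
        [segment_to_image(ds.X[i], config).pixels for i in range(len(ds))]
    )
    cfg = dict(ds.config)
    cfg["scalogram"] = {
        "wavelet": config.wavelet,
        "fmin": config.fmin,
        "fmax": config.fmax,
        "voices_per_octave": config.voices_per_octave,
        "out_size": config.out_size,
        "colormap": config.colormap,
        "normalization": config.normalization,
    }
    return BeatDataset(
        X=imgs,
        labels=ds.labels.copy(),
        subjects=ds.subjects.copy(),
        fs=ds.fs,
        kind="images",
        config=cfg,
    )


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 10
    lr: float = 1e-3
    batch_size: int = 64
    seed: int = 0


@dataclass
class IdentifierModel:
    """A trained network together with its identity label space."""

    net: Sequential
    classes: list[str]  # index -> subject id
    history: pd.DataFrame  # per-epoch loss / accuracy
    config: TrainConfig
    spec: ArchitectureSpec

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(images.astype(np.float32))


def train_identifier(
    spec: ArchitectureSpec,
    train_ds: BeatDataset,
    config: TrainConfig = TrainConfig(),
) -> IdentifierModel:
    """Train the identification network on an image dataset.

    Deterministic given the config seed: weight initialization and the
    per-epoch shuffle both derive from it.
    """
    classes = sorted(set(train_ds.subjects.tolist()))
    if len(classes) < 2:
        raise ValueError("training set must contain at least 2 subjects")
    if spec.n_classes != len(classes):
        raise ValueError(
            f"spec declares {spec.n_classes} classes but the training set "
            f"has {len(classes)} subjects"
        )
    if train_ds.kind != "images" or train_ds.X.shape[1:] != spec.input_shape:
        raise ValueError(f"training images must have shape {spec.input_shape}")
    class_of = {c: i for i, c in enumerate(classes)}
    y = np.array([class_of[s] for s in train_ds.subjects], dtype=np.int64)
    x = train_ds.X.astype(np.float32)

    net = build_model(spec, seed=config.seed)
    opt = Adam(net, lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    for epoch in range(config.epochs):
        order = rng.permutation(x.shape[0])
        losses, correct = [], 0
        for i in range(0, x.shape[0], config.batch_size):
            idx = order[i : i + config.batch_size]
            logits = net.forward(x[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y[idx])
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
        rows.append(
            {
                "epoch": epoch + 1,
                "loss": float(np.mean(losses)),
                "accuracy": correct / x.shape[0],
            }
        )
    return IdentifierModel(
        net=net,
        classes=classes,
        history=pd.DataFrame(rows),
        config=config,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# metrics


@dataclass
class EvalReport:
    confusion: pd.DataFrame  # rows = true subject, cols = predicted
    per_class: pd.DataFrame  # one-vs-rest metrics per subject
    macro: dict[str, float]
    accuracy: float
    roc: dict[str, pd.DataFrame]  # subject -> (threshold, far, frr)
    cdf: pd.DataFrame  # (score, cumulative_fraction)
    scores: np.ndarray = field(repr=False, default=None)
    y_true: np.ndarray = field(repr=False, default=None)


def _one_vs_rest_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """The five confusion-matrix metrics; undefined ratios become NaN."""

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    precision = ratio(tp, tp + fp)
    recall = ratio(tp, tp + fn)
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else float("nan")
    )
    return {
        "accuracy": ratio(tp + tn, tp + fp + fn + tn),
        "specificity": ratio(tn, fp + tn),
        "recall": recall,
        "precision": precision,
        "f1": f1,
    }


def evaluate(model: IdentifierModel, test_ds: BeatDataset) -> EvalReport:
    """Score a test image dataset: confusion matrix, metrics, ROC, CDF."""
    unseen = set(test_ds.subjects.tolist()) - set(model.classes)
    if unseen:
        raise ValueError(f"test subjects absent from the model: {sorted(unseen)}")
    scores = model.predict_proba(test_ds.X)
    class_of = {c: i for i, c in enumerate(model.classes)}
    y_true = np.array([class_of[s] for s in test_ds.subjects], dtype=np.int64)
    y_pred = scores.argmax(axis=1)  # ties resolve to the lowest class index

    k = len(model.classes)
    conf = np.zeros((k, k), dtype=np.int64)
    np.add.at(conf, (y_true, y_pred), 1)
    confusion = pd.DataFrame(conf, index=model.classes, columns=model.classes)

    rows = {}
    total = int(conf.sum())
    for ci, cls in enumerate(model.classes):
        tp = int(conf[ci, ci])
        fp = int(conf[:, ci].sum() - tp)
        fn = int(conf[ci, :].sum() - tp)
        tn = total - tp - fp - fn
        rows[cls] = _one_vs_rest_metrics(tp, fp, fn, tn)
    per_class = pd.DataFrame(rows).T
    macro = {}
    for m in per_class.columns:
        vals = per_class[m].to_numpy()
        vals = vals[~np.isnan(vals)]  # undefined cells stay out of the average
        macro[m] = float(vals.mean()) if vals.size else float("nan")

    return EvalReport(
        confusion=confusion,
        per_class=per_class,
        macro=macro,
        accuracy=float(np.trace(conf)) / total,
        roc=roc_curves(scores, y_true, model.classes),
        cdf=cdf_curve(scores, y_true),
        scores=scores,
        y_true=y_true,
    )


def roc_curves(
    scores: np.ndarray, y_true: np.ndarray, classes: list[str]
) -> dict[str, pd.DataFrame]:
    """One-vs-rest FAR/FRR sweeps per enrolled identity.

    Acceptance rule at threshold t: score >= t.  FAR = accepted impostors /
    impostors, FRR = rejected genuines / genuines.  Thresholds are the
    sorted unique observed scores plus a point above the maximum, so both
    degenerate operating points (accept all, reject all) are present.  A
    class with no genuine samples yields None (undefined, not fabricated).
    """
    out: dict[str, pd.DataFrame] = {}
    for ci, cls in enumerate(classes):
        genuine = scores[y_true == ci, ci]
        impostor = scores[y_true != ci, ci]
        if genuine.size == 0:
            out[cls] = None
            continue
        thresholds = np.unique(np.concatenate([scores[:, ci], [np.inf]]))
        far = np.array(
            [
                (impostor >= t).mean() if impostor.size else float("nan")
                for t in thresholds
            ]
        )
        frr = np.array([(genuine < t).mean() for t in thresholds])
        out[cls] = pd.DataFrame(
            {"threshold": thresholds, "far": far, "frr": frr}
        )
    return out


def cdf_curve(scores: np.ndarray, y_true: np.ndarray) -> pd.DataFrame:
    """Empirical CDF of the score assigned to the true identity."""
    s = np.sort(scores[np.arange(len(y_true)), y_true])
    frac = np.arange(1, s.size + 1) / s.size
    return pd.DataFrame({"score": s, "cumulative_fraction": frac})


def confusion_margins(confusion: pd.DataFrame) -> pd.DataFrame:
    """Per-class TPR/FNR (row margins) and FPR/TNR (column margins)."""
    conf = confusion.to_numpy(dtype=float)
    total = conf.sum()
    rows = {}
    for ci, cls in enumerate(confusion.index):
        tp = conf[ci, ci]
        row = conf[ci, :].sum()
        col = conf[:, ci].sum()
        fp = col - tp
        neg = total - row
        rows[cls] = {
            "tpr": tp / row if row else float("nan"),
            "fnr": (row - tp) / row if row else float("nan"),
            "fpr": fp / neg if neg else float("nan"),
            "tnr": (neg - fp) / neg if neg else float("nan"),
        }
    return pd.DataFrame(rows).T


def scenario_report(
    images: BeatDataset,
    scenarios: list[SplitSpec],
    train_config: TrainConfig = TrainConfig(),
) -> pd.DataFrame:
    """Run each scenario end-to-end and tabulate the macro metrics.

    One row per (scenario, arrhythmia filter): number of enrolled subjects,
    train/test sizes, overall accuracy and the macro-averaged one-vs-rest
    metrics.  Cells whose metric is undefined (zero-division in the
    confusion matrix) are NaN.
    """
    rows = []
    for split_spec in scenarios:
        split = make_split(images, split_spec)
        train_ds = images.select(split.train_idx)
        test_ds = images.select(split.test_idx)
        spec = ArchitectureSpec(n_classes=len(split.subjects))
        model = train_identifier(spec, train_ds, train_config)
        report = evaluate(model, test_ds)
        rows.append(
            {
                "scenario": split_spec.scenario,
                "arrhythmia_filter": split_spec.arrhythmia_filter,
                "n_subjects": len(split.subjects),
                "n_train": int(split.train_idx.size),
                "n_test": int(split.test_idx.size),
                "accuracy": report.accuracy,
                **{f"macro_{k}": v for k, v in report.macro.items()},
            }
        )
    return pd.DataFrame(rows)
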