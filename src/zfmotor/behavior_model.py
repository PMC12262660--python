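"""Semi-supervised behavior classification.

Clip mining uses KMeans (k=9) on flattened, normalized behavior windows to
separate stationary from moving windows, so that candidate clips can be
pulled out for manual class labelling.  The supervised model is a PCA
(retaining 95% of the variance, seed 2023, no whitening) followed by a
random forest, trained per plate format on a 90/10 stratified split of the
labelled clips.  Everything needed for inference — normalization
constants, the fitted PCA basis, the forest, the class set and the window
layout — is serialized together in a :class:`ModelBundle`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, f1_score, precision_recall_fscore_support

from . import __version__ as _pkg_version
from .config import CLASS_SETS, RunConfig
from .keypoint_io import PoseTrack
from .preprocess import (
    FLATTEN_ORDER,
    Normalizer,
    egocentric_align,
    flatten_windows,
    make_windows,
    window_starts,
)

__all__ = [
    "MiningResult",
    "ModelBundle",
    "EvalReport",
    "kmeans_mine",
    "extract_clips",
    "split_train_test",
    "train",
    "predict",
    "predict_track",
    "evaluate",
    "umap_embed",
]


# ---------------------------------------------------------------------------
# Unsupervised clip mining
# ---------------------------------------------------------------------------

@dataclass
class MiningResult:
    """KMeans assignments plus which clusters look stationary."""

    assignments: np.ndarray  # cluster id per window
    stationary_clusters: tuple[int, ...]
    cluster_mean_displacement_mm: np.ndarray  # per cluster
    k: int

    def is_stationary(self) -> np.ndarray:
        return np.isin(self.assignments, self.stationary_clusters)


def kmeans_mine(
    features: np.ndarray,
    displacement_mm: np.ndarray,
    k: int = 9,
    seed: int = 2023,
    stationary_path_mm: float = 0.5,
) -> MiningResult:
    """Cluster feature vectors and flag stationary clusters.

    A cluster is flagged stationary when the mean within-window net
    center displacement of its members falls below ``stationary_path_mm``.
    The flags are used only to mine movement vs stationary clips for
    manual labelling, never as final class labels.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise ValueError("features must be a 2-D (windows x features) matrix")
    if len(features) < k:
        raise ValueError(f"need at least k={k} feature vectors, got {len(features)}")
    n_distinct = len(np.unique(features, axis=0))
    if n_distinct < k:
        raise ValueError(
            f"only {n_distinct} distinct feature vectors for k={k}; "
            "clustering would be degenerate"
        )
    displacement_mm = np.asarray(displacement_mm, dtype=float)
    if len(displacement_mm) != len(features):
        raise ValueError("displacement_mm must parallel features")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    assignments = km.fit_predict(features)
    mean_path = np.array(
        [
            displacement_mm[assignments == c].mean() if (assignments == c).any()
            else np.inf
            for c in range(k)
        ]
    )
    stationary = tuple(int(c) for c in np.flatnonzero(mean_path < stationary_path_mm))
    return MiningResult(
        assignments=assignments,
        stationary_clusters=stationary,
        cluster_mean_displacement_mm=mean_path,
        k=k,
    )


def extract_clips(
    track: PoseTrack,
    window_indices: np.ndarray,
    out_dir: str | Path,
    W: int = 40,
    render: bool = False,
) -> list[Path]:
    """Export selected windows of a track as per-clip coordinate CSVs.

    Clips are named ``{well}_{start_frame}`` (CSV columns
    ``frame,keypoint_index,y,x`` with frame indices relative to the
    track).  With ``render=True`` a PNG trajectory sketch is written next
    to each CSV for quick visual review.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    starts = window_starts(track.frames, W)
    window_indices = np.asarray(window_indices, dtype=int)
    if window_indices.size and (
        window_indices.min() < 0 or window_indices.max() >= len(starts)
    ):
        raise IndexError("window index out of range")
    paths = []
    for idx in window_indices:
        s = int(starts[idx])
        clip = track.coords[s : s + W]
        frame = np.repeat(np.arange(s, s + W), 8)
        kp = np.tile(np.arange(8), W)
        df = pd.DataFrame(
            {
                "frame": frame,
                "keypoint_index": kp,
                "y": clip[:, :, 0].ravel(),
                "x": clip[:, :, 1].ravel(),
            }
        )
        path = out_dir / f"{track.well_id}_{s}.csv"
        df.to_csv(path, index=False)
        if render:
            _render_clip_png(clip, path.with_suffix(".png"))
        paths.append(path)
    return paths


def _render_clip_png(clip: np.ndarray, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3, 3))
    for t in range(0, len(clip), max(len(clip) // 8, 1)):
        ax.plot(clip[t, :, 1], clip[t, :, 0], "-o", ms=2, alpha=0.5)
    ax.invert_yaxis()
    ax.set_aspect("equal")
    fig.savefig(path, dpi=80)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Supervised training
# ---------------------------------------------------------------------------

def split_train_test(
    labels: np.ndarray,
    train_fraction: float = 0.9,
    seed: int = 2023,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified 90/10 split; returns (train_idx, test_idx).

    Each class is split independently to within one clip of the target
    fraction, with at least one clip per class on each side — so tiny
    classes (down to 2 clips) still appear in both subsets.
    """
    labels = np.asarray(labels)
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        raise ValueError("need at least 2 clips per class to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in sorted(counts.index):
        cls_idx = np.flatnonzero(labels == cls)
        n = len(cls_idx)
        n_train = int(np.clip(round(train_fraction * n), 1, n - 1))
        perm = rng.permutation(cls_idx)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    return (
        np.sort(np.concatenate(train_idx)),
        np.sort(np.concatenate(test_idx)),
    )


@dataclass
class ModelBundle:
    """Everything needed to reproduce inference, serializable as a directory."""

    normalizer: Normalizer
    pca: PCA
    forest: RandomForestClassifier
    classes: tuple[str, ...]
    plate_format: str
    W: int = 40
    stride: int = 1
    flatten_order: str = FLATTEN_ORDER
    metadata: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.W * 8 * 2

    def featurize(self, windows: np.ndarray) -> np.ndarray:
        """Aligned windows -> normalized flat feature vectors."""
        return flatten_windows(self.normalizer.apply(windows))

    def save(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "classes": list(self.classes),
            "plate_format": self.plate_format,
            "W": self.W,
            "stride": self.stride,
            "flatten_order": self.flatten_order,
            "normalizer": self.normalizer.to_dict(),
            "metadata": self.metadata,
            "package_version": _pkg_version,
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        joblib.dump({"pca": self.pca, "forest": self.forest}, out_dir / "model.joblib")
        return out_dir

    @classmethod
    def load(cls, in_dir: str | Path) -> "ModelBundle":
        in_dir = Path(in_dir)
        manifest = json.loads((in_dir / "manifest.json").read_text())
        fitted = joblib.load(in_dir / "model.joblib")
        return cls(
            normalizer=Normalizer.from_dict(manifest["normalizer"]),
            pca=fitted["pca"],
            forest=fitted["forest"],
            classes=tuple(manifest["classes"]),
            plate_format=manifest["plate_format"],
            W=manifest["W"],
            stride=manifest["stride"],
            flatten_order=manifest["flatten_order"],
            metadata=manifest.get("metadata", {}),
        )


def train(
    clips: np.ndarray,
    labels: np.ndarray,
    config: RunConfig | None = None,
) -> ModelBundle:
    """Fit normalizer -> PCA -> random forest on labelled training clips.

    ``clips`` are raw (N, W, 8, 2) pixel-coordinate clips; they are
    egocentrically aligned here, the normalizer is fitted on the aligned
    training set only, and the PCA keeps enough components for 95% of the
    training variance (no whitening, fixed seed).  Raises if any class of
    the plate format's class set is missing from the labels.
    """
    config = config or RunConfig()
    labels = np.asarray(labels)
    class_set = CLASS_SETS[config.plate_format]
    missing = [c for c in class_set if c not in labels]
    if missing:
        raise ValueError(f"class absent from training data: {missing}")
    if len(clips) < 2:
        raise ValueError("PCA needs at least 2 training clips")
    aligned = egocentric_align(np.asarray(clips, dtype=float))
    normalizer = Normalizer.fit(aligned, plate_format=config.plate_format)
    X = flatten_windows(normalizer.apply(aligned))
    pca = PCA(
        n_components=config.pca_variance,
        whiten=False,
        random_state=config.pca_seed,
        svd_solver="full",
    )
    Xp = pca.fit_transform(X)
    forest = RandomForestClassifier(
        n_estimators=config.rf_trees,
        random_state=config.rf_seed,
        n_jobs=1,
    )
    forest.fit(Xp, labels)
    class_counts = pd.Series(labels).value_counts().to_dict()
    return ModelBundle(
        normalizer=normalizer,
        pca=pca,
        forest=forest,
        classes=class_set,
        plate_format=config.plate_format,
        W=config.window_frames,
        stride=config.stride,
        metadata={
            "class_counts": {k: int(v) for k, v in class_counts.items()},
            "pca_components": int(pca.n_components_),
            "pca_explained_variance": float(pca.explained_variance_ratio_.sum()),
            "config": config.to_dict(),
        },
    )


def predict(bundle: ModelBundle, features: np.ndarray) -> np.ndarray:
    """Per-window motor calls from normalized flat feature vectors."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[1] != bundle.n_features:
        raise ValueError(
            f"feature length {features.shape[1]} != W*8*2 = {bundle.n_features}"
        )
    return bundle.forest.predict(bundle.pca.transform(features)).astype("<U10")


def predict_track(bundle: ModelBundle, track: PoseTrack) -> np.ndarray:
    """Slide windows over a full track and call each one."""
    windows = make_windows(track, W=bundle.W, stride=bundle.stride)
    aligned = egocentric_align(windows)
    return predict(bundle, bundle.featurize(aligned))


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Row-normalized confusion matrix and F1 summaries for a test set."""

    confusion: pd.DataFrame  # true x predicted, rows sum to 1
    per_class: pd.DataFrame  # precision / recall / f1 / support
    f1_micro: float
    f1_macro: float
    f1_weighted: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "confusion": self.confusion.to_dict(),
                "per_class": self.per_class.to_dict(),
                "f1_micro": self.f1_micro,
                "f1_macro": self.f1_macro,
                "f1_weighted": self.f1_weighted,
            },
            indent=2,
        )

    def save(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "eval.json").write_text(self.to_json())
        self.confusion.to_csv(out_dir / "confusion.csv")
        return out_dir


def evaluate(
    bundle: ModelBundle, test_clips: np.ndarray, test_labels: np.ndarray
) -> EvalReport:
    """Compare predictions on held-out clips with their manual labels."""
    test_labels = np.asarray(test_labels)
    aligned = egocentric_align(np.asarray(test_clips, dtype=float))
    pred = predict(bundle, bundle.featurize(aligned))
    classes = list(bundle.classes)
    cm = confusion_matrix(test_labels, pred, labels=classes).astype(float)
    row_sums = cm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        cm_norm = np.where(row_sums > 0, cm / row_sums, 0.0)
    prec, rec, f1, support = precision_recall_fscore_support(
        test_labels, pred, labels=classes, zero_division=0
    )
    return EvalReport(
        confusion=pd.DataFrame(cm_norm, index=classes, columns=classes),
        per_class=pd.DataFrame(
            {"precision": prec, "recall": rec, "f1": f1, "support": support},
            index=classes,
        ),
        f1_micro=float(f1_score(test_labels, pred, average="micro")),
        f1_macro=float(f1_score(test_labels, pred, average="macro")),
        f1_weighted=float(f1_score(test_labels, pred, average="weighted")),
    )


def umap_embed(features: np.ndarray, seed: int = 2023) -> np.ndarray:
    """2-D UMAP embedding of feature vectors, for visualization only."""
    import umap

    features = np.asarray(features, dtype=float)
    if len(features) < 10:
        raise ValueError("need at least 10 samples for a UMAP embedding")
    reducer = umap.UMAP(n_components=2, random_state=seed)
    return np.asarray(reducer.fit_transform(features), dtype=float)
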