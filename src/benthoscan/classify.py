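"""Sparse polygon annotation -> pixel datasets -> benthic classifier maps.

Supervised benthic mapping from a handful of annotated polygons (typically
<2% of the scene's pixels): polygons are rasterized to a label map, labeled
pixels become feature rows — either full-resolution spectra restricted to
400-750 nm and Z-normed per pixel ("hsi" mode, which removes per-pixel
brightness/gain differences underwater), or the raw three R/G/B band
intensities ("rgb" mode) — a stratified 75/25 split feeds one of three
classifiers (multi-layer perceptron, per-class Mahalanobis distance, linear
SVM), and the fitted model predicts every pixel of the image. Performance
is reported as a confusion matrix with overall accuracy and per-class
precision (producer accuracy) and recall (user accuracy).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cube_io import SpectralCube, band_index

__all__ = [
    "AnnotationSet", "LabelMap", "PixelDataset", "ClassifierModel", "MetricsReport",
    "UNLABELED", "rasterize_annotations", "extract_dataset", "split_dataset",
    "train_classifier", "predict_map", "evaluate", "pool_datasets",
    "read_annotation_json", "write_annotation_json",
]

UNLABELED: int = -1
RGB_WAVELENGTHS = (640.0, 540.0, 460.0)


@dataclass
class AnnotationSet:
    """Labeled polygons: ``regions`` is a list of (vertices, label) where
    vertices are (line, sample) pairs in image coordinates."""

    regions: list[tuple[np.ndarray, str]]
    image_id: str = ""

    def __post_init__(self) -> None:
        checked = []
        for verts, label in self.regions:
            verts = np.asarray(verts, dtype=float)
            if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
                raise ValueError("each polygon needs >= 3 (line, sample) vertices")
            if not label:
                raise ValueError("polygon labels must be non-empty")
            checked.append((verts, str(label)))
        self.regions = checked

    @property
    def labels(self) -> list[str]:
        return sorted({label for _, label in self.regions})


@dataclass
class LabelMap:
    """Integer class index per pixel with a legend; UNLABELED marks no class."""

    indices: np.ndarray
    legend: dict[int, str]

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices)
        present = set(np.unique(self.indices).tolist()) - {UNLABELED}
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"label indices {sorted(missing)} absent from legend")

    @property
    def shape(self) -> tuple[int, int]:
        return self.indices.shape

    def name_of(self, index: int) -> str:
        return self.legend[index]


@dataclass
class PixelDataset:
    """Feature matrix (N x F) + class names (N) + per-row provenance
    ``(image_id, line, sample)``."""

    features: np.ndarray
    labels: np.ndarray
    provenance: list[tuple[str, int, int]]
    mode: str = "hsi"
    band_range: tuple[float, float] = (400.0, 750.0)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.features.ndim != 2 or self.features.shape[0] == 0:
            raise ValueError("features must be a non-empty N x F matrix")
        if self.labels.size != self.features.shape[0]:
            raise ValueError("labels length must match feature rows")
        if len(self.provenance) != self.features.shape[0]:
            raise ValueError("provenance length must match feature rows")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain missing/non-finite values")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels.tolist()))


@dataclass
class ClassifierModel:
    """A fitted benthic classifier plus the preprocessing that feeds it."""

    algorithm: str
    mode: str
    band_range: tuple[float, float]
    classes: list[str]
    estimator: object
    seed: int = 0
    hyperparams: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class names for an (N, F) feature matrix."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.algorithm == "mahalanobis":
            idx = self.estimator.predict_indices(X)
            return np.asarray(self.classes, dtype=object)[idx]
        return np.asarray(self.estimator.predict(X), dtype=object)


@dataclass
class MetricsReport:
    """Confusion-matrix metrics: rows are true classes, columns predicted.

    accuracy = trace/total; precision_k = M[k,k]/column-k sum (producer
    accuracy); recall_k = M[k,k]/row-k sum (user accuracy). Classes with no
    validation rows (or never predicted) carry NaN metrics rather than being
    dropped.
    """

    confusion: np.ndarray
    classes: list[str]
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    support: np.ndarray

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "accuracy": float(self.accuracy),
            "precision": [None if np.isnan(p) else float(p) for p in self.precision],
            "recall": [None if np.isnan(r) else float(r) for r in self.recall],
            "support": self.support.tolist(),
        }


# ---------------------------------------------------------------------------
# annotation I/O and rasterization

def read_annotation_json(path) -> AnnotationSet:
    """Read ``{"image_id": ..., "regions": [{"label", "vertices"}, ...]}``."""
    with open(path) as fh:
        payload = json.load(fh)
    regions = [(np.asarray(r["vertices"], dtype=float), r["label"]) for r in payload["regions"]]
    return AnnotationSet(regions, image_id=payload.get("image_id", ""))


def write_annotation_json(annotations: AnnotationSet, path) -> None:
    payload = {
        "image_id": annotations.image_id,
        "regions": [
            {"label": label, "vertices": np.asarray(verts, dtype=float).tolist()}
            for verts, label in annotations.regions
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def _points_on_edges(points: np.ndarray, verts: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Boolean: point lies on a polygon edge (boundary-inclusive rule)."""
    on = np.zeros(points.shape[0], dtype=bool)
    closed = np.vstack([verts, verts[:1]])
    for (y0, x0), (y1, x1) in zip(closed[:-1], closed[1:]):
        dy, dx = y1 - y0, x1 - x0
        cross = (points[:, 0] - y0) * dx - (points[:, 1] - x0) * dy
        seg2 = dy * dy + dx * dx
        if seg2 == 0:
            on |= (np.abs(points[:, 0] - y0) < tol) & (np.abs(points[:, 1] - x0) < tol)
            continue
        t = ((points[:, 0] - y0) * dy + (points[:, 1] - x0) * dx) / seg2
        on |= (np.abs(cross) <= tol * np.sqrt(seg2)) & (t >= -tol) & (t <= 1 + tol)
    return on


def _rasterize_polygon(verts: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Even-odd, boundary-inclusive pixel-center rasterization of one polygon."""
    verts = np.asarray(verts, dtype=float)
    L, S = shape
    lmin = max(int(np.floor(verts[:, 0].min())), 0)
    lmax = min(int(np.ceil(verts[:, 0].max())), L - 1)
    smin = max(int(np.floor(verts[:, 1].min())), 0)
    smax = min(int(np.ceil(verts[:, 1].max())), S - 1)
    mask = np.zeros(shape, dtype=bool)
    if lmax < lmin or smax < smin:
        return mask
    gl, gs = np.meshgrid(np.arange(lmin, lmax + 1), np.arange(smin, smax + 1), indexing="ij")
    pts = np.column_stack([gl.ravel(), gs.ravel()]).astype(float)

    # even-odd crossing count over edges, vectorized over pixel centers
    inside = np.zeros(pts.shape[0], dtype=bool)
    closed = np.vstack([verts, verts[:1]])
    y, x = pts[:, 0], pts[:, 1]
    for (y0, x0), (y1, x1) in zip(closed[:-1], closed[1:]):
        crosses = (y0 <= y) != (y1 <= y)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = x0 + (y - y0) * (x1 - x0) / (y1 - y0)
        inside ^= crosses & (x < np.where(crosses, x_at, np.inf))
    inside |= _points_on_edges(pts, verts)
    mask[gl.ravel()[inside], gs.ravel()[inside]] = True
    return mask


def _polygon_area(verts: np.ndarray) -> float:
    closed = np.vstack([verts, verts[:1]])
    return 0.5 * abs(float(np.sum(closed[:-1, 0] * closed[1:, 1] - closed[1:, 0] * closed[:-1, 1])))


def rasterize_annotations(annotations: AnnotationSet, shape: tuple[int, int]) -> LabelMap:
    """Burn labeled polygons into a label map (last-listed polygon wins overlaps).

    Pixel centers inside a polygon under the even-odd rule (boundary
    inclusive) take its class index; everything else is UNLABELED.
    Zero-area polygons are skipped with a warning.
    """
    legend_names = annotations.labels
    index_of = {name: i for i, name in enumerate(legend_names)}
    indices = np.full(shape, UNLABELED, dtype=np.int32)
    for verts, label in annotations.regions:
        if _polygon_area(verts) == 0.0:
            warnings.warn(f"degenerate zero-area polygon for '{label}' skipped")
            continue
        if verts[:, 0].min() < -0.5 or verts[:, 1].min() < -0.5 or \
           verts[:, 0].max() > shape[0] - 0.5 or verts[:, 1].max() > shape[1] - 0.5:
            raise ValueError(f"polygon for '{label}' extends outside image bounds {shape}")
        mask = _rasterize_polygon(verts, shape)
        indices[mask] = index_of[label]
    return LabelMap(indices, {i: name for name, i in index_of.items()})


# ---------------------------------------------------------------------------
# feature extraction

def _hsi_band_selector(cube: SpectralCube, band_range: tuple[float, float]) -> np.ndarray:
    lo, hi = band_range
    sel = (cube.wavelengths >= lo) & (cube.wavelengths <= hi)
    if sel.sum() < 2:
        raise ValueError(f"fewer than 2 bands in range {band_range}")
    return sel


def _featurize(
    pixels: np.ndarray, cube: SpectralCube, mode: str, band_range: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Feature rows for an (N, B) pixel-spectra block.

    Returns (features, valid): hsi rows with zero spectral SD are flagged
    invalid (Z-norm undefined) rather than filled.
    """
    if mode == "hsi":
        sub = pixels[:, _hsi_band_selector(cube, band_range)].astype(float)
        mean = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=0, keepdims=True)
        valid = sd[:, 0] > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            feats = (sub - mean) / sd
        feats[~valid] = 0.0
        return feats, valid
    if mode == "rgb":
        bands = [band_index(cube, w) for w in RGB_WAVELENGTHS]
        return pixels[:, bands].astype(float), np.ones(pixels.shape[0], dtype=bool)
    raise ValueError(f"unknown feature mode '{mode}' (expected 'hsi' or 'rgb')")


def extract_dataset(
    cube: SpectralCube,
    labels: LabelMap,
    mode: str = "hsi",
    band_range: tuple[float, float] = (400.0, 750.0),
    image_id: str = "",
) -> PixelDataset:
    """Labeled pixels -> feature rows in deterministic (line, sample) scan order.

    hsi: bands restricted to ``band_range`` then each pixel spectrum Z-normed
    across bands (zero mean, unit SD per row). rgb: raw intensities at the
    nearest bands to 640/540/460 nm, no normalization. hsi pixels with zero
    spectral SD are excluded with a warning.
    """
    if labels.shape != cube.shape[:2]:
        raise ValueError("label map shape does not match cube spatial shape")
    ll, ss = np.nonzero(labels.indices != UNLABELED)
    if ll.size == 0:
        raise ValueError("no labeled pixels")
    order = np.lexsort((ss, ll))
    ll, ss = ll[order], ss[order]
    pixels = cube.values[ll, ss, :]
    feats, valid = _featurize(pixels, cube, mode, band_range)
    if not valid.all():
        warnings.warn(f"{int((~valid).sum())} zero-SD pixel(s) excluded from hsi dataset")
    feats, ll, ss = feats[valid], ll[valid], ss[valid]
    names = np.asarray(
        [labels.legend[i] for i in labels.indices[ll, ss]], dtype=object
    )
    provenance = [(image_id, int(l), int(s)) for l, s in zip(ll, ss)]
    return PixelDataset(feats, names, provenance, mode=mode, band_range=tuple(band_range))


def split_dataset(
    ds: PixelDataset, train_fraction: float = 0.75, seed: int = 0
) -> tuple[PixelDataset, PixelDataset]:
    """Stratified train/validation split, reproducible by seed.

    Per class k, round(train_fraction * N_k) rows go to training; the split
    is disjoint and exhaustive. Every class needs >= 4 rows.
    """
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    val_idx: list[np.ndarray] = []
    for cls in ds.classes:
        rows = np.nonzero(ds.labels == cls)[0]
        if rows.size < 4:
            raise ValueError(f"class '{cls}' has only {rows.size} rows; need >= 4 to split")
        perm = rng.permutation(rows)
        n_train = int(np.floor(train_fraction * rows.size + 0.5))
        n_train = min(max(n_train, 1), rows.size - 1)
        train_idx.append(perm[:n_train])
        val_idx.append(perm[n_train:])
    tr = np.sort(np.concatenate(train_idx))
    va = np.sort(np.concatenate(val_idx))

    def subset(idx: np.ndarray) -> PixelDataset:
        return PixelDataset(
            ds.features[idx], ds.labels[idx], [ds.provenance[i] for i in idx],
            mode=ds.mode, band_range=ds.band_range,
        )

    return subset(tr), subset(va)


# ---------------------------------------------------------------------------
# classifiers

class MahalanobisClassifier:
    """Mahalanobis-distance classifier, implemented from its definition.

    Prediction is argmin_k of (x - mu_k)^T Sigma^{-1} (x - mu_k) over the
    class training means mu_k, ties broken toward the lexicographically
    first class. By default Sigma is the within-class covariance pooled over
    all classes — the standard form of this classifier in hyperspectral
    remote sensing, and the only well-posed one when per-class training sets
    are smaller than the band count (the usual sparse-annotation regime).
    ``covariance="per_class"`` switches to an independent Sigma_k per class
    (quadratic discriminant form); that variant needs n_k comfortably above
    F to be meaningful. Either way the matrix is regularized as
    Sigma + eps*I with eps = eps_scale * trace(Sigma)/F.
    """

    def __init__(self, eps_scale: float = 1e-6, covariance: str = "pooled"):
        if covariance not in ("pooled", "per_class"):
            raise ValueError("covariance must be 'pooled' or 'per_class'")
        self.eps_scale = eps_scale
        self.covariance = covariance
        self.means_: np.ndarray | None = None
        self.precisions_: np.ndarray | None = None  # (K, F, F) or (1, F, F) pooled

    def _regularized_inverse(self, sigma: np.ndarray, what: str) -> np.ndarray:
        F = sigma.shape[0]
        eps = self.eps_scale * np.trace(sigma) / F
        if eps <= 0:  # degenerate (identical rows): identity metric
            eps = self.eps_scale
        try:
            return np.linalg.inv(sigma + eps * np.eye(F))
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"{what} covariance singular despite shrinkage; increase eps_scale"
            ) from err

    def fit(self, X: np.ndarray, y_idx: np.ndarray, n_classes: int) -> "MahalanobisClassifier":
        n, F = X.shape
        self.means_ = np.zeros((n_classes, F))
        scatters = []
        dof = 0
        for k in range(n_classes):
            rows = X[y_idx == k]
            if rows.shape[0] == 0:
                raise ValueError(f"class index {k} has no training rows")
            self.means_[k] = rows.mean(axis=0)
            centered = rows - self.means_[k]
            scatters.append(centered.T @ centered)
            dof += max(rows.shape[0] - 1, 0)
        if self.covariance == "pooled":
            pooled = sum(scatters) / max(dof, 1)
            self.precisions_ = self._regularized_inverse(pooled, "pooled")[None, :, :]
        else:
            self.precisions_ = np.stack(
                [
                    self._regularized_inverse(
                        s / max(int((y_idx == k).sum()) - 1, 1), f"class index {k}"
                    )
                    for k, s in enumerate(scatters)
                ]
            )
        return self

    def distances(self, X: np.ndarray) -> np.ndarray:
        """Squared Mahalanobis distance of each row to each class, (N, K)."""
        X = np.atleast_2d(X)
        K = self.means_.shape[0]
        out = np.empty((X.shape[0], K))
        for k in range(K):
            d = X - self.means_[k]
            prec = self.precisions_[0 if self.precisions_.shape[0] == 1 else k]
            out[:, k] = np.einsum("ij,ij->i", d @ prec, d)
        return out

    def predict_indices(self, X: np.ndarray) -> np.ndarray:
        # argmin takes the first minimum -> lexicographically first class on ties
        return np.argmin(self.distances(X), axis=1)


def train_classifier(
    train: PixelDataset,
    algorithm: str = "perceptron",
    seed: int = 0,
    hyperparams: dict | None = None,
) -> ClassifierModel:
    """Fit one of {perceptron, mahalanobis, svm_linear} on a training dataset.

    perceptron: one-hidden-layer MLP (64 units by default, <= 500 epochs with
    early stopping); svm_linear: linear-kernel SVM, one-vs-rest, C = 1;
    mahalanobis: :class:`MahalanobisClassifier`. Hyperparameters can be
    overridden via ``hyperparams`` and are recorded on the model.
    """
    hp = dict(hyperparams or {})
    classes = train.classes
    if len(classes) < 2:
        raise ValueError("need >= 2 classes to train a classifier")
    X, y = train.features, train.labels

    if algorithm == "perceptron":
        from sklearn.neural_network import MLPClassifier

        params = {
            "hidden_layer_sizes": (hp.pop("hidden_units", 64),),
            "max_iter": hp.pop("max_iter", 500),
            # stop early on training-loss plateau: with a few dozen annotated
            # rows per class a held-out-score criterion plateaus long before
            # the fit converges
            "early_stopping": hp.pop("early_stopping", False),
            "n_iter_no_change": hp.pop("n_iter_no_change", 25),
            "tol": hp.pop("tol", 1e-5),
            "random_state": seed,
        }
        params.update(hp)
        est = MLPClassifier(**params).fit(X, y)
        used = params
    elif algorithm == "svm_linear":
        from sklearn.svm import LinearSVC

        params = {"C": hp.pop("C", 1.0), "max_iter": hp.pop("max_iter", 5000),
                  "random_state": seed}
        params.update(hp)
        est = LinearSVC(**params).fit(X, y)
        used = params
    elif algorithm == "mahalanobis":
        eps_scale = hp.pop("eps_scale", 1e-6)
        covariance = hp.pop("covariance", "pooled")
        if hp:
            raise ValueError(f"unknown mahalanobis hyperparams: {sorted(hp)}")
        y_idx = np.searchsorted(np.asarray(classes), y.astype(str))
        est = MahalanobisClassifier(eps_scale=eps_scale, covariance=covariance).fit(
            X, y_idx, len(classes)
        )
        used = {"eps_scale": eps_scale, "covariance": covariance}
    else:
        raise ValueError(
            f"unknown algorithm '{algorithm}'; expected perceptron, mahalanobis or svm_linear"
        )
    return ClassifierModel(
        algorithm=algorithm, mode=train.mode, band_range=train.band_range,
        classes=list(classes), estimator=est, seed=seed, hyperparams=used,
    )


def predict_map(
    model: ClassifierModel,
    cube: SpectralCube,
    chunk_lines: int = 32,
) -> tuple[LabelMap, dict]:
    """Classify every pixel of an image; returns the map and a QC report.

    hsi pixels whose spectrum has zero SD (Z-norm undefined) are assigned by
    nearest class mean of the raw band-subset spectrum and counted in the QC
    report. Processing is chunked by line block to bound memory.
    """
    lo, hi = model.band_range
    if model.mode == "hsi" and not (cube.wavelengths[0] <= lo and cube.wavelengths[-1] >= hi):
        raise ValueError("cube wavelength axis does not cover the model band range")
    L, S, _ = cube.shape
    legend_names = model.classes
    name_to_idx = {n: i for i, n in enumerate(legend_names)}
    out = np.empty((L, S), dtype=np.int32)
    n_fallback = 0

    if model.mode == "hsi":
        sel = _hsi_band_selector(cube, model.band_range)
        class_means: dict[str, np.ndarray] | None = None
    for start in range(0, L, chunk_lines):
        block = cube.values[start : start + chunk_lines]
        flat = block.reshape(-1, block.shape[2])
        feats, valid = _featurize(flat, cube, model.mode, model.band_range)
        pred = np.empty(flat.shape[0], dtype=object)
        if valid.any():
            pred[valid] = model.predict(feats[valid])
        if not valid.all():
            n_fallback += int((~valid).sum())
            if class_means is None:
                class_means = _raw_class_means(model)
            raw = flat[~valid][:, sel].astype(float)
            names = np.asarray(list(class_means), dtype=object)
            centers = np.stack([class_means[n] for n in names])
            nearest = np.argmin(
                ((raw[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), axis=1
            )
            pred[~valid] = names[nearest]
        out[start : start + chunk_lines] = np.asarray(
            [name_to_idx[p] for p in pred], dtype=np.int32
        ).reshape(block.shape[:2])
    qc = {"n_fallback_pixels": n_fallback, "n_pixels": L * S}
    return LabelMap(out, dict(enumerate(legend_names))), qc


def _raw_class_means(model: ClassifierModel) -> dict[str, np.ndarray]:
    """Raw-feature class centers for the zero-SD fallback path.

    For mahalanobis the fitted means are reused; otherwise zero vectors per
    class (the Z-normed feature origin), which makes the fallback an
    arbitrary-but-deterministic assignment for flat spectra.
    """
    if model.algorithm == "mahalanobis" and isinstance(model.estimator, MahalanobisClassifier):
        F = model.estimator.means_.shape[1]
        return {n: model.estimator.means_[i] for i, n in enumerate(model.classes)}
    # flat spectra carry no class information; nearest-to-origin of Z-space
    F = None
    try:
        F = model.estimator.coefs_[0].shape[0]  # MLP
    except AttributeError:
        try:
            F = model.estimator.coef_.shape[1]  # LinearSVC
        except AttributeError:
            pass
    if F is None:
        raise ValueError("cannot infer feature dimension for fallback assignment")
    return {n: np.zeros(F) for n in model.classes}


def evaluate(model: ClassifierModel, validation: PixelDataset) -> MetricsReport:
    """Confusion matrix + accuracy/precision/recall on a validation dataset.

    Model classes absent from the validation set keep their row (support 0)
    with NaN recall; classes never predicted get NaN precision.
    """
    if validation.n == 0:
        raise ValueError("validation dataset is empty")
    extra = set(validation.classes) - set(model.classes)
    if extra:
        raise ValueError(f"validation classes {sorted(extra)} unknown to model")
    classes = list(model.classes)
    idx = {c: i for i, c in enumerate(classes)}
    pred = model.predict(validation.features)
    K = len(classes)
    conf = np.zeros((K, K), dtype=np.int64)
    for t, p in zip(validation.labels, pred):
        conf[idx[t], idx[p]] += 1
    return metrics_from_confusion(conf, classes)


def metrics_from_confusion(conf: np.ndarray, classes: list[str]) -> MetricsReport:
    """Derive accuracy / per-class precision / recall from a confusion matrix."""
    conf = np.asarray(conf)
    total = conf.sum()
    diag = np.diag(conf).astype(float)
    col = conf.sum(axis=0).astype(float)
    row = conf.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(col > 0, diag / col, np.nan)
        recall = np.where(row > 0, diag / row, np.nan)
    return MetricsReport(
        confusion=conf,
        classes=list(classes),
        accuracy=float(diag.sum() / total),
        precision=precision,
        recall=recall,
        support=conf.sum(axis=1),
    )


def pool_datasets(datasets: list[PixelDataset]) -> PixelDataset:
    """Row-concatenate datasets from multiple images (same mode and F).

    Provenance must be disjoint across inputs; class lists are unioned
    implicitly by concatenating labels.
    """
    if not datasets:
        raise ValueError("no datasets to pool")
    first = datasets[0]
    seen: set[tuple[str, int, int]] = set()
    for ds in datasets:
        if ds.mode != first.mode or ds.n_features != first.n_features:
            raise ValueError("datasets differ in feature mode or dimension")
        overlap = seen & set(ds.provenance)
        if overlap:
            raise ValueError(f"provenance overlap across datasets, e.g. {next(iter(overlap))}")
        seen |= set(ds.provenance)
    return PixelDataset(
        np.vstack([ds.features for ds in datasets]),
        np.concatenate([ds.labels for ds in datasets]),
        [p for ds in datasets for p in ds.provenance],
        mode=first.mode,
        band_range=first.band_range,
    )
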