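"""Colour classification of fruit accessions in CIELAB space.

Harvest-maturity classification is the fixed DUS threshold rule derived
from the panel's CIELAB distributions — white if L* ≥ 70, else green if
a* ≤ −5, else purple, with the purple subtype violet if b* < −2.5 and
red otherwise.  Accessions within a configurable margin of any boundary
are flagged borderline rather than re-assigned (light-purple fruits with
green pulp genuinely straddle the green boundary).

Physiological-ripeness classification is unsupervised: K-means on the
accession-mean (L*, a*, b*) with the cluster number chosen by the Elbow
method (maximum second difference of the within-cluster sum of squares)
and the mean Silhouette coefficient, and the K = 3 solution mapped onto
the yellow/ochre/brown descriptor states by centroid lightness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from .colorimetry import RGBColor, lab_to_rgb, rgb_hex

__all__ = [
    "ColorCategory",
    "HarvestColorClassifier",
    "classify_harvest",
    "intensity_from_note",
    "LabKMeans",
    "kmeans_fit",
    "silhouette_mean",
    "select_k",
    "PcaScores",
    "pca_scores",
    "map_ripeness_clusters",
    "purple_k2_intensity_map",
    "agreement",
    "CategoryRange",
    "derive_category_ranges",
]

RIPENESS_ORDER = ("yellow", "ochre", "brown")  # decreasing centroid L*


@dataclass(frozen=True)
class ColorCategory:
    """A DUS colour descriptor state, with optional borderline flags."""

    stage: str  # "H" or "P"
    label: str  # white/green/purple or yellow/ochre/brown
    subtype: str | None = None  # violet/red, purple only
    intensity: str | None = None  # light/medium/dark
    borderline: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.subtype is not None and self.label != "purple":
            raise ValueError("subtype applies only to purple fruits")

    @property
    def full_label(self) -> str:
        return f"{self.label}-{self.subtype}" if self.subtype else self.label


def intensity_from_note(note: float) -> str:
    """DUS colour-intensity note → light (1–4) / medium (5–6) / dark (7–9)."""
    if not 1 <= note <= 9:
        raise ValueError(f"intensity note must lie in [1, 9], got {note}")
    return "light" if note <= 4 else ("medium" if note <= 6 else "dark")


class HarvestColorClassifier(BaseEstimator, ClassifierMixin):
    """Fixed-threshold harvest-maturity colour classifier.

    Decision order: L* ≥ l_white → white; else a* ≤ a_green → green;
    else purple, split into violet (b* < b_violet) and red.  The rule
    needs no training; ``fit`` only validates input and records the
    class inventory so the estimator composes with sklearn tooling.

    Parameters
    ----------
    l_white, a_green, b_violet : float
        Category thresholds in CIELAB units.
    margin : float
        Half-width of the borderline warning band around each boundary.
    """

    def __init__(self, l_white: float = 70.0, a_green: float = -5.0,
                 b_violet: float = -2.5, margin: float = 2.0):
        self.l_white = l_white
        self.a_green = a_green
        self.b_violet = b_violet
        self.margin = margin

    def fit(self, X, y=None) -> "HarvestColorClassifier":
        X = self._validate(X)
        self.n_features_in_ = 3
        self.classes_ = np.array(["green", "purple-red", "purple-violet", "white"])
        return self

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != 3 or not np.isfinite(X).all():
            raise ValueError("expected finite (n, 3) array of (L*, a*, b*)")
        return X

    def predict(self, X) -> np.ndarray:
        X = self._validate(X)
        L, a, b = X[:, 0], X[:, 1], X[:, 2]
        out = np.where(
            L >= self.l_white,
            "white",
            np.where(a <= self.a_green, "green",
                     np.where(b < self.b_violet, "purple-violet", "purple-red")),
        )
        return out.astype(object)

    def predict_frame(self, X, pulp_green=None) -> pd.DataFrame:
        """Labels plus borderline flags (and green-pulp context if given)."""
        X = self._validate(X)
        labels = self.predict(X)
        flags = []
        for i, (L, a, b) in enumerate(X):
            f = []
            if abs(L - self.l_white) < self.margin:
                f.append("L*~white boundary")
            if L < self.l_white and abs(a - self.a_green) < self.margin:
                f.append("a*~green boundary")
            if labels[i].startswith("purple") and abs(b - self.b_violet) < self.margin:
                f.append("b*~violet/red boundary")
            if pulp_green is not None and f and bool(np.asarray(pulp_green)[i]):
                f.append("green pulp")
            flags.append(";".join(f))
        return pd.DataFrame(
            {"label": labels, "category": [l.split("-")[0] for l in labels],
             "subtype": [l.split("-")[1] if "-" in l else None for l in labels],
             "borderline": flags}
        )


def classify_harvest(lab, pulp_green=None, l_white=70.0, a_green=-5.0,
                     b_violet=-2.5, margin=2.0) -> ColorCategory:
    """Classify one accession-mean harvest colour (threshold rule)."""
    clf = HarvestColorClassifier(l_white, a_green, b_violet, margin).fit(np.zeros((1, 3)))
    arr = np.asarray([lab.as_array() if hasattr(lab, "as_array") else lab], dtype=float)
    row = clf.predict_frame(arr, None if pulp_green is None else [pulp_green]).iloc[0]
    flags = tuple(row.borderline.split(";")) if row.borderline else ()
    return ColorCategory("H", row.category, row.subtype, borderline=flags)


class LabKMeans(BaseEstimator):
    """K-means cluster model on accession colours, with DUS mapping.

    Lloyd's algorithm with k-means++ initialisation and ``n_init``
    restarts (best within-cluster sum of squares kept), run on raw Lab
    coordinates, which share one perceptual scale.  Fitted attributes:
    ``cluster_centers_``, ``labels_``, ``wcss_``, ``silhouette_`` and,
    after mapping, ``descriptor_map_`` (cluster index → label).
    """

    def __init__(self, n_clusters: int = 3, n_init: int = 10, random_state: int = 0):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None) -> "LabKMeans":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("expected non-empty (n, d) matrix")
        if self.n_clusters > X.shape[0] or self.n_clusters < 1:
            raise ValueError("need 1 <= n_clusters <= n points")
        km = KMeans(n_clusters=self.n_clusters, n_init=self.n_init,
                    random_state=self.random_state)
        km.fit(X)
        self._km = km
        self.cluster_centers_ = km.cluster_centers_
        self.labels_ = km.labels_
        self.wcss_ = float(km.inertia_)
        self.silhouette_ = (
            silhouette_mean(X, self.labels_) if 2 <= self.n_clusters <= X.shape[0] - 1 else np.nan
        )
        self.descriptor_map_: dict[int, str] | None = None
        return self

    def predict(self, X) -> np.ndarray:
        return self._km.predict(np.asarray(X, dtype=float))

    def map_ripeness(self) -> "LabKMeans":
        """K = 3 clusters → yellow/ochre/brown by decreasing centroid L*."""
        self.descriptor_map_ = map_ripeness_clusters(self)
        return self

    def map_purple_intensity(self) -> "LabKMeans":
        """K = 2 purple clusters → dark vs light/medium by centroid L*."""
        self.descriptor_map_ = purple_k2_intensity_map(self)
        return self

    def descriptor_labels(self) -> np.ndarray:
        if self.descriptor_map_ is None:
            raise ValueError("no descriptor_map_; call a mapping method first")
        return np.array([self.descriptor_map_[int(c)] for c in self.labels_], dtype=object)


def kmeans_fit(points, k: int, seed: int = 0, n_init: int = 10) -> LabKMeans:
    """Fit a K-means cluster model (thin wrapper over LabKMeans)."""
    return LabKMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(points)


def silhouette_mean(points, labels) -> float:
    """Mean silhouette coefficient, (b − a) / max(a, b) per point.

    Singleton clusters and fully degenerate points contribute 0.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    with np.errstate(divide="ignore", invalid="ignore"):
        s = silhouette_samples(points, labels)
    return float(np.nan_to_num(s, nan=0.0).mean())


def map_ripeness_clusters(model: LabKMeans) -> dict[int, str]:
    """Order K = 3 centroids by L* descending → yellow, ochre, brown.

    Ties on L* break toward higher b* (yellower) first.
    """
    if model.n_clusters != 3:
        raise ValueError("ripeness mapping needs a K = 3 model")
    c = model.cluster_centers_
    order = sorted(range(3), key=lambda i: (-c[i, 0], -c[i, 2]))
    return {int(idx): RIPENESS_ORDER[rank] for rank, idx in enumerate(order)}


def purple_k2_intensity_map(model: LabKMeans) -> dict[int, str]:
    """Lower-L* centroid → dark; the other → light/medium.

    Ties on L* break toward higher chroma = light/medium.
    """
    if model.n_clusters != 2:
        raise ValueError("intensity mapping needs a K = 2 model")
    c = model.cluster_centers_
    if c[0, 0] != c[1, 0]:
        dark = int(np.argmin(c[:, 0]))
    else:
        dark = int(np.argmin(np.hypot(c[:, 1], c[:, 2])))
    return {dark: "dark", 1 - dark: "light/medium"}


@dataclass
class SelectKResult:
    elbow_k: int | None
    silhouette_k: int
    diagnostics: pd.DataFrame


def select_k(points, k_range=range(2, 9), seed: int = 0, n_init: int = 10) -> SelectKResult:
    """Cluster-number selection by Elbow and Silhouette.

    elbow_k maximises the second difference of the WCSS curve (interior
    K only; None when the range has no interior); silhouette_k maximises
    the mean silhouette.  The diagnostics table carries both curves.
    """
    points = np.asarray(points, dtype=float)
    ks = sorted(k_range)
    if not ks or ks[0] < 2 or ks[-1] > points.shape[0] - 1:
        raise ValueError("k_range must lie within [2, n-1]")
    rows = []
    for k in ks:
        m = kmeans_fit(points, k, seed=seed, n_init=n_init)
        rows.append((k, m.wcss_, m.silhouette_))
    diag = pd.DataFrame(rows, columns=["K", "wcss", "silhouette"])
    w = diag.wcss.to_numpy()
    d2 = np.full(len(ks), np.nan)
    if len(ks) >= 3:
        d2[1:-1] = w[:-2] - 2 * w[1:-1] + w[2:]
    diag["wcss_second_diff"] = d2
    elbow_k = int(diag.K[np.nanargmax(d2)]) if np.isfinite(d2).any() else None
    sil_k = int(diag.K[diag.silhouette.idxmax()])
    return SelectKResult(elbow_k, sil_k, diag)


@dataclass
class PcaScores:
    scores: pd.DataFrame  # columns PC1, PC2
    explained: tuple[float, float]
    loadings: np.ndarray


def pca_scores(points, index=None) -> PcaScores:
    """Top-2 principal-component scores of z-scored colour columns.

    Sign convention: the largest-magnitude loading of each component is
    made positive, so score plots are reproducible across runs.
    """
    X = np.asarray(points, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("PCA needs at least 3 accessions")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance column; cannot z-score")
    Z = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=2)
    scores = pca.fit_transform(Z)
    load = pca.components_.copy()
    for i in range(2):
        j = int(np.argmax(np.abs(load[i])))
        if load[i, j] < 0:
            load[i] *= -1
            scores[:, i] *= -1
    df = pd.DataFrame(scores, columns=["PC1", "PC2"], index=index)
    return PcaScores(df, tuple(pca.explained_variance_ratio_[:2]), load)


def agreement(labels_a, labels_b) -> tuple[pd.DataFrame, float]:
    """Cross-tabulation and adjusted Rand index of two labelings."""
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 items")
    table = pd.crosstab(pd.Series(a, name="A"), pd.Series(b, name="B"))
    return table, float(adjusted_rand_score(a, b))


@dataclass
class CategoryRange:
    """Min/max CIELAB box of one colour category plus a rendered gradient."""

    label: str
    lab_min: tuple[float, float, float]
    lab_max: tuple[float, float, float]
    n: int
    gradient: list[RGBColor] = field(default_factory=list)

    @property
    def hex_codes(self) -> list[str]:
        return [rgb_hex(c) for c in self.gradient]


def derive_category_ranges(means: pd.DataFrame, label_col: str = "label",
                           n_swatches: int = 8) -> list[CategoryRange]:
    """Per-category CIELAB min/max boxes with gradient swatches.

    ``means`` needs columns L, a, b and a category label column.  The
    gradient linearly interpolates between the two box corners ordered
    by L* and converts each step to sRGB.
    """
    out = []
    for label, grp in means.groupby(label_col, sort=True):
        if grp.empty:
            continue
        lab = grp[["L", "a", "b"]].to_numpy(dtype=float)
        lo, hi = lab.min(axis=0), lab.max(axis=0)
        t = np.linspace(0.0, 1.0, n_swatches)[:, None]
        grad = [lab_to_rgb(tuple(v)) for v in lo[None, :] * (1 - t) + hi[None, :] * t]
        out.append(CategoryRange(str(label), tuple(lo), tuple(hi), len(grp), grad))
    if not out:
        raise ValueError("no non-empty categories")
    return out
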