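"""Population structure and marker–trait association.

Two stages mirror the classical germplasm-panel workflow:

1. model selection for the number of subpopulations from Bayesian-
   clustering run summaries via the Evanno ΔK statistic, with a PCA +
   K-means surrogate producing the Q-matrix of membership proportions;
2. a structure-corrected general linear model scan: each trait is
   regressed on an intercept, the first K−1 Q columns and the marker's
   genotype-class indicators, and the marker is judged by the partial
   F-test against the Q-only model.  Partial R² = (RSS_reduced −
   RSS_full) / TSS is the per-marker explained phenotypic variance.

SSR genotypes are co-dominant allele-size pairs; genotype classes are the
unordered pairs, treated as factor levels (no dosage assumption).
Classes with fewer than ``min_class_size`` observations are pooled into a
"rare" class, which is dropped if it stays below the minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "AssociationResult",
    "evanno_delta_k",
    "StructureQ",
    "surrogate_q",
    "genotype_classes",
    "glm_association",
    "association_scan",
    "MarkerTraitGLM",
]


@dataclass(frozen=True)
class AssociationResult:
    """One marker × trait partial-F test (association-table cell)."""

    marker: str
    trait: str
    n: int
    n_classes: int
    f_stat: float
    p_value: float
    partial_r2: float
    significant: bool
    note: str = ""


def evanno_delta_k(runs: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Evanno ΔK over run summaries with columns (K, run, LnPD).

    ΔK(K) = mean over runs of |LnPD(K+1) − 2·LnPD(K) + LnPD(K−1)|
    divided by the run-to-run sd of LnPD(K); runs are paired by run
    index.  Defined for interior K only.  ΔK is 0 wherever the numerator
    is 0 (e.g. exactly linear curves) and NaN where the sd is 0 with a
    nonzero numerator.

    Returns the per-K table (K, mean_lnpd, sd_lnpd, delta_k) and the
    optimal K (argmax ΔK over interior K).
    """
    req = {"K", "run", "LnPD"}
    if not req.issubset(runs.columns):
        raise ValueError(f"runs table needs columns {sorted(req)}")
    wide = runs.pivot(index="run", columns="K", values="LnPD").sort_index(axis=1)
    ks = wide.columns.to_numpy()
    if len(ks) < 3:
        raise ValueError("ΔK needs at least 3 contiguous K values")
    if np.any(np.diff(ks) != 1):
        raise ValueError("K grid must be contiguous")
    if wide.isna().any().any() or wide.shape[0] < 2:
        raise ValueError("need the same >=2 runs at every K")
    arr = wide.to_numpy()  # runs x K
    second = arr[:, 2:] - 2.0 * arr[:, 1:-1] + arr[:, :-2]
    num = np.abs(second).mean(axis=0)
    sd = arr.std(axis=0, ddof=1)[1:-1]
    safe_sd = np.where(sd > 0, sd, 1.0)
    delta = np.where(num == 0.0, 0.0, np.where(sd > 0, num / safe_sd, np.nan))
    table = pd.DataFrame(
        {
            "K": ks[1:-1],
            "mean_lnpd": arr.mean(axis=0)[1:-1],
            "sd_lnpd": sd,
            "delta_k": delta,
        }
    )
    if not np.isfinite(delta).any():
        raise ValueError("ΔK undefined at every interior K (zero run-to-run sd)")
    optimal = int(table.loc[np.nanargmax(np.where(np.isfinite(delta), delta, -np.inf)), "K"])
    return table, optimal


def _dosage_matrix(genotypes: pd.DataFrame) -> np.ndarray:
    """One-hot allele-count encoding of a co-dominant genotype table."""
    markers = sorted({c[:-2] for c in genotypes.columns if c.endswith("_1")})
    if not markers:
        raise ValueError("no '<marker>_1'/'<marker>_2' columns found")
    cols = []
    for mk in markers:
        pair = genotypes[[f"{mk}_1", f"{mk}_2"]].to_numpy(dtype=float)
        alleles = np.unique(pair[np.isfinite(pair)])
        for al in alleles:
            cols.append((pair == al).sum(axis=1).astype(float))
    return np.column_stack(cols)


class StructureQ(BaseEstimator, TransformerMixin):
    """PCA + K-means surrogate for a Bayesian-clustering Q-matrix.

    One-hot allele dosages are reduced to the top K−1 principal
    components, cluster centres come from K-means, and soft membership
    proportions are inverse-squared-distance weights, row-normalised.

    Parameters
    ----------
    n_subpopulations : int
        K, the assumed number of subpopulations.
    random_state : int
        Seed for K-means initialisation.
    """

    def __init__(self, n_subpopulations: int = 2, random_state: int = 0):
        self.n_subpopulations = n_subpopulations
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "StructureQ":
        k = self.n_subpopulations
        if k < 1:
            raise ValueError("n_subpopulations must be >= 1")
        dos = _dosage_matrix(X)
        if k > dos.shape[0]:
            raise ValueError("more subpopulations than accessions")
        self.n_features_in_ = X.shape[1]
        if k == 1:
            self.scores_ = np.zeros((dos.shape[0], 0))
            self.cluster_centers_ = np.zeros((1, 0))
            return self
        self._pca = PCA(n_components=k - 1, random_state=self.random_state)
        self.scores_ = self._pca.fit_transform(dos - dos.mean(axis=0))
        km = KMeans(n_clusters=k, n_init=10, random_state=self.random_state)
        km.fit(self.scores_)
        self.cluster_centers_ = km.cluster_centers_
        self.labels_ = km.labels_
        return self

    def transform(self, X: pd.DataFrame | None = None) -> np.ndarray:
        """Membership proportions for the fitted panel (rows sum to 1)."""
        if self.n_subpopulations == 1:
            return np.ones((self.scores_.shape[0], 1))
        if X is None:
            scores = self.scores_
        else:
            scores = self._pca.transform(_dosage_matrix(X) - 0)
        d2 = ((scores[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        q = np.zeros_like(d2)
        zero = d2 < 1e-12
        hit = zero.any(axis=1)
        q[hit] = zero[hit] / zero[hit].sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore"):
            w = 1.0 / d2[~hit]
        q[~hit] = w / w.sum(axis=1, keepdims=True)
        return q

    def fit_transform(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).transform(None)


def surrogate_q(genotypes: pd.DataFrame, k: int, seed: int = 0) -> pd.DataFrame:
    """Q-matrix (accession × K membership proportions) as a DataFrame."""
    est = StructureQ(n_subpopulations=k, random_state=seed)
    q = est.fit_transform(genotypes)
    idx = genotypes["accession"] if "accession" in genotypes else genotypes.index
    return pd.DataFrame(q, index=pd.Index(idx, name="accession"), columns=[f"Q{i + 1}" for i in range(k)])


def genotype_classes(pair: np.ndarray, min_class_size: int = 3) -> np.ndarray:
    """Factor-level coding of unordered allele-size pairs.

    Returns integer class labels (−1 = dropped: missing, or member of a
    rare pool that stayed below ``min_class_size``).
    """
    ok = np.isfinite(pair).all(axis=1)
    key = np.full(pair.shape[0], None, dtype=object)
    srt = np.sort(pair[ok], axis=1)
    key[ok] = [f"{int(x)}/{int(y)}" for x, y in srt]
    labels = np.full(pair.shape[0], -1, dtype=int)
    uniq, counts = np.unique(srt, axis=0, return_counts=True) if ok.any() else (np.empty((0, 2)), np.array([]))
    keep = [tuple(u) for u, c in zip(uniq, counts) if c >= min_class_size]
    rare = [tuple(u) for u, c in zip(uniq, counts) if c < min_class_size]
    lookup = {k: i for i, k in enumerate(keep)}
    rare_label = len(keep) if sum(c for u, c in zip(uniq, counts) if tuple(u) in rare) >= min_class_size else -1
    for row in np.flatnonzero(ok):
        t = tuple(np.sort(pair[row]))
        labels[row] = lookup.get(t, rare_label)
    return labels


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def glm_association(
    y: np.ndarray,
    marker_pair: np.ndarray,
    q: np.ndarray,
    marker: str = "",
    trait: str = "",
    alpha: float = 0.001,
    min_class_size: int = 3,
) -> AssociationResult:
    """Partial-F test of one marker on one trait, correcting for structure.

    The reduced model is [intercept | first K−1 Q columns]; the full
    model adds the genotype-class indicators.  Rows with a missing
    phenotype or genotype are dropped listwise.
    """
    y = np.asarray(y, dtype=float)
    q = np.asarray(q, dtype=float)
    labels = genotype_classes(marker_pair, min_class_size=min_class_size)
    keep = np.isfinite(y) & (labels >= 0)
    y_k, lab_k, q_k = y[keep], labels[keep], q[keep]
    classes = np.unique(lab_k)
    n = int(keep.sum())
    if classes.size < 2:
        return AssociationResult(marker, trait, n, int(classes.size), np.nan, np.nan, np.nan, False, "single genotype class")
    x_red = np.column_stack([np.ones(n), q_k[:, :-1]])
    dummies = (lab_k[:, None] == classes[1:][None, :]).astype(float)
    x_full = np.column_stack([x_red, dummies])
    rss_red, rank_red = _rss(x_red, y_k)
    rss_full, rank_full = _rss(x_full, y_k)
    df1 = rank_full - rank_red
    df2 = n - rank_full
    if df1 < 1 or df2 < 1:
        return AssociationResult(marker, trait, n, int(classes.size), np.nan, np.nan, np.nan, False, "rank-deficient design")
    tss = float(((y_k - y_k.mean()) ** 2).sum())
    if tss == 0 or rss_full < 0:
        return AssociationResult(marker, trait, n, int(classes.size), np.nan, np.nan, np.nan, False, "constant trait")
    f = ((rss_red - rss_full) / df1) / (rss_full / df2) if rss_full > 0 else np.inf
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    p = max(p, np.nextafter(0, 1))  # p in (0, 1]
    r2 = float(max(0.0, (rss_red - rss_full) / tss))
    return AssociationResult(marker, trait, n, int(classes.size), float(f), p, r2, bool(p < alpha))


def association_scan(
    traits: pd.DataFrame,
    genotypes: pd.DataFrame,
    q: pd.DataFrame | np.ndarray,
    alpha: float = 0.001,
    min_class_size: int = 3,
) -> pd.DataFrame:
    """Full marker × trait scan; one row per testable pair.

    ``traits`` is the accession × trait matrix (index = accession IDs,
    aligned with the genotype table).  The output annotates the
    p < alpha significance flag and the R² > 0.15 / > 0.20 tiers.
    """
    if isinstance(q, pd.DataFrame):
        q = q.to_numpy()
    geno = genotypes.set_index("accession") if "accession" in genotypes else genotypes
    common = traits.index.intersection(geno.index)
    if len(common) == 0:
        raise ValueError("traits and genotypes share no accession keys")
    pos = {a: i for i, a in enumerate(geno.index)}
    sel = np.array([pos[a] for a in common])
    geno, q = geno.loc[common], q[sel]
    traits = traits.loc[common]
    markers = sorted({c[:-2] for c in geno.columns if c.endswith("_1")})
    rows = []
    for mk in markers:
        pair = geno[[f"{mk}_1", f"{mk}_2"]].to_numpy(dtype=float)
        for tr in traits.columns:
            res = glm_association(
                traits[tr].to_numpy(dtype=float), pair, q,
                marker=mk, trait=tr, alpha=alpha, min_class_size=min_class_size,
            )
            tier = ""
            if np.isfinite(res.partial_r2):
                if res.partial_r2 > 0.20:
                    tier = ">0.20"
                elif res.partial_r2 > 0.15:
                    tier = ">0.15"
            rows.append(
                (res.marker, res.trait, res.n, res.n_classes, res.f_stat,
                 res.p_value, res.partial_r2, res.significant, tier, res.note)
            )
    return pd.DataFrame(
        rows,
        columns=["marker", "trait", "n", "classes", "F", "p", "R2", f"sig_{alpha:g}", "tier", "note"],
    ).rename(columns={f"sig_{alpha:g}": "significant"}).assign(alpha=alpha)


class MarkerTraitGLM(BaseEstimator):
    """Estimator façade over the structure-corrected association scan.

    ``fit(genotypes, traits)`` derives (or accepts) a Q-matrix and runs
    the full partial-F scan; results land in ``results_``.
    """

    def __init__(self, n_subpopulations: int = 2, alpha: float = 0.001,
                 min_class_size: int = 3, random_state: int = 0):
        self.n_subpopulations = n_subpopulations
        self.alpha = alpha
        self.min_class_size = min_class_size
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y: pd.DataFrame, q: pd.DataFrame | None = None) -> "MarkerTraitGLM":
        """X: genotype table; y: accession × trait matrix."""
        if q is None:
            q = surrogate_q(X, self.n_subpopulations, seed=self.random_state)
        self.q_ = q
        self.results_ = association_scan(
            y, X, q, alpha=self.alpha, min_class_size=self.min_class_size
        )
        return self

    def significant_(self) -> pd.DataFrame:
        return self.results_[self.results_["significant"]]
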