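"""Physicochemical embedding, PCA and clustering of peptide repertoires.

Each fixed-length peptide is encoded position-by-position with four
physicochemical properties (molecular weight, hydropathy, surface area,
isoelectric point) plus 20 residue-identity indicators, giving 24·L features.
Columns are standardised to zero mean / unit variance (mandatory when mixing
Da, A^2 and indicator units), zero-variance columns are dropped and recorded,
and the matrix is decomposed by PCA.  k-means on the first two principal
components, with the number of clusters chosen at the silhouette-coefficient
peak, partitions the repertoire; per-cluster percentages and motif summaries
describe the partition, and the loading report ranks the features that drive
each component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .constants import AMINO_ACIDS, PROPERTY_NAMES, default_property_table, validate_property_table
from .io import Repertoire
from .motif import motif_summary, position_frequency_matrix


@dataclass
class FeatureMatrix:
    """Standardised per-position feature encoding of an equal-length peptide set."""

    length: int
    data: pd.DataFrame           # n x kept-features, standardised
    column_means: pd.Series      # pre-standardisation means, all columns
    column_sds: pd.Series        # pre-standardisation sds, all columns
    dropped_columns: list[str]   # zero-variance columns removed
    sequences: list[str]

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def is_degenerate(self) -> bool:
        return self.data.shape[1] == 0


def _column_labels(length: int) -> list[str]:
    labels = []
    for pos in range(1, length + 1):
        for prop in PROPERTY_NAMES:
            labels.append(f"P{pos}_{prop}")
        for aa in AMINO_ACIDS:
            labels.append(f"P{pos}_is_{aa}")
    return labels


def encode_peptides(
    rep: Repertoire | list[str],
    length: int,
    table: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Encode peptides of ``length`` as a standardised 24·L feature matrix.

    Column order is position-major: the four properties then the 20 identity
    indicators for P1, then P2, ...  Before standardisation the identity
    block of each position sums to 1 per row.
    """
    table = validate_property_table(table) if table is not None else default_property_table()
    seqs = rep.sequences(length) if isinstance(rep, Repertoire) else [s for s in rep if len(s) == length]
    if not seqs:
        raise ValueError(f"no peptides of length {length}")
    prop = table.to_numpy()  # 20 x 4, row order = AMINO_ACIDS
    aa_idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    n = len(seqs)
    raw = np.zeros((n, 24 * length), dtype=float)
    for r, s in enumerate(seqs):
        for pos, aa in enumerate(s):
            base = 24 * pos
            k = aa_idx[aa]
            raw[r, base:base + 4] = prop[k]
            raw[r, base + 4 + k] = 1.0
    cols = _column_labels(length)
    means = raw.mean(axis=0)
    sds = raw.std(axis=0, ddof=0)
    # relative tolerance: a numerically constant column (sd at rounding level)
    # counts as zero-variance
    keep = sds > 1e-8 * np.maximum(1.0, np.abs(means))
    sds = np.where(keep, sds, 0.0)
    std = (raw[:, keep] - means[keep]) / sds[keep]
    kept_cols = [c for c, k in zip(cols, keep) if k]
    dropped = [c for c, k in zip(cols, keep) if not k]
    return FeatureMatrix(
        length=length,
        data=pd.DataFrame(std, columns=kept_cols),
        column_means=pd.Series(means, index=cols),
        column_sds=pd.Series(sds, index=cols),
        dropped_columns=dropped,
        sequences=list(seqs),
    )


@dataclass
class PCAClusterResult:
    scores: pd.DataFrame              # n x n_components, columns PC1..
    loadings: pd.DataFrame            # features x components
    variance_fractions: np.ndarray
    silhouette_by_k: dict[int, float]
    chosen_k: int
    labels: np.ndarray                # cluster index per peptide
    cluster_percentages: dict[int, float]
    cluster_motifs: dict[int, dict] = field(default_factory=dict)
    density_grid: dict | None = None

    def top_loading_features(self, component: int = 1, k: int = 10) -> pd.Series:
        """Features ranked by |loading| on one component (1-based)."""
        col = f"PC{component}"
        return self.loadings[col].reindex(
            self.loadings[col].abs().sort_values(ascending=False, kind="stable").index
        ).head(k)

    def loading_report(self, component: int = 1) -> pd.DataFrame:
        """|loading| aggregated by (position, feature type) for one component."""
        col = f"PC{component}"
        rows = []
        for feat, val in self.loadings[col].items():
            pos, _, rest = feat.partition("_")
            ftype = "identity" if rest.startswith("is_") else rest
            rows.append((pos, ftype, abs(val)))
        df = pd.DataFrame(rows, columns=["position", "feature_type", "abs_loading"])
        return (
            df.groupby(["position", "feature_type"], sort=True)["abs_loading"]
            .sum()
            .reset_index()
            .sort_values("abs_loading", ascending=False, kind="stable")
            .reset_index(drop=True)
        )


def _fix_signs(scores: np.ndarray, loadings: np.ndarray) -> None:
    """Orient each PC so its largest-|loading| feature loads positively."""
    for c in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1.0
            scores[:, c] *= -1.0


def pca_cluster(
    features: FeatureMatrix,
    k_candidates: tuple[int, ...] = (2, 3, 4, 5, 6),
    seed: int = 0,
    n_components: int | None = None,
    with_density: bool = False,
    with_motifs: bool = True,
) -> PCAClusterResult:
    """PCA of the standardised features plus k-means on the first two PCs.

    The number of clusters is the silhouette-coefficient peak over
    ``k_candidates`` (ties go to the smaller k); k-means uses 10 seeded
    restarts, and cluster indices are relabelled by decreasing cluster size
    (ties by centroid coordinates) so labels are reproducible.
    """
    if features.is_degenerate:
        raise ValueError("degenerate feature matrix: all columns were zero-variance")
    X = features.data.to_numpy()
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 peptides")
    n_components = min(n_components or min(n, p), min(n, p))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T.copy()
    _fix_signs(scores, loadings)
    pc_cols = [f"PC{i + 1}" for i in range(n_components)]
    scores_df = pd.DataFrame(scores, columns=pc_cols)
    loadings_df = pd.DataFrame(loadings, index=features.data.columns, columns=pc_cols)

    xy = scores[:, :2] if scores.shape[1] >= 2 else scores[:, :1]
    sil: dict[int, float] = {}
    best_labels: dict[int, np.ndarray] = {}
    for k in sorted(k_candidates):
        if k < 2 or k >= n:
            continue
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        lab = km.fit_predict(xy)
        if len(np.unique(lab)) < 2:
            continue
        sil[k] = float(silhouette_score(xy, lab))
        best_labels[k] = lab
    if not sil:
        raise ValueError("no valid clustering among candidate k values")
    chosen_k = min(sil, key=lambda k: (-sil[k], k))
    labels = best_labels[chosen_k]

    # deterministic relabelling: cluster 0 = largest, ties by centroid coords
    order = sorted(
        np.unique(labels),
        key=lambda c: (-(labels == c).sum(), tuple(xy[labels == c].mean(axis=0))),
    )
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[c] for c in labels])

    percentages = {
        int(c): float(100.0 * (labels == c).sum() / n) for c in np.unique(labels)
    }
    motifs: dict[int, dict] = {}
    if with_motifs:
        for c in np.unique(labels):
            seqs = [s for s, lab in zip(features.sequences, labels) if lab == c]
            try:
                motifs[int(c)] = motif_summary(position_frequency_matrix(seqs, features.length))
            except ValueError:
                motifs[int(c)] = {}

    density = None
    if with_density and xy.shape[1] == 2 and n > 2:
        kde = gaussian_kde(xy.T)  # Scott's-rule bandwidth
        gx = np.linspace(xy[:, 0].min(), xy[:, 0].max(), 50)
        gy = np.linspace(xy[:, 1].min(), xy[:, 1].max(), 50)
        gxx, gyy = np.meshgrid(gx, gy)
        dens = kde(np.vstack([gxx.ravel(), gyy.ravel()])).reshape(gxx.shape)
        density = {"x": gx, "y": gy, "density": dens}

    return PCAClusterResult(
        scores=scores_df,
        loadings=loadings_df,
        variance_fractions=pca.explained_variance_ratio_,
        silhouette_by_k=sil,
        chosen_k=int(chosen_k),
        labels=labels,
        cluster_percentages=percentages,
        cluster_motifs=motifs,
        density_grid=density,
    )
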