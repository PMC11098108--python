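"""Population growth-curve parameters and the strain-panel decomposition.

From each OD600 curve, four parameters are extracted on the log scale
y(t) = ln(N/N0):

* **MGR** — maximum growth rate, the largest sliding-window least-squares
  slope of y vs t (h^-1);
* **SPG** — saturation point of growth, the maximum of a median-smoothed y
  (dimensionless ln-fold growth);
* **AUC** — trapezoidal area under y over the full record (ln-fold * h);
* **Texp** — duration of the exponential phase, the total time over which
  the local slope stays above a fraction of MGR (h).

Across a panel of strains and media these parameters are strongly
correlated, so the panel is z-scored, decomposed by PCA, and the strains
grouped by average-linkage hierarchical clustering on the leading
component scores — the standard workflow for sorting deletion mutants into
growth-profile classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import medfilt
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA

__all__ = [
    "GrowthCurve",
    "GrowthParams",
    "PanelDecomposition",
    "log_transform",
    "extract_growth_params",
    "average_replicates",
    "panel_matrix",
    "decompose_and_cluster",
]

OD_FLOOR = 1e-4


@dataclass
class GrowthCurve:
    """One well's OD600 time series."""

    strain: str
    medium: str
    times: np.ndarray
    od: np.ndarray
    replicate: str = "r1"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("times must be 1-d with >= 2 points")
        if self.od.shape != self.times.shape:
            raise ValueError("od must match times in shape")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("od must be >= 0")


@dataclass
class GrowthParams:
    """The four growth parameters plus a floored-reading count."""

    mgr: float
    spg: float
    auc: float
    texp: float
    n_floored: int = 0


def log_transform(curve: GrowthCurve, n0_points: int = 3,
                  floor: float = OD_FLOOR) -> np.ndarray:
    """ln(N/N0) with N0 the mean of the first ``n0_points`` floored readings.

    Averaging the first readings makes N0 robust to first-read noise;
    values below the floor are clipped before the log.
    """
    od = np.maximum(curve.od, floor)
    if np.any(od <= 0):
        raise ValueError("non-positive OD after flooring")
    n0 = od[:max(1, min(n0_points, od.size))].mean()
    return np.log(od / n0)


def _window_slopes(t: np.ndarray, y: np.ndarray, window: int) -> np.ndarray:
    """Least-squares slope of y vs t over each sliding window."""
    tw = np.lib.stride_tricks.sliding_window_view(t, window)
    yw = np.lib.stride_tricks.sliding_window_view(y, window)
    tc = tw - tw.mean(axis=1, keepdims=True)
    yc = yw - yw.mean(axis=1, keepdims=True)
    denom = np.einsum("ij,ij->i", tc, tc)
    return np.einsum("ij,ij->i", tc, yc) / denom


def extract_growth_params(curve: GrowthCurve, window: int = 5,
                          exp_fraction: float = 0.5, n0_points: int = 3,
                          floor: float = OD_FLOOR) -> GrowthParams:
    """Extract (MGR, SPG, AUC, Texp) from one growth curve.

    MGR is the maximum sliding-window slope of ln(N/N0); SPG the maximum of
    a 3-point median-filtered ln(N/N0) (a plateau statistic, so a single
    noisy frame cannot set it); AUC the trapezoidal integral over the full
    record; Texp the total time covered by windows whose slope is at least
    ``exp_fraction`` of MGR (zero for curves that never grow).
    """
    n = curve.times.size
    if n < 10:
        raise ValueError("need >= 10 points for parameter extraction")
    if not 3 <= window <= n // 2:
        raise ValueError(f"window must be in [3, n/2], got {window}")
    if not 0 < exp_fraction < 1:
        raise ValueError("exp_fraction must be in (0, 1)")
    y = log_transform(curve, n0_points=n0_points, floor=floor)
    t = curve.times
    n_floored = int(np.sum(curve.od < floor))

    slopes = _window_slopes(t, y, window)
    mgr = float(slopes.max())
    spg = float(medfilt(y, kernel_size=3).max())
    auc = float(np.trapezoid(y, t))

    if mgr <= 1e-9:
        mgr = max(mgr, 0.0)
        texp = 0.0
    else:
        qualify = slopes >= exp_fraction * mgr
        # union of the time intervals covered by qualifying windows
        texp = 0.0
        cover_end = -np.inf
        for i in np.flatnonzero(qualify):
            lo, hi = t[i], t[i + window - 1]
            lo = max(lo, cover_end)
            if hi > lo:
                texp += hi - lo
                cover_end = hi
    return GrowthParams(mgr=mgr, spg=spg, auc=auc, texp=float(texp),
                        n_floored=n_floored)


def average_replicates(params: pd.DataFrame) -> pd.DataFrame:
    """Average growth parameters over replicates per strain x medium."""
    cols = [c for c in ("mgr", "spg", "auc", "texp") if c in params.columns]
    return (params.groupby(["strain", "medium"], as_index=False)[cols]
            .mean())


def panel_matrix(params: pd.DataFrame
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the strain x (parameter-medium) feature matrix, z-scored.

    Input is a tidy table with one row per strain x medium (replicates
    already averaged) and columns mgr/spg/auc/texp.  Every strain must have
    every medium; missing cells raise rather than being silently imputed.
    Returns the z-scored matrix and the feature correlation matrix.
    """
    required = {"strain", "medium"}
    if not required.issubset(params.columns):
        raise ValueError("params table needs 'strain' and 'medium' columns")
    value_cols = [c for c in ("mgr", "spg", "auc", "texp")
                  if c in params.columns]
    if not value_cols:
        raise ValueError("no growth-parameter columns found")
    if params.duplicated(["strain", "medium"]).any():
        raise ValueError("multiple rows per strain x medium; average "
                         "replicates first")
    wide = params.pivot(index="strain", columns="medium", values=value_cols)
    if wide.isna().any().any():
        missing = wide.columns[wide.isna().any()].tolist()
        raise ValueError(f"missing strain x medium cells for features "
                         f"{missing}; no silent imputation")
    wide.columns = [f"{p}-{m}" for p, m in wide.columns]
    if len(wide) < 2:
        raise ValueError("need >= 2 strains to z-score the panel")
    centered = wide - wide.mean(axis=0)
    sd = wide.std(axis=0, ddof=0)
    z = centered.copy()
    nonzero = sd > 0
    z.loc[:, nonzero] = centered.loc[:, nonzero] / sd[nonzero]
    # sd == 0 columns are identically zero after centering already
    corr = wide.corr()
    return z, corr


@dataclass
class PanelDecomposition:
    """PCA scores/loadings and cluster labels for a strain panel."""

    scores: pd.DataFrame            # strains x components
    loadings: pd.DataFrame          # features x components
    variance_explained: np.ndarray  # fraction per component, non-increasing
    cluster_labels: pd.Series       # integer label per strain
    column_means: np.ndarray = field(default=None, repr=False)

    def reconstruct(self) -> np.ndarray:
        """scores @ loadings.T + column means (exact with all components)."""
        return self.scores.to_numpy() @ self.loadings.to_numpy().T \
            + self.column_means


def decompose_and_cluster(matrix: pd.DataFrame, n_clusters: int = 2,
                          n_score_components: int = 2) -> PanelDecomposition:
    """PCA of the panel matrix + average-linkage clustering of the strains.

    Components come from the singular decomposition of the centered matrix;
    strains are grouped by agglomerative clustering (average linkage,
    Euclidean metric) on the first ``n_score_components`` component scores.
    """
    X = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) \
        else np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("panel matrix must be finite")
    n_strains, n_feat = X.shape
    if n_strains < 3:
        raise ValueError("need >= 3 strains to decompose")
    if not 1 <= n_clusters <= n_strains:
        raise ValueError("n_clusters must be in [1, n_strains]")

    index = (matrix.index if isinstance(matrix, pd.DataFrame)
             else pd.RangeIndex(n_strains))
    columns = (matrix.columns if isinstance(matrix, pd.DataFrame)
               else pd.RangeIndex(n_feat))

    pca = PCA(n_components=min(n_strains, n_feat), svd_solver="full")
    scores = pca.fit_transform(X)
    comp_names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    k = min(n_score_components, scores.shape[1])
    if n_clusters == 1:
        labels = np.zeros(n_strains, dtype=int)
    else:
        clusterer = AgglomerativeClustering(
            n_clusters=n_clusters, linkage="average", metric="euclidean")
        labels = clusterer.fit_predict(scores[:, :k])
    return PanelDecomposition(
        scores=pd.DataFrame(scores, index=index, columns=comp_names),
        loadings=pd.DataFrame(pca.components_.T, index=columns,
                              columns=comp_names),
        variance_explained=pca.explained_variance_ratio_,
        cluster_labels=pd.Series(labels, index=index, name="cluster"),
        column_means=pca.mean_)
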