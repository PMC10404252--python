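"""State-space structure of ensemble PN responses: PCA trajectories,
hierarchical clustering of odor vectors, and cosine-angle valence
similarity scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.ndimage import uniform_filter1d
from scipy.spatial.distance import pdist

from .datasets import BinnedResponseMatrix

__all__ = [
    "TrajectorySet",
    "pca_trajectories",
    "ClusterTree",
    "hierarchical_cluster",
    "valence_angle_scores",
    "pairwise_angles",
]


@dataclass
class TrajectorySet:
    """Per-odor projections onto the top principal components.

    ``trajectories[odor]`` is (n_components x bins_per_odor);
    ``variance_fractions`` is the full normalized eigenvalue spectrum,
    non-increasing.
    """

    trajectories: dict[str, np.ndarray]
    variance_fractions: np.ndarray
    components: np.ndarray  # (n_pns, n_components) eigenvectors, columns
    pn_ids: list[str]

    @property
    def captured_variance(self) -> float:
        k = next(iter(self.trajectories.values())).shape[0]
        return float(self.variance_fractions[:k].sum())


def _canonical_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    out = vectors.copy()
    for k in range(out.shape[1]):
        j = np.argmax(np.abs(out[:, k]))
        if out[j, k] < 0:
            out[:, k] = -out[:, k]
    return out


def pca_trajectories(
    X: BinnedResponseMatrix,
    n_components: int = 3,
    center: bool = True,
    subtract_first_bin: bool = True,
    smooth: bool = True,
) -> TrajectorySet:
    """Project trial-averaged ensemble activity onto its top eigenvectors.

    The PN x PN covariance is taken over all concatenated time bins; each
    bin's PN vector is projected onto the leading eigenvectors, the first
    bin of each odor segment is subtracted (common pre-stimulus origin) and
    the trajectory is smoothed with a three-point moving average.
    """
    data = X.data
    if n_components > X.n_pns:
        raise ValueError("more components requested than PNs")
    mean = data.mean(axis=1, keepdims=True) if center else np.zeros((X.n_pns, 1))
    centered = data - mean
    cov = (centered @ centered.T) / max(data.shape[1] - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = _canonical_signs(evecs[:, order])
    total = evals.sum()
    fractions = evals / total if total > 0 else evals
    proj = evecs[:, :n_components].T @ centered  # (k, T)
    b = X.bins_per_odor
    trajectories = {}
    for j, odor in enumerate(X.odor_ids):
        seg = proj[:, j * b : (j + 1) * b].copy()
        if subtract_first_bin:
            seg -= seg[:, [0]]
        if smooth:
            seg = uniform_filter1d(seg, size=3, axis=1, mode="nearest")
        trajectories[odor] = seg
    return TrajectorySet(trajectories, fractions, evecs[:, :n_components], list(X.pn_ids))


@dataclass
class ClusterTree:
    """Agglomerative tree: scipy linkage matrix plus leaf ordering."""

    linkage: np.ndarray
    ids: list[str]
    leaf_order: list[str]

    def merge_records(self) -> list[dict]:
        """Nested merge records (child indices < n_items are leaves)."""
        return [
            {"left": int(a), "right": int(b), "height": float(h), "size": int(s)}
            for a, b, h, s in self.linkage
        ]


def hierarchical_cluster(
    vectors: pd.DataFrame, optimal_ordering: bool = True, method: str = "complete"
) -> ClusterTree:
    """Complete-linkage agglomeration on correlation distance (1 - Pearson r).

    ``vectors`` holds one row per item (e.g. one 89-d mean ON response per
    odor).  Constant rows have undefined correlation and are rejected.
    """
    X = vectors.to_numpy(dtype=float)
    ids = list(map(str, vectors.index))
    if len(ids) < 2:
        raise ValueError("need at least two items to cluster")
    flat = np.ptp(X, axis=1) == 0
    if flat.any():
        bad = [ids[i] for i in np.flatnonzero(flat)]
        raise ValueError(f"constant vectors have undefined correlation distance: {bad}")
    d = pdist(X, metric="correlation")
    Z = hierarchy.linkage(d, method=method)
    if optimal_ordering:
        Z = hierarchy.optimal_leaf_ordering(Z, d)
    leaves = hierarchy.leaves_list(Z)
    return ClusterTree(Z, ids, [ids[i] for i in leaves])


def pairwise_angles(vectors: pd.DataFrame) -> pd.DataFrame:
    """Pairwise angles (degrees) between row vectors."""
    X = vectors.to_numpy(dtype=float)
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        bad = [vectors.index[i] for i in np.flatnonzero(norms == 0)]
        raise ValueError(f"zero vectors have undefined angles: {bad}")
    cos = (X @ X.T) / np.outer(norms, norms)
    ang = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    return pd.DataFrame(ang, index=vectors.index, columns=vectors.index)


def valence_angle_scores(vectors: pd.DataFrame, appetitive: dict[str, bool]) -> pd.DataFrame:
    """Mean angular similarity of each odor to the appetitive and
    non-appetitive groups (self-comparison excluded).

    ``net_score`` = mean angle to non-appetitive others minus mean angle to
    appetitive others; positive means appetitive-like response geometry.
    """
    ids = list(map(str, vectors.index))
    missing = [o for o in ids if o not in appetitive]
    if missing:
        raise ValueError(f"missing valence labels for {missing}")
    ang = pairwise_angles(vectors).to_numpy()
    is_app = np.array([bool(appetitive[o]) for o in ids])
    rows = []
    for i, odor in enumerate(ids):
        others = np.arange(len(ids)) != i
        app_sel = others & is_app
        non_sel = others & ~is_app
        m_app = float(ang[i, app_sel].mean()) if app_sel.any() else np.nan
        m_non = float(ang[i, non_sel].mean()) if non_sel.any() else np.nan
        rows.append(
            {
                "odor_id": odor,
                "mean_angle_appetitive": m_app,
                "mean_angle_nonappetitive": m_non,
                "net_score": m_non - m_app,
            }
        )
    return pd.DataFrame(rows).set_index("odor_id")
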