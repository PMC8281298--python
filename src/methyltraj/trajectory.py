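"""Variability filtering, dimensionality reduction and pseudotime inference.

The trajectory model follows the SCORPIUS-style recipe for a small bulk time
course: keep the most variable loci by MAD, run unscaled PCA on the samples,
cluster the first two components with k-means, order the cluster centers by
the exact shortest open path, and refine the ordered-center polyline into a
principal curve (Hastie–Stuetzle alternation of projection and per-coordinate
smoothing).  Pseudotime is each sample's normalized arc-length along the
curve.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

MAD_CONSTANT = 1.4826  # consistency with the normal sd


class TrajectoryError(ValueError):
    pass


@dataclass
class VariabilitySelection:
    mad_per_probe: pd.Series
    cutoff_value: float
    selected_probes: List[str]


@dataclass
class ReducedSpace:
    scores: pd.DataFrame  # samples x components
    explained_variance_fraction: np.ndarray
    n_components: int


@dataclass
class Trajectory:
    cluster_centers: np.ndarray  # k x d
    center_order: List[int]
    curve: np.ndarray  # polyline, m x d
    pseudotime: pd.Series  # per sample, in [0, 1]
    projection_sse: float = math.nan
    converged: bool = True
    sse_history: List[float] = field(default_factory=list)


def mad(values) -> float:
    """Median absolute deviation, scaled by 1.4826 for normal consistency."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise TrajectoryError("mad of empty vector")
    return MAD_CONSTANT * float(np.median(np.abs(x - np.median(x))))


def mad_per_probe(beta: pd.DataFrame) -> pd.Series:
    x = beta.to_numpy(dtype=float)
    med = np.median(x, axis=1, keepdims=True)
    return pd.Series(MAD_CONSTANT * np.median(np.abs(x - med), axis=1),
                     index=beta.index, name="mad")


def select_top_mad(beta: pd.DataFrame, fraction: float = 0.05) -> VariabilitySelection:
    """Keep the ``ceil(fraction * n_probes)`` most variable probes by MAD.

    Ties at the cutoff are broken lexicographically by probe id so the
    selection is deterministic.
    """
    if not (0 < fraction < 1):
        raise TrajectoryError("fraction must be in (0, 1)")
    n = len(beta.index)
    k = math.ceil(fraction * n)
    if k < 1:
        raise TrajectoryError("fraction * n_probes < 1")
    mads = mad_per_probe(beta)
    order = sorted(zip(-mads.to_numpy(), beta.index.astype(str)))
    selected = [pid for _, pid in order[:k]]
    cutoff = float(mads[selected[-1]])
    return VariabilitySelection(mad_per_probe=mads, cutoff_value=cutoff,
                                selected_probes=selected)


def pca_reduce(beta_subset: pd.DataFrame, n_components: int = 2) -> ReducedSpace:
    """Unscaled PCA with samples as observations and probes as features.

    Features are mean-centered but not variance-scaled, so high-amplitude
    loci dominate the leading components, as intended for beta values that
    share a common scale.
    """
    x = beta_subset.to_numpy(dtype=float).T  # samples x probes
    if np.isnan(x).any():
        raise TrajectoryError("missing values in the beta matrix; run QC first")
    max_rank = min(x.shape)
    if n_components > max_rank:
        raise TrajectoryError(f"n_components > min(n_samples, n_probes) = {max_rank}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    return ReducedSpace(
        scores=pd.DataFrame(scores, index=beta_subset.columns,
                            columns=[f"PC{i + 1}" for i in range(n_components)]),
        explained_variance_fraction=pca.explained_variance_ratio_,
        n_components=n_components,
    )


def shortest_open_path(centers: np.ndarray) -> List[int]:
    """Exact shortest open Hamiltonian path over <= 8 points.

    Enumerates the k!/2 undirected orderings and returns the one with the
    smallest total Euclidean length (first ordering in lexicographic order on
    ties, starting from the lower endpoint index).
    """
    k = len(centers)
    if k > 8:
        raise TrajectoryError("exhaustive path search limited to k <= 8")
    if k == 1:
        return [0]
    dist = cdist(centers, centers)
    best, best_len = None, np.inf
    for perm in itertools.permutations(range(k)):
        if perm[0] > perm[-1]:  # each undirected ordering once
            continue
        length = sum(dist[perm[i], perm[i + 1]] for i in range(k - 1))
        if length < best_len - 1e-12:
            best, best_len = perm, length
    return list(best)


def _project_to_polyline(points: np.ndarray, polyline: np.ndarray):
    """Project points onto a polyline.

    Returns (arclength position per point, squared distance per point,
    total polyline length)."""
    seg_vec = np.diff(polyline, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    seg_len = np.where(seg_len == 0, 1e-12, seg_len)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    pos = np.empty(len(points))
    d2 = np.full(len(points), np.inf)
    for s in range(len(seg_vec)):
        a, v, L = polyline[s], seg_vec[s], seg_len[s]
        t = np.clip((points - a) @ v / (L * L), 0.0, 1.0)
        proj = a + t[:, None] * v
        dist2 = ((points - proj) ** 2).sum(axis=1)
        better = dist2 < d2
        d2[better] = dist2[better]
        pos[better] = cum[s] + t[better] * L
    return pos, d2, cum[-1]


def _smooth_coordinate(arclen: np.ndarray, values: np.ndarray, grid: np.ndarray,
                       degree: int = 3) -> np.ndarray:
    """Cubic polynomial smoother (df = 4) of one coordinate against arc-length."""
    uniq = np.unique(arclen)
    deg = min(degree, max(1, len(uniq) - 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", np.exceptions.RankWarning)
        coefs = np.polyfit(arclen, values, deg)
    return np.polyval(coefs, grid)


def fit_principal_curve(points: np.ndarray, init_polyline: np.ndarray,
                        n_grid: int = 101, max_iter: int = 50,
                        tol: float = 1e-4):
    """Hastie–Stuetzle principal curve from an initial polyline.

    Alternates projecting the points onto the current polyline with
    re-estimating each coordinate by a low-df smoother against arc-length.
    Returns (polyline, arclength positions, sse, converged, sse_history).
    """
    # densify the initial polyline so projections are smooth
    polyline = _resample_polyline(init_polyline, n_grid)
    pos, d2, total = _project_to_polyline(points, polyline)
    sse = float(d2.sum())
    history = [sse]
    converged = False
    for _ in range(max_iter):
        grid = np.linspace(pos.min(), pos.max(), n_grid)
        new_poly = np.column_stack([
            _smooth_coordinate(pos, points[:, j], grid) for j in range(points.shape[1])
        ])
        new_pos, new_d2, _ = _project_to_polyline(points, new_poly)
        new_sse = float(new_d2.sum())
        history.append(new_sse)
        rel = abs(sse - new_sse) / max(sse, 1e-12)
        polyline, pos, sse = new_poly, new_pos, new_sse
        if rel < tol:
            converged = True
            break
    if not converged:
        warnings.warn("principal curve did not converge; returning last iterate")
    return polyline, pos, sse, converged, history


def _resample_polyline(polyline: np.ndarray, n: int) -> np.ndarray:
    seg = np.diff(polyline, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    if cum[-1] == 0:
        return np.repeat(polyline[:1], n, axis=0)
    s = np.linspace(0, cum[-1], n)
    out = np.empty((n, polyline.shape[1]))
    for j in range(polyline.shape[1]):
        out[:, j] = np.interp(s, cum, polyline[:, j])
    return out


def infer_trajectory(space: ReducedSpace, k: int = 4, seed: int = 0,
                     n_restarts: int = 10, max_iter: int = 50,
                     tol: float = 1e-4) -> Trajectory:
    """Infer a pseudotime trajectory through the sample cloud.

    Uses the first two components: k-means (with restarts) finds stage-like
    clusters, the exact shortest open path orders their centers, and a
    principal curve refines the ordered-center polyline.  Pseudotime is the
    min–max scaled arc-length of each sample's projection.
    """
    pts = space.scores.iloc[:, :2].to_numpy(dtype=float)
    n = len(pts)
    if k > n:
        raise TrajectoryError("k cannot exceed the number of samples")
    if k > 8:
        raise TrajectoryError("k <= 8 required for exact path search")

    centers = None
    for attempt in range(10):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed + attempt)
        labels = km.fit_predict(pts)
        if len(np.unique(labels)) == k:
            centers = km.cluster_centers_
            break
    if centers is None:
        raise TrajectoryError("k-means produced empty clusters in 10 restarts")

    order = shortest_open_path(centers)
    init = centers[order]
    curve, pos, sse, converged, history = fit_principal_curve(
        pts, init, max_iter=max_iter, tol=tol
    )
    span = pos.max() - pos.min()
    if span == 0:
        ptime = np.zeros(n)
    else:
        ptime = (pos - pos.min()) / span
    return Trajectory(
        cluster_centers=centers,
        center_order=order,
        curve=curve,
        pseudotime=pd.Series(ptime, index=space.scores.index, name="pseudotime"),
        projection_sse=sse,
        converged=converged,
        sse_history=history,
    )


def orient_pseudotime(traj: Trajectory, samples: pd.DataFrame, anchor_stage: str) -> Trajectory:
    """Flip pseudotime so the anchor stage (e.g. the stem-cell stage) sits near 0."""
    if anchor_stage not in set(samples["stage"]):
        raise TrajectoryError(f"unknown stage label {anchor_stage!r}")
    anchor_samples = samples.index[samples["stage"] == anchor_stage]
    mean_pt = traj.pseudotime.loc[[s for s in anchor_samples if s in traj.pseudotime.index]].mean()
    if mean_pt > 0.5:
        flipped = 1.0 - traj.pseudotime
        return Trajectory(
            cluster_centers=traj.cluster_centers,
            center_order=list(reversed(traj.center_order)),
            curve=traj.curve[::-1].copy(),
            pseudotime=flipped,
            projection_sse=traj.projection_sse,
            converged=traj.converged,
            sse_history=list(traj.sse_history),
        )
    return traj


def plot_trajectory(space: ReducedSpace, traj: Trajectory,
                    samples: Optional[pd.DataFrame] = None, path=None):
    """Diagnostic scatter of PC1/PC2 with the fitted curve overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    pts = space.scores.iloc[:, :2]
    if samples is not None:
        for stage, grp in pts.groupby(samples.loc[pts.index, "stage"]):
            ax.scatter(grp.iloc[:, 0], grp.iloc[:, 1], label=str(stage), s=30)
        ax.legend(fontsize=7)
    else:
        ax.scatter(pts.iloc[:, 0], pts.iloc[:, 1], s=30)
    ax.plot(traj.curve[:, 0], traj.curve[:, 1], "k-", lw=1)
    evf = space.explained_variance_fraction
    ax.set_xlabel(f"PC1 ({evf[0]:.1%})")
    ax.set_ylabel(f"PC2 ({evf[1]:.1%})" if len(evf) > 1 else "PC2")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
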