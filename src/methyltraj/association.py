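"""Per-locus GAM regression on pseudotime and the trajectory signature.

Each locus' beta values are regressed on (two-decimal rounded) pseudotime
with a cubic regression spline.  Significance of the smooth term against the
intercept-only model comes from the exact F-test of the unpenalized spline
(fixed degrees of freedom), which is calibrated under the null; the curve
reported for shape classification is the penalized fit with its smoothing
parameter chosen per locus by generalized cross-validation, which is what a
GCV-tuned F-statistic is not: selecting the smoothing parameter on the same
data inflates the apparent significance, so estimation and testing use
different amounts of shrinkage.  Bonferroni-significant loci form the
trajectory signature, are labelled hypo-/hypermethylated from the fitted
endpoints, and are grouped into shape modules by Ward clustering of their
standardized fitted curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.interpolate import BSpline

PSEUDOTIME_GRID = np.linspace(0.0, 1.0, 101)
CURVE_CLIP = (-0.1, 1.1)  # plausible beta range incl. bounded smoother overshoot


class AssociationError(ValueError):
    pass


@dataclass
class GamFit:
    probe_id: str
    pvalue: float
    edf: float
    fitted_curve: np.ndarray  # on PSEUDOTIME_GRID
    delta_end: float
    singular: bool = False


@dataclass
class TrajectorySignature:
    """Bonferroni-significant loci with direction and shape-module labels."""

    table: pd.DataFrame  # index probe_id; columns pvalue, delta_end, direction[, module]
    alpha: float
    n_tests: int

    @property
    def probes(self) -> List[str]:
        return list(self.table.index)

    @property
    def n_hypo(self) -> int:
        return int((self.table["direction"] == "hypo").sum())

    @property
    def n_hyper(self) -> int:
        return int((self.table["direction"] == "hyper").sum())

    def __len__(self) -> int:
        return len(self.table)


def round_pseudotime(t) -> np.ndarray:
    """Half-up rounding of pseudotime to two decimals."""
    t = np.asarray(t, dtype=float)
    return np.floor(t * 100.0 + 0.5) / 100.0


def _spline_basis(t: np.ndarray, basis_dim: int = 4):
    """Cubic B-spline basis on [0, 1] with ``basis_dim`` columns, plus its
    curvature penalty matrix (integrated squared second derivative)."""
    if basis_dim < 4:
        raise AssociationError("basis_dim must be >= 4 for a cubic basis")
    n_interior = basis_dim - 4
    interior = np.linspace(0, 1, n_interior + 2)[1:-1] if n_interior else np.array([])
    knots = np.concatenate([[0.0] * 4, interior, [1.0] * 4])
    B = BSpline.design_matrix(t, knots, 3).toarray()
    grid = np.linspace(0.0, 1.0, 201)
    D = np.column_stack([
        BSpline(knots, np.eye(basis_dim)[i], 3).derivative(2)(grid)
        for i in range(basis_dim)
    ])
    w = np.full(len(grid), grid[1] - grid[0])
    w[[0, -1]] /= 2.0
    P = (D * w[:, None]).T @ D
    Bg = BSpline.design_matrix(PSEUDOTIME_GRID, knots, 3).toarray()
    return B, P, Bg


def fit_gam_matrix(beta: pd.DataFrame, t, basis_dim: int = 4,
                   lambda_grid: Optional[np.ndarray] = None):
    """Vectorized per-locus GAM fits against a shared pseudotime.

    Returns ``(results, fitted_curves)`` where ``results`` is a DataFrame
    indexed by probe with columns pvalue/edf/delta_end/singular and
    ``fitted_curves`` is an array (n_probes x 101) on the unit pseudotime
    grid.  The design matrix is shared across loci, so the whole matrix is
    fitted with a handful of 4x4 solves per smoothing-parameter value.
    """
    t = np.asarray(t, dtype=float)
    if t.min() < 0 or t.max() > 1:
        raise AssociationError("pseudotime must lie in [0, 1]")
    n = len(t)
    if np.allclose(t, t[0]):
        raise AssociationError("pseudotime values are all equal")
    if n < basis_dim + 2:
        raise AssociationError(f"need at least basis_dim + 2 = {basis_dim + 2} samples")
    if beta.shape[1] != n:
        raise AssociationError("beta columns must match pseudotime length")

    Y = beta.to_numpy(dtype=float).T  # n x p
    p = Y.shape[1]
    B, P, Bg = _spline_basis(t, basis_dim)
    BtB = B.T @ B
    # scale the penalty so the lambda grid is dimensionless
    P_s = P * (np.trace(BtB) / max(np.trace(P), 1e-12))
    if lambda_grid is None:
        lambda_grid = np.logspace(-8, 8, 33)

    BtY = B.T @ Y
    rss = np.empty((len(lambda_grid), p))
    edf = np.empty(len(lambda_grid))
    solvers = []
    for li, lam in enumerate(lambda_grid):
        M = np.linalg.solve(BtB + lam * P_s, np.eye(basis_dim))
        solvers.append(M)
        coefs = M @ BtY  # basis_dim x p
        resid = Y - B @ coefs
        rss[li] = (resid ** 2).sum(axis=0)
        edf[li] = float(np.trace(B @ M @ B.T))
    denom = np.maximum(n - edf, 1e-6)
    gcv = n * rss / (denom ** 2)[:, None]
    best = np.argmin(gcv, axis=0)

    fitted = np.empty((p, len(PSEUDOTIME_GRID)))
    coef_sel = np.empty((basis_dim, p))
    for li in np.unique(best):
        cols = np.flatnonzero(best == li)
        coef_sel[:, cols] = solvers[li] @ BtY[:, cols]
    fitted[:, :] = (Bg @ coef_sel).T
    np.clip(fitted, CURVE_CLIP[0], CURVE_CLIP[1], out=fitted)

    # exact F-test on the unpenalized spline: numerator df = basis_dim - 1
    coef0, _, rank0, _ = np.linalg.lstsq(B, Y, rcond=None)
    rss_un = ((Y - B @ coef0) ** 2).sum(axis=0)
    rss0 = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    # constant loci have rss0 at rounding-noise level, not exactly zero
    singular = (rss0 <= 1e-25) | (rank0 < basis_dim)
    df_num = basis_dim - 1
    df_den = n - basis_dim
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss_un) / df_num) / np.maximum(rss_un / df_den, 1e-300)
    F = np.where(F < 0, 0.0, F)
    pval = np.where(singular, 1.0, stats.f.sf(F, df_num, df_den))
    if singular.any():
        warnings.warn(f"{int(singular.sum())} loci had a degenerate fit; p set to 1")

    results = pd.DataFrame(
        {
            "pvalue": pval,
            # smooth-term edf of the GCV fit (excludes the intercept)
            "edf": edf[best] - 1.0,
            "delta_end": fitted[:, -1] - fitted[:, 0],
            "singular": singular,
        },
        index=beta.index,
    )
    return results, fitted


def fit_locus_gam(beta_locus, t, basis_dim: int = 4, probe_id: str = "locus") -> GamFit:
    """Fit a single locus; see :func:`fit_gam_matrix` for the model."""
    y = np.asarray(beta_locus, dtype=float)
    df = pd.DataFrame(y[None, :], index=[probe_id])
    res, fitted = fit_gam_matrix(df, t, basis_dim=basis_dim)
    row = res.iloc[0]
    return GamFit(
        probe_id=probe_id,
        pvalue=float(row["pvalue"]),
        edf=float(row["edf"]),
        fitted_curve=fitted[0],
        delta_end=float(row["delta_end"]),
        singular=bool(row["singular"]),
    )


def classify_direction(delta_end: float) -> str:
    """hypo if the fitted curve ends below its start, hyper otherwise."""
    if delta_end < 0:
        return "hypo"
    if delta_end == 0:
        warnings.warn("delta_end exactly zero; classified hyper by convention")
    return "hyper"


def bonferroni_select(results: pd.DataFrame, alpha: float = 0.05,
                      n_tests: Optional[int] = None) -> TrajectorySignature:
    """Keep loci with ``p <= alpha / n_tests`` (n_tests defaults to the
    number of fitted loci)."""
    if n_tests is None:
        n_tests = len(results)
    if n_tests > 0:
        thresh = alpha / n_tests
        keep = results[results["pvalue"] <= thresh].copy()
    else:
        keep = results.iloc[0:0].copy()
    keep["direction"] = [classify_direction(d) for d in keep["delta_end"]] if len(keep) else []
    keep = keep.sort_values("pvalue")
    return TrajectorySignature(table=keep, alpha=alpha, n_tests=n_tests)


def assign_modules(signature: TrajectorySignature, fitted_curves: pd.DataFrame,
                   n_modules: int = 9, seed: int = 0) -> TrajectorySignature:
    """Group signature loci into shape modules.

    Each fitted curve is z-scored, curves are Ward-clustered on Euclidean
    distance and the tree cut into ``n_modules`` groups.  Module ids are
    relabelled by the mean pseudotime of maximum absolute change, so labels
    are reproducible across runs.  ``fitted_curves`` must be indexed by probe
    with one column per grid point.
    """
    probes = signature.probes
    if len(probes) < n_modules:
        raise AssociationError(f"signature smaller than n_modules = {n_modules}")
    curves = fitted_curves.loc[probes].to_numpy(dtype=float)
    mu = curves.mean(axis=1, keepdims=True)
    sd = curves.std(axis=1, keepdims=True)
    z = np.where(sd > 1e-12, (curves - mu) / np.where(sd > 1e-12, sd, 1.0), 0.0)

    if n_modules == 1:
        labels = np.ones(len(probes), dtype=int)
    else:
        Z = linkage(z, method="ward")
        labels = fcluster(Z, t=n_modules, criterion="maxclust")

    # relabel by when each module changes fastest along pseudotime
    grid = PSEUDOTIME_GRID
    change_time = {}
    for lab in np.unique(labels):
        mean_curve = curves[labels == lab].mean(axis=0)
        grad = np.abs(np.gradient(mean_curve, grid))
        change_time[lab] = float(grid[int(np.argmax(grad))])
    order = sorted(np.unique(labels), key=lambda lab: (change_time[lab], lab))
    remap = {old: new + 1 for new, old in enumerate(order)}
    new_labels = np.array([remap[lab] for lab in labels], dtype=int)

    table = signature.table.copy()
    table.loc[probes, "module"] = new_labels
    table["module"] = table["module"].astype(int)
    return TrajectorySignature(table=table, alpha=signature.alpha, n_tests=signature.n_tests)


def summarize_module_change(signature: TrajectorySignature, beta: pd.DataFrame,
                            samples: pd.DataFrame, stage_a: str, stage_b: str) -> pd.Series:
    """Per-module mean beta change stage_a -> stage_b, in percentage points."""
    for stage in (stage_a, stage_b):
        if stage not in set(samples["stage"]):
            raise AssociationError(f"unknown stage {stage!r}")
    if "module" not in signature.table.columns:
        raise AssociationError("assign_modules first")
    cols_a = [s for s in beta.columns if samples.loc[s, "stage"] == stage_a]
    cols_b = [s for s in beta.columns if samples.loc[s, "stage"] == stage_b]
    mean_a = beta[cols_a].mean(axis=1)
    mean_b = beta[cols_b].mean(axis=1)
    diff = (mean_b - mean_a) * 100.0
    out = {}
    for mod, grp in signature.table.groupby("module"):
        out[int(mod)] = float(diff.loc[grp.index].mean())
    return pd.Series(out, name="mean_change_pct").sort_index()


def signature_to_table(signature: TrajectorySignature,
                       annotation: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Flat signature table, optionally joined with genomic annotation."""
    out = signature.table.copy()
    out.index.name = "probe_id"
    if annotation is not None:
        cols = [c for c in ("gene_symbols", "chromosome", "position",
                            "region_group", "cgi_relation") if c in annotation.columns]
        out = out.join(annotation[cols], how="left")
    return out
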