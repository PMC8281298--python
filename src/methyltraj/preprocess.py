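"""Intensity-level QC, filtering and normalization.

The stages mirror the standard array workflow: detection-p based sample and
probe filtering (p-filter), a median-intensity sample check, two-chemistry
background equalization followed by within-type quantile normalization of the
methylated and unmethylated channels (dasen-style), beta computation with the
conventional offset, and annotation-based probe exclusion (SNP-adjacent and
cross-hybridizing probes).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set

import numpy as np
import pandas as pd

BETA_OFFSET = 100.0


class QCError(ValueError):
    pass


@dataclass
class IntensityPair:
    """Matched methylated/unmethylated intensities plus QC channels."""

    methylated: pd.DataFrame
    unmethylated: pd.DataFrame
    detection_p: Optional[pd.DataFrame] = None
    beadcount: Optional[pd.DataFrame] = None
    probe_type: Optional[pd.Series] = None

    def __post_init__(self):
        m, u = self.methylated, self.unmethylated
        if not m.index.equals(u.index) or not m.columns.equals(u.columns):
            raise QCError("methylated/unmethylated matrices must share probe and sample indexes")
        for name in ("detection_p", "beadcount"):
            other = getattr(self, name)
            if other is not None and (
                not other.index.equals(m.index) or not other.columns.equals(m.columns)
            ):
                raise QCError(f"{name} index mismatch")
        if self.probe_type is not None and not self.probe_type.index.equals(m.index):
            raise QCError("probe_type index mismatch")

    @property
    def probes(self) -> pd.Index:
        return self.methylated.index

    @property
    def samples(self) -> pd.Index:
        return self.methylated.columns

    def subset(self, probes=None, samples=None) -> "IntensityPair":
        def cut(df):
            if df is None:
                return None
            out = df
            if probes is not None:
                out = out.loc[probes]
            if samples is not None:
                out = out[samples]
            return out

        return IntensityPair(
            methylated=cut(self.methylated),
            unmethylated=cut(self.unmethylated),
            detection_p=cut(self.detection_p),
            beadcount=cut(self.beadcount),
            probe_type=self.probe_type.loc[probes] if (self.probe_type is not None and probes is not None) else self.probe_type,
        )


@dataclass
class QCReport:
    failed_samples: Dict[str, str] = field(default_factory=dict)
    removed_probes: Dict[str, str] = field(default_factory=dict)
    thresholds: Dict[str, float] = field(default_factory=dict)
    n_samples_before: int = 0
    n_samples_after: int = 0
    n_probes_before: int = 0
    n_probes_after: int = 0

    def validate(self) -> None:
        assert self.n_samples_after == self.n_samples_before - len(self.failed_samples)
        assert self.n_probes_after == self.n_probes_before - len(self.removed_probes)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def compute_beta(intensities: IntensityPair, offset: float = BETA_OFFSET) -> pd.DataFrame:
    """Beta values ``M / (M + U + offset)``, elementwise."""
    if offset < 0:
        raise QCError("offset must be non-negative")
    m, u = intensities.methylated, intensities.unmethylated
    return m / (m + u + offset)


def median_intensity_check(intensities: IntensityPair, min_median: float) -> Set[str]:
    """Samples whose median methylated OR unmethylated intensity is below threshold."""
    med_m = intensities.methylated.median(axis=0)
    med_u = intensities.unmethylated.median(axis=0)
    bad = (med_m < min_median) | (med_u < min_median)
    return set(bad.index[bad])


def pfilter(intensities: IntensityPair, detp_thresh: float = 0.05,
            sample_frac: float = 0.01, probe_frac: float = 0.01,
            bead_min: int = 3, bead_frac: float = 0.05) -> QCReport:
    """Detection-p based QC: flag bad samples first, then bad probes.

    A sample fails when more than ``sample_frac`` of its probes have detection
    p above ``detp_thresh``.  Among surviving samples, a probe fails when its
    detection p exceeds the threshold in more than ``probe_frac`` of samples,
    or (when bead counts are available) its bead count is below ``bead_min``
    in more than ``bead_frac`` of samples.
    """
    if intensities.detection_p is None:
        raise QCError("pfilter requires detection p-values")
    detp = intensities.detection_p
    report = QCReport(
        thresholds={
            "detp_thresh": detp_thresh,
            "sample_frac": sample_frac,
            "probe_frac": probe_frac,
            "bead_min": bead_min,
            "bead_frac": bead_frac,
        },
        n_samples_before=len(intensities.samples),
        n_probes_before=len(intensities.probes),
    )
    frac_bad = (detp > detp_thresh).mean(axis=0)
    for sid in detp.columns[frac_bad > sample_frac]:
        report.failed_samples[sid] = (
            f"detection p > {detp_thresh} in {frac_bad[sid]:.1%} of probes"
        )
    surviving = [s for s in detp.columns if s not in report.failed_samples]
    if not surviving:
        raise QCError("all samples failed the p-filter: empty dataset")

    probe_bad = (detp[surviving] > detp_thresh).mean(axis=1)
    flagged = set(detp.index[probe_bad > probe_frac])
    for pid in flagged:
        report.removed_probes[pid] = f"detection p > {detp_thresh} in >{probe_frac:.0%} of samples"
    if intensities.beadcount is not None:
        low_bead = (intensities.beadcount[surviving] < bead_min).mean(axis=1)
        for pid in detp.index[low_bead > bead_frac]:
            if pid not in report.removed_probes:
                report.removed_probes[pid] = f"beadcount < {bead_min} in >{bead_frac:.0%} of samples"

    report.n_samples_after = len(surviving)
    report.n_probes_after = report.n_probes_before - len(report.removed_probes)
    report.validate()
    return report


def _quantile_normalize(mat: np.ndarray) -> np.ndarray:
    """Classic quantile normalization: each column takes the cross-column mean
    order-statistic distribution; ties within a column get the mean of the
    corresponding reference values."""
    n, p = mat.shape
    order = np.argsort(mat, axis=0, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(n)
    for j in range(p):
        ranks[order[:, j], j] = rows
    sorted_mat = np.take_along_axis(mat, order, axis=0)
    ref = sorted_mat.mean(axis=1)
    out = ref[ranks]
    # average reference values over tied entries, per column
    for j in range(p):
        col = mat[:, j]
        uniq, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        if len(uniq) < n:
            sums = np.bincount(inv, weights=out[:, j])
            out[:, j] = (sums / counts)[inv]
    return out


def dasen_normalize(intensities: IntensityPair, background_quantile: float = 0.05,
                    offset: float = BETA_OFFSET) -> pd.DataFrame:
    """Two-chemistry background equalization + within-type quantile normalization.

    Per sample and channel, type-I intensities are shifted by the difference
    of the low-quantile backgrounds so both chemistries share a baseline; each
    channel is then quantile-normalized across samples within probe type, and
    beta is computed from the normalized intensities.
    """
    if len(intensities.samples) < 2:
        raise QCError("dasen needs at least 2 samples")
    if intensities.probe_type is None:
        raise QCError("dasen needs probe_type assignments")
    ptype = intensities.probe_type
    meth = intensities.methylated.to_numpy(dtype=float).copy()
    unmeth = intensities.unmethylated.to_numpy(dtype=float).copy()
    is_one = (ptype == "I").to_numpy()
    is_two = ~is_one

    for mat in (meth, unmeth):
        if is_one.sum() >= 2 and is_two.sum() >= 2:
            q1 = np.quantile(mat[is_one], background_quantile, axis=0)
            q2 = np.quantile(mat[is_two], background_quantile, axis=0)
            mat[is_one] += (q2 - q1)[None, :]
        else:
            warnings.warn("a probe type has <2 probes; background shift skipped")

    for mask in (is_one, is_two):
        if mask.sum() >= 2:
            meth[mask] = _quantile_normalize(meth[mask])
            unmeth[mask] = _quantile_normalize(unmeth[mask])
        else:
            warnings.warn("a probe type has <2 probes; quantile normalization skipped for it")

    meth_df = pd.DataFrame(meth, index=intensities.probes, columns=intensities.samples)
    unmeth_df = pd.DataFrame(unmeth, index=intensities.probes, columns=intensities.samples)
    return meth_df / (meth_df + unmeth_df + offset)


def filter_probes(beta: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Drop SNP-adjacent and cross-hybridizing probes (annotation flags)."""
    covered = beta.index.intersection(annotation.index)
    if len(covered) < len(beta.index):
        warnings.warn(f"{len(beta.index) - len(covered)} probes lack annotation; dropped")
    ann = annotation.loc[covered]
    keep = covered[~(ann["snp_flag"].astype(bool) | ann["crossreactive_flag"].astype(bool))]
    if len(keep) == 0:
        raise QCError("no probes left after SNP/cross-reactive exclusion")
    return beta.loc[keep]


def qc_pipeline(intensities: IntensityPair, annotation: Optional[pd.DataFrame] = None,
                min_median: Optional[float] = None, detp_thresh: float = 0.05,
                sample_frac: float = 0.01, probe_frac: float = 0.01):
    """Full preprocessing: sample QC -> probe QC -> dasen -> annotation exclusion.

    Returns ``(beta, report)``.  ``min_median`` has no universal default; pass
    a value appropriate for the array's intensity scale (a common heuristic is
    a fraction of the expected total intensity).
    """
    report = pfilter(intensities, detp_thresh=detp_thresh,
                     sample_frac=sample_frac, probe_frac=probe_frac)
    failed = set(report.failed_samples)
    if min_median is not None:
        for sid in median_intensity_check(intensities, min_median):
            if sid not in failed:
                report.failed_samples[sid] = f"median intensity < {min_median}"
                failed.add(sid)
        report.thresholds["min_median"] = min_median
    keep_samples = [s for s in intensities.samples if s not in failed]
    if not keep_samples:
        raise QCError("all samples failed QC: empty dataset")
    keep_probes = [p for p in intensities.probes if p not in report.removed_probes]
    sub = intensities.subset(probes=keep_probes, samples=keep_samples)
    beta = dasen_normalize(sub)
    beta = beta.dropna(axis=0, how="any")
    if annotation is not None:
        n_before = len(beta)
        beta = filter_probes(beta, annotation)
        for pid in set(sub.probes) - set(beta.index):
            if pid not in report.removed_probes:
                report.removed_probes[pid] = "SNP/cross-reactive/unannotated"
        del n_before
    report.n_samples_after = len(keep_samples)
    report.n_probes_after = len(beta)
    report.n_probes_before = len(intensities.probes)
    return beta, report
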