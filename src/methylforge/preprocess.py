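"""Probe/sample QC, normalization, and the beta / M-value transforms.

Beta is the methylated fraction ``M / (M + U + offset)``; the M-value is
its logit on the log2 scale, ``log2(beta / (1 - beta))``, the
variance-stabilized scale used for regression. Probe filtering removes
detection failures and SNP-overlapping probes; sample QC flags specimens
whose genome-wide beta density is not bimodal and multidimensional-scaling
outliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import SignalMatrix

logger = logging.getLogger(__name__)


@dataclass
class QcReport:
    """Dropped probes (with reasons) and per-sample QC flags."""

    dropped_probes: list[tuple[str, str]] = field(default_factory=list)
    sample_flags: dict[str, dict[str, bool]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "dropped_probes": [list(t) for t in self.dropped_probes],
            "sample_flags": self.sample_flags,
        }


def compute_beta(meth, unmeth, offset: float = 100.0):
    """Beta = meth / (meth + unmeth + offset), elementwise.

    Defined as 0 (with a warning) where the denominator vanishes. Works on
    scalars, arrays and DataFrames; labels are preserved.
    """
    if offset < 0:
        raise ValueError("offset must be non-negative")
    m = np.asarray(meth, dtype=float)
    u = np.asarray(unmeth, dtype=float)
    if (m < 0).any() or (u < 0).any():
        raise ValueError("intensities must be non-negative")
    denom = m + u + offset
    zero = denom == 0
    if zero.any():
        logger.warning("zero total signal at %d entries; beta set to 0", zero.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(zero, 0.0, m / np.where(zero, 1.0, denom))
    if isinstance(meth, pd.DataFrame):
        return pd.DataFrame(beta, index=meth.index, columns=meth.columns)
    if np.isscalar(meth) or np.ndim(meth) == 0:
        return float(beta)
    return beta


def beta_to_m(beta, eps: float = 1e-6):
    """M-value: log2(b / (1 - b)) after clipping b to [eps, 1 - eps]."""
    if not (0 < eps < 0.5):
        raise ValueError("eps must lie in (0, 0.5)")
    b = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    m = np.log2(b / (1.0 - b))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if np.isscalar(beta) or np.ndim(beta) == 0:
        return float(m)
    return m


def m_to_beta(m):
    """Inverse of :func:`beta_to_m` (on the clipped domain)."""
    arr = np.asarray(m, dtype=float)
    b = 1.0 / (1.0 + np.power(2.0, -arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(b, index=m.index, columns=m.columns)
    if np.isscalar(m) or np.ndim(m) == 0:
        return float(b)
    return b


def filter_probes(
    signal: SignalMatrix,
    manifest: pd.DataFrame,
    det_threshold: float = 0.01,
    det_policy: str = "any",
) -> tuple[SignalMatrix, QcReport]:
    """Drop detection-failed and SNP-overlapping probes.

    ``det_policy='any'`` (default, strictest) drops a probe whose
    detection p exceeds ``det_threshold`` in at least one sample;
    ``'fraction:x'`` drops it when the failing fraction of samples exceeds
    ``x``. Probes flagged as overlapping a SNP are always dropped.
    """
    if not manifest.index.is_unique:
        raise ValueError("manifest probe ids must be unique")
    missing = signal.probe_ids.difference(manifest.index)
    if len(missing):
        raise ValueError(f"manifest does not cover {len(missing)} probes")

    detp = signal.detection_p
    fail = (detp > det_threshold).to_numpy()
    if det_policy == "any":
        det_drop = fail.any(axis=1)
    elif det_policy.startswith("fraction:"):
        frac = float(det_policy.split(":", 1)[1])
        det_drop = fail.mean(axis=1) > frac
    else:
        raise ValueError(f"unknown det_policy {det_policy!r}")
    snp_drop = manifest.loc[signal.probe_ids, "snp_flag"].to_numpy(dtype=bool)

    report = QcReport()
    for pid, d, s in zip(signal.probe_ids, det_drop, snp_drop):
        if d:
            report.dropped_probes.append((pid, "detection"))
        elif s:
            report.dropped_probes.append((pid, "snp"))
    keep = ~(det_drop | snp_drop)
    if not keep.any():
        raise ValueError("no probes survive filtering")
    kept = signal.probe_ids[keep]
    return signal.subset_probes(kept), report


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common distribution of row-rank means.

    The reference distribution is the across-column mean of the sorted
    columns; each entry is replaced by the reference value at its
    within-column rank, tied entries sharing the mean over their rank
    range. Labels are preserved.
    """
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("missing values not allowed")
    if values.shape[1] < 2:
        logger.warning("single-column input; quantile normalization is a no-op")
        return matrix.copy()
    reference = np.sort(values, axis=0).mean(axis=1)
    n = values.shape[0]
    out = np.empty_like(values)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def sample_qc(
    beta: pd.DataFrame,
    midband: tuple[float, float] = (0.3, 0.7),
    midband_max: float = 0.35,
    mds_k: float = 5.0,
) -> QcReport:
    """Flag non-bimodal samples and multidimensional-scaling outliers.

    A sample fails the bimodality check when more than ``midband_max`` of
    its betas fall in the mid-band (default [0.3, 0.7]) — a bimodal
    genome-wide density concentrates mass near 0 and 1. MDS outliers are
    samples whose 2-D classical-scaling coordinates (from 1 - Pearson
    correlation distances) lie more than ``mds_k``
    median-absolute-deviations from the centroid.
    """
    if beta.shape[1] < 3:
        raise ValueError("need >= 3 samples for sample QC")
    values = beta.to_numpy(dtype=float)
    lo, hi = midband
    mid_frac = ((values >= lo) & (values <= hi)).mean(axis=0)
    bimodal_pass = mid_frac <= midband_max

    # classical (Torgerson) MDS of 1 - Pearson correlation distances
    sd = values.std(axis=0)
    if (sd == 0).all():
        logger.warning("constant beta matrix; MDS coordinates all zero")
        coords = np.zeros((values.shape[1], 2))
    else:
        corr = np.corrcoef(values, rowvar=False)
        corr = np.nan_to_num(corr, nan=0.0)
        dist = 1.0 - corr
        d2 = dist**2
        n = d2.shape[0]
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ d2 @ j
        w, v = np.linalg.eigh(b)
        top = np.argsort(w)[::-1][:2]
        coords = v[:, top] * np.sqrt(np.maximum(w[top], 0.0))

    centroid = coords.mean(axis=0)
    dists = np.linalg.norm(coords - centroid, axis=1)
    mad = np.median(np.abs(dists - np.median(dists)))
    if mad == 0:
        outlier = np.zeros(len(dists), dtype=bool)
    else:
        outlier = (dists - np.median(dists)) / mad > mds_k

    report = QcReport()
    for i, sid in enumerate(beta.columns):
        report.sample_flags[sid] = {
            "bimodality_pass": bool(bimodal_pass[i]),
            "mds_outlier": bool(outlier[i]),
        }
    return report
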