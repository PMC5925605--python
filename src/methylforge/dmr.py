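"""Bump hunting: differentially methylated regions with resampling FWER.

Probes are chained into clusters (neighboring CpGs no more than ``maxgap``
bp apart), the per-probe tumor-minus-normal beta difference is smoothed
within clusters, and maximal same-sign runs exceeding an effect cutoff
with a minimum probe count become candidate regions. Family-wise error is
controlled by recomputing the maximum candidate statistic under B
label-resampled null datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import validate_manifest

logger = logging.getLogger(__name__)

REGION_COLUMNS = ["chrom", "start", "end", "n_probes", "value", "area"]


@dataclass
class ProbeCluster:
    """A maximal chain of probes with inter-probe gaps <= maxgap."""

    cluster_id: int
    probe_ids: list[str]
    chrom: str


def cluster_index(manifest: pd.DataFrame, maxgap: int) -> np.ndarray:
    """Cluster id per probe, in manifest order (greedy gap chaining)."""
    chrom = manifest["chrom"].to_numpy()
    pos = manifest["pos"].to_numpy()
    if len(manifest) == 0:
        return np.array([], dtype=int)
    new = np.ones(len(manifest), dtype=bool)
    same_chrom = chrom[1:] == chrom[:-1]
    close = (pos[1:] - pos[:-1]) <= maxgap
    new[1:] = ~(same_chrom & close)
    return np.cumsum(new) - 1


def cluster_probes(manifest: pd.DataFrame, maxgap: int = 500) -> list[ProbeCluster]:
    """Chain probes into maximal clusters with gaps <= ``maxgap`` bp."""
    validate_manifest(manifest)
    ids = cluster_index(manifest, maxgap)
    out = []
    for cid in np.unique(ids):
        rows = manifest.index[ids == cid]
        out.append(
            ProbeCluster(
                cluster_id=int(cid),
                probe_ids=list(rows),
                chrom=str(manifest.loc[rows[0], "chrom"]),
            )
        )
    return out


def probe_level_values(beta: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Per-probe delta-beta: mean over tumors minus mean over normals."""
    from .diffmeth import delta_beta

    return delta_beta(beta, groups)


def smooth_in_clusters(values, cluster_ids: np.ndarray, window: int = 3):
    """Truncated running mean within each cluster.

    ``window`` must be odd; half-width ``(window - 1) / 2`` windows are
    truncated at cluster edges (small clusters average whatever neighbors
    exist). ``window = 1`` is the identity. Accepts a 1-D vector or a 2-D
    (probe x replicate) array; smoothing acts along axis 0.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    arr = np.asarray(values, dtype=float)
    if window == 1:
        return arr.copy()
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[:, None]
    half = (window - 1) // 2
    out = np.empty_like(arr)
    boundaries = np.flatnonzero(np.diff(cluster_ids)) + 1
    starts = np.concatenate([[0], boundaries])
    stops = np.concatenate([boundaries, [len(cluster_ids)]])
    for s, e in zip(starts, stops):
        block = arr[s:e]
        csum = np.vstack([np.zeros((1, block.shape[1])), np.cumsum(block, axis=0)])
        idx = np.arange(e - s)
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half + 1, e - s)
        out[s:e] = (csum[hi] - csum[lo]) / (hi - lo)[:, None]
    return out[:, 0] if squeeze else out


def _max_run_stat(
    sm: np.ndarray, cluster_ids: np.ndarray, cutoff: float, min_probes: int
) -> float:
    """Largest |mean| over qualifying same-sign runs in one smoothed vector."""
    above = np.abs(sm) > cutoff
    if not above.any():
        return 0.0
    sgn = np.sign(sm)
    brk = np.ones(len(sm), dtype=bool)
    brk[1:] = (
        (cluster_ids[1:] != cluster_ids[:-1])
        | (sgn[1:] != sgn[:-1])
        | ~above[:-1]
    )
    # cumulative break count gives a distinct id per same-sign run
    ids = np.cumsum(brk)[above]
    vals = sm[above]
    lengths = np.bincount(ids)
    sums = np.bincount(ids, weights=vals)
    ok = lengths >= min_probes
    if not ok.any():
        return 0.0
    return float(np.max(np.abs(sums[ok] / lengths[ok])))


def find_bumps(
    smoothed,
    cluster_ids: np.ndarray,
    manifest: pd.DataFrame,
    cutoff: float = 0.2,
    min_probes: int = 3,
) -> pd.DataFrame:
    """Candidate regions: same-sign runs of |smoothed| > cutoff.

    Runs are maximal within a cluster; those with fewer than
    ``min_probes`` probes are discarded. Region coordinates are the first
    and last probe positions (1-based inclusive); ``value`` is the mean
    smoothed delta-beta over the run and ``area`` the sum of absolute
    smoothed values.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sm = np.asarray(smoothed, dtype=float)
    pos = manifest["pos"].to_numpy()
    chrom = manifest["chrom"].to_numpy()
    probe_ids = np.asarray(manifest.index)

    above = np.abs(sm) > cutoff
    sgn = np.sign(sm)
    rows = []
    i, n = 0, len(sm)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i + 1
        while (
            j < n
            and above[j]
            and sgn[j] == sgn[i]
            and cluster_ids[j] == cluster_ids[i]
        ):
            j += 1
        if j - i >= min_probes:
            seg = sm[i:j]
            rows.append(
                {
                    "chrom": chrom[i],
                    "start": int(pos[i]),
                    "end": int(pos[j - 1]),
                    "n_probes": j - i,
                    "value": float(seg.mean()),
                    "area": float(np.abs(seg).sum()),
                    "probe_ids": list(probe_ids[i:j]),
                }
            )
        i = j
    return pd.DataFrame(rows, columns=REGION_COLUMNS + ["probe_ids"])


def _null_contrasts(
    groups: pd.Series, B: int, rng: np.random.Generator, scheme: str
) -> np.ndarray:
    """Sample-weight matrix (n_samples x B) of label-resampled contrasts."""
    is_tumor = (groups == "tumor").to_numpy()
    n = len(is_tumor)
    n_t = int(is_tumor.sum())
    n_n = n - n_t
    w = np.empty((n, B))
    for b in range(B):
        if scheme == "permute":
            perm = rng.permutation(n)
            tumor_cols = np.zeros(n, dtype=bool)
            tumor_cols[perm[:n_t]] = True
        elif scheme == "bootstrap":
            draw = rng.integers(0, 2, size=n).astype(bool)
            # guard against single-class draws
            while draw.all() or (~draw).all():
                draw = rng.integers(0, 2, size=n).astype(bool)
            tumor_cols = draw
        else:
            raise ValueError(f"unknown null scheme {scheme!r}")
        k = int(tumor_cols.sum())
        w[:, b] = np.where(tumor_cols, 1.0 / k, -1.0 / (n - k))
    return w


def resampling_fwer(
    beta: pd.DataFrame,
    groups: pd.Series,
    manifest: pd.DataFrame,
    maxgap: int = 500,
    window: int = 3,
    cutoff: float = 0.2,
    min_probes: int = 3,
    B: int = 1000,
    seed: int = 0,
    null: str = "permute",
) -> pd.DataFrame:
    """Candidate regions with resampling family-wise error rates.

    The observed candidates are computed on the true labels; for each of
    ``B`` label-resampled null datasets the maximum qualifying region
    statistic (|mean smoothed delta-beta|) is recorded, and each
    candidate's FWER is ``(1 + #{null max >= |value|}) / (B + 1)`` — the
    add-one form keeps estimates away from zero (floor ``1/(B+1)``).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    manifest = manifest.loc[beta.index]
    cluster_ids = cluster_index(manifest, maxgap)
    groups = groups.reindex(beta.columns)

    observed = probe_level_values(beta, groups).to_numpy()
    sm = smooth_in_clusters(observed, cluster_ids, window)
    candidates = find_bumps(sm, cluster_ids, manifest, cutoff, min_probes)

    rng = np.random.default_rng(seed)
    w = _null_contrasts(groups, B, rng, null)
    null_delta = beta.to_numpy() @ w  # probes x B
    null_sm = smooth_in_clusters(null_delta, cluster_ids, window)
    null_max = np.array(
        [_max_run_stat(null_sm[:, b], cluster_ids, cutoff, min_probes)
         for b in range(B)]
    )
    fwer = np.array(
        [
            (1.0 + float((null_max >= abs(v)).sum())) / (B + 1.0)
            for v in candidates["value"]
        ]
    )
    candidates = candidates.copy()
    candidates["fwer"] = fwer
    return candidates


def significant_regions(candidates: pd.DataFrame, fwer_threshold: float = 0.01,
                        B: int | None = None) -> pd.DataFrame:
    """Filter candidates at the FWER threshold (warns near the floor)."""
    if B is not None and 1.0 / (B + 1.0) >= fwer_threshold:
        logger.warning(
            "B=%d cannot reach FWER < %g (floor %.4g)", B, fwer_threshold,
            1.0 / (B + 1.0),
        )
    return candidates[candidates["fwer"] < fwer_threshold].reset_index(drop=True)
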