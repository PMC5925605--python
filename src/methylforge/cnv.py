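"""Copy-number inference from total methylation-array intensity.

Total intensity (methylated + unmethylated) is quantile-normalized,
divided by the per-probe median over normal samples and log10-transformed,
so 0 is diploid, one-copy loss sits near log10(1/2) = -0.301 and a
one-copy gain near log10(3/2) = 0.176 at purity 1. Per sample and
chromosome the ordered log ratios are segmented by recursive binary
segmentation: the split maximizing the two-sample t statistic is accepted
when its permutation p-value clears ``alpha``, then both halves are
segmented recursively. Segments are filtered on marker count and mean log
ratio, cleaned against normal-sample segments and a blacklist, and
aggregated to recurrent intervals across tumors.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import SignalMatrix
from .preprocess import quantile_normalize

logger = logging.getLogger(__name__)

SEGMENT_COLUMNS = [
    "sample_id", "chrom", "start", "end", "n_markers", "mean_log_ratio",
]


def total_intensity(signal: SignalMatrix) -> pd.DataFrame:
    """Summed methylated + unmethylated intensity per probe and sample."""
    return signal.meth + signal.unmeth


def log_ratio(T: pd.DataFrame, normal_ids, eps: float = 1e-6) -> pd.DataFrame:
    """log10 of normalized intensity over the per-probe median of normals.

    Columns are quantile-normalized first; probes whose intensity is zero
    in every sample are excluded (flagged missing). Zero normal medians
    are floored at the smallest positive median.
    """
    normal_ids = list(normal_ids)
    if len(normal_ids) < 2:
        raise ValueError("need >= 2 normal samples")
    all_zero = (T.to_numpy() == 0).all(axis=1)
    if all_zero.any():
        logger.warning("excluding %d all-zero probe rows", int(all_zero.sum()))
        T = T.loc[~all_zero]
    qn = quantile_normalize(T)
    med = qn[normal_ids].median(axis=1).to_numpy()
    zero_med = med <= 0
    if zero_med.any():
        floor = med[med > 0].min()
        logger.warning("flooring %d zero normal medians", int(zero_med.sum()))
        med = np.where(zero_med, floor, med)
    ratio = qn.to_numpy() / med[:, None]
    return pd.DataFrame(
        np.log10(np.maximum(ratio, eps)), index=qn.index, columns=qn.columns
    )


def smooth_outliers(
    L: pd.DataFrame, manifest: pd.DataFrame, k_sd: float = 3.0
) -> pd.DataFrame:
    """Shrink isolated spikes toward their local neighborhood median.

    Per sample, a probe deviating more than ``k_sd`` sample standard
    deviations from the median of its up-to-±2-probe neighborhood (self
    excluded) is pulled back to that median ± ``k_sd * sd``, preserving
    the deviation's sign. Chromosomes with fewer than 5 probes pass
    through unchanged.
    """
    manifest = manifest.loc[L.index]
    out = L.to_numpy(dtype=float).copy()
    chroms = manifest["chrom"].to_numpy()
    sds = out.std(axis=0)
    for chrom in pd.unique(chroms):
        rows = np.flatnonzero(chroms == chrom)
        if len(rows) < 5:
            continue
        block = out[rows]
        n = len(rows)
        med = np.empty_like(block)
        for i in range(n):
            nb = np.concatenate(
                [block[max(0, i - 2):i], block[i + 1:min(n, i + 3)]]
            )
            med[i] = np.median(nb, axis=0)
        dev = block - med
        for j in range(block.shape[1]):
            limit = k_sd * sds[j]
            mask = np.abs(dev[:, j]) > limit
            block[mask, j] = med[mask, j] + np.sign(dev[mask, j]) * limit
        out[rows] = block
    return pd.DataFrame(out, index=L.index, columns=L.columns)


def _max_t_split(v: np.ndarray, min_side: int = 2) -> tuple[int, float]:
    """Best binary split of ``v`` by pooled two-sample t; returns (index, |t|).

    The split index i divides ``v`` into ``v[:i]`` and ``v[i:]``.
    """
    n = len(v)
    if n < 2 * min_side:
        return -1, 0.0
    s = np.cumsum(v)
    q = np.cumsum(v**2)
    i = np.arange(min_side, n - min_side + 1)
    n1 = i.astype(float)
    n2 = n - n1
    s1 = s[i - 1]
    s2 = s[-1] - s1
    ss1 = q[i - 1] - s1**2 / n1
    ss2 = (q[-1] - q[i - 1]) - s2**2 / n2
    diff = s1 / n1 - s2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled = np.maximum(ss1 + ss2, 0.0) / max(n - 2, 1)
        t = np.abs(diff) / np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    t = np.where(np.isnan(t), np.where(diff == 0, 0.0, np.inf), t)
    best = int(np.argmax(t))
    return int(i[best]), float(t[best])


def _arc_lengths(n: int, min_side: int = 2, exact_below: int = 256,
                 ratio: float = 1.25) -> np.ndarray:
    """Arc lengths scanned by the circular statistic.

    Exhaustive for short intervals; a geometric ladder above
    ``exact_below`` keeps the scan near-linear while retaining power for
    segments of any length (a true segment is covered by a nearby ladder
    length). The same ladder is used for observed and permuted data, so
    the permutation test remains valid for the ladder-max statistic.
    """
    lo, hi = min_side, n - min_side
    if hi < lo:
        return np.array([], dtype=int)
    if n <= exact_below:
        return np.arange(lo, hi + 1)
    lengths = []
    m = lo
    while m < hi:
        lengths.append(m)
        m = max(m + 1, int(m * ratio))
    lengths.append(hi)
    return np.array(sorted(set(lengths)), dtype=int)


def _arc_t_matrix(s: np.ndarray, q: np.ndarray, m: int, n: int) -> np.ndarray:
    """|t| of every length-``m`` arc vs its complement; rows = replicates.

    ``s`` and ``q`` are cumulative sums / sums of squares with a leading
    zero column, shape (replicates, n + 1).
    """
    sw = s[:, m:] - s[:, :-m]
    qw = q[:, m:] - q[:, :-m]
    stot = s[:, -1][:, None]
    qtot = q[:, -1][:, None]
    n2 = n - m
    ss_in = qw - sw**2 / m
    ss_out = (qtot - qw) - (stot - sw) ** 2 / n2
    diff = sw / m - (stot - sw) / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled = np.maximum(ss_in + ss_out, 0.0) / max(n - 2, 1)
        t = np.abs(diff) / np.sqrt(pooled * (1.0 / m + 1.0 / n2))
    return np.where(np.isnan(t), np.where(diff == 0, 0.0, np.inf), t)


def _max_arc_t(v: np.ndarray, min_side: int = 2,
               lengths: np.ndarray | None = None) -> tuple[int, int, float]:
    """Best arc (i, j, |t|) over the scanned lengths (two change points)."""
    n = len(v)
    if lengths is None:
        lengths = _arc_lengths(n, min_side)
    s = np.concatenate([[0.0], np.cumsum(v)])[None, :]
    q = np.concatenate([[0.0], np.cumsum(v**2)])[None, :]
    best = (-1, -1, 0.0)
    for m in lengths:
        t = _arc_t_matrix(s, q, int(m), n)[0]
        k = int(np.argmax(t))
        if t[k] > best[2]:
            best = (k, k + int(m), float(t[k]))
    return best


def _refine_arc(v: np.ndarray, i: int, j: int, min_side: int,
                radius: int = 8) -> tuple[int, int]:
    """Locally maximize the arc t over boundaries within ``radius`` probes."""
    n = len(v)
    s = np.concatenate([[0.0], np.cumsum(v)])
    q = np.concatenate([[0.0], np.cumsum(v**2)])
    best_t, best = -1.0, (i, j)
    for ii in range(max(0, i - radius), min(j - 1, i + radius) + 1):
        for jj in range(max(ii + min_side, j - radius), min(n, j + radius) + 1):
            m = jj - ii
            if m < min_side or n - m < min_side:
                continue
            sw = s[jj] - s[ii]
            qw = q[jj] - q[ii]
            ss_in = qw - sw**2 / m
            ss_out = (q[-1] - qw) - (s[-1] - sw) ** 2 / (n - m)
            diff = sw / m - (s[-1] - sw) / (n - m)
            pooled = max(ss_in + ss_out, 0.0) / max(n - 2, 1)
            if pooled == 0:
                t = np.inf if diff != 0 else 0.0
            else:
                t = abs(diff) / np.sqrt(pooled * (1.0 / m + 1.0 / (n - m)))
            if t > best_t:
                best_t, best = t, (ii, jj)
    return best


def _perm_max_t(
    v: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    min_side: int = 2,
    circular: bool = True,
    stop_count: float | None = None,
    t_obs: float | None = None,
) -> np.ndarray:
    """Max statistic of ``n_perm`` within-interval shuffles of ``v``.

    When ``stop_count`` and ``t_obs`` are given, the loop stops early once
    more than ``stop_count`` null maxima have reached ``t_obs`` — the
    permutation p-value is then guaranteed to exceed the significance
    level, so the decision cannot change (the returned array is shorter).
    """
    n = len(v)
    out = np.empty(n_perm)
    lengths = _arc_lengths(n, min_side) if circular else None
    chunk = max(1, int(4_000_000 // max(n, 1)))
    done = 0
    exceed = 0
    first = stop_count is not None  # small pilot chunk enables early exit
    while done < n_perm:
        b = min(16 if first else chunk, n_perm - done)
        first = False
        keys = rng.random((b, n))
        perm = np.take_along_axis(
            np.broadcast_to(v, (b, n)).copy(), np.argsort(keys, axis=1), axis=1
        )
        s = np.concatenate(
            [np.zeros((b, 1)), np.cumsum(perm, axis=1)], axis=1
        )
        q = np.concatenate(
            [np.zeros((b, 1)), np.cumsum(perm**2, axis=1)], axis=1
        )
        if circular:
            mx = np.zeros(b)
            for m in lengths:
                t = _arc_t_matrix(s, q, int(m), n)
                mx = np.maximum(mx, t.max(axis=1))
        else:
            i = np.arange(min_side, n - min_side + 1)
            n1 = i.astype(float)
            n2 = n - n1
            s1 = s[:, i]
            s2 = s[:, -1][:, None] - s1
            ss1 = q[:, i] - s1**2 / n1
            ss2 = (q[:, -1][:, None] - q[:, i]) - s2**2 / n2
            diff = s1 / n1 - s2 / n2
            with np.errstate(divide="ignore", invalid="ignore"):
                pooled = np.maximum(ss1 + ss2, 0.0) / max(n - 2, 1)
                t = np.abs(diff) / np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
            t = np.where(np.isnan(t), np.where(diff == 0, 0.0, np.inf), t)
            mx = t.max(axis=1)
        out[done:done + b] = mx
        done += b
        if stop_count is not None and t_obs is not None:
            exceed += int((mx >= t_obs).sum())
            if exceed > stop_count:
                return out[:done]
    return out


def segment(
    values,
    alpha: float = 0.01,
    n_perm: int = 10_000,
    seed: int = 0,
    min_side: int = 2,
    circular: bool = True,
) -> list[int]:
    """Recursive segmentation of an ordered log-ratio vector.

    With ``circular=True`` (default) each interval is scanned for the arc
    (two change points) maximizing the pooled two-sample t statistic
    between inside and outside means — the scan that gives power for
    short interior segments on long chromosomes; ``circular=False``
    restricts to single binary splits. The best statistic is tested by
    permutation (``n_perm`` shuffles of the interval, re-maximizing each
    time with the identical scan) and accepted when
    ``(1 + #{perm max >= observed}) / (n_perm + 1) < alpha``; accepted
    change points split the interval and the parts are segmented
    recursively. Returns sorted change-point indices (each the first
    index of a new segment).
    """
    v = np.asarray(values, dtype=float)
    if n_perm >= 1 and n_perm + 1 <= 1.0 / alpha:
        logger.warning(
            "n_perm=%d cannot reach p < %g (floor %.3g)",
            n_perm, alpha, 1.0 / (n_perm + 1),
        )
    rng = np.random.default_rng(seed)
    changepoints: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        seg = v[lo:hi]
        n = len(seg)
        if n < 2 * min_side or np.ptp(seg) == 0:
            return
        if circular:
            i, j, t_obs = _max_arc_t(seg, min_side)
        else:
            split, t_obs = _max_t_split(seg, min_side)
            i, j = split, n
        if i < 0 or t_obs == 0.0:
            return
        stop_count = alpha * (n_perm + 1.0) - 1.0
        null_max = _perm_max_t(
            seg, n_perm, rng, min_side, circular,
            stop_count=stop_count, t_obs=t_obs,
        )
        exceed = float((null_max >= t_obs).sum())
        if len(null_max) < n_perm:  # stopped early: p >= alpha guaranteed
            return
        p = (1.0 + exceed) / (n_perm + 1.0)
        if p >= alpha:
            return
        if circular:
            i, j = _refine_arc(seg, i, j, min_side)
        cuts = sorted({c for c in (i, j) if 0 < c < n})
        for c in cuts:
            changepoints.append(lo + c)
        bounds = [lo, *[lo + c for c in cuts], hi]
        for a, b in zip(bounds[:-1], bounds[1:]):
            recurse(a, b)

    recurse(0, len(v))
    return sorted(changepoints)


def segment_matrix(
    L: pd.DataFrame,
    manifest: pd.DataFrame,
    alpha: float = 0.01,
    n_perm: int = 10_000,
    seed: int = 0,
    sample_ids=None,
    circular: bool = True,
) -> pd.DataFrame:
    """Segment every (sample, chromosome) track of a log-ratio matrix.

    Returns one row per segment with marker count, mean log ratio and
    1-based inclusive coordinates taken from the first/last probe.
    """
    manifest = manifest.loc[L.index]
    chroms = manifest["chrom"].to_numpy()
    pos = manifest["pos"].to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    columns = list(L.columns if sample_ids is None else sample_ids)
    for sid in columns:
        col = L[sid].to_numpy(dtype=float)
        for chrom in pd.unique(chroms):
            ilocs = np.flatnonzero(chroms == chrom)
            v = col[ilocs]
            cps = segment(
                v, alpha=alpha, n_perm=n_perm,
                seed=int(rng.integers(0, 2**31 - 1)), circular=circular,
            )
            bounds = [0, *cps, len(v)]
            for a, b in zip(bounds[:-1], bounds[1:]):
                rows.append(
                    {
                        "sample_id": sid,
                        "chrom": chrom,
                        "start": int(pos[ilocs[a]]),
                        "end": int(pos[ilocs[b - 1]]),
                        "n_markers": b - a,
                        "mean_log_ratio": float(v[a:b].mean()),
                    }
                )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def call_segments(
    segments: pd.DataFrame,
    min_markers: int = 5,
    gain_cut: float = 0.2,
    loss_cut: float = -0.3,
) -> pd.DataFrame:
    """Keep segments with enough markers and a gain/loss mean log ratio.

    A gain requires mean log ratio > ``gain_cut`` (0.2 ~ at least one
    copy amplification) and a loss mean < ``loss_cut`` (-0.3 ~ one-copy
    deletion); the asymmetry reflects the log scale of copy ratios.
    """
    ok = segments["n_markers"] >= min_markers
    mean = segments["mean_log_ratio"]
    gain = mean > gain_cut
    loss = mean < loss_cut
    out = segments[ok & (gain | loss)].copy()
    out["direction"] = np.where(out["mean_log_ratio"] > gain_cut, "gain", "loss")
    return out.reset_index(drop=True)


def _overlap_bp(s1: int, e1: int, s2: int, e2: int) -> int:
    return max(0, min(e1, e2) - max(s1, s2) + 1)


def filter_shared_and_blacklist(
    tumor_segs: pd.DataFrame,
    normal_segs: pd.DataFrame,
    blacklist: list[tuple[str, int, int]] | None = None,
    shared_frac: float = 0.5,
) -> pd.DataFrame:
    """Drop tumor segments mirrored in normals or hitting the blacklist.

    A tumor segment is discarded when a same-direction normal-sample
    segment covers at least ``shared_frac`` of its length, or when it
    overlaps any blacklist interval by >= 1 bp (e.g. regions of known
    germline copy-number polymorphism).
    """
    blacklist = blacklist or []
    keep = []
    for _, seg in tumor_segs.iterrows():
        length = seg["end"] - seg["start"] + 1
        shared = False
        for _, nseg in normal_segs.iterrows():
            if nseg["chrom"] != seg["chrom"] or nseg["direction"] != seg["direction"]:
                continue
            ov = _overlap_bp(seg["start"], seg["end"], nseg["start"], nseg["end"])
            if ov >= shared_frac * length:
                shared = True
                break
        banned = any(
            chrom == seg["chrom"] and _overlap_bp(seg["start"], seg["end"], s, e) >= 1
            for chrom, s, e in blacklist
        )
        if not shared and not banned:
            keep.append(seg)
    return pd.DataFrame(keep, columns=list(tumor_segs.columns)).reset_index(drop=True)


def recurrent_segments(segs: pd.DataFrame, min_samples: int = 2) -> pd.DataFrame:
    """Maximal intervals covered by >= ``min_samples`` distinct tumors.

    Per chromosome and direction, a breakpoint sweep counts how many
    samples' segments cover each sub-interval; maximal runs with coverage
    at or above ``min_samples`` are reported with their peak support.
    """
    if min_samples < 2:
        raise ValueError("min_samples must be >= 2")
    rows = []
    for (chrom, direction), sub in segs.groupby(["chrom", "direction"]):
        events = []
        for _, seg in sub.iterrows():
            events.append((int(seg["start"]), 1))
            events.append((int(seg["end"]) + 1, -1))
        events.sort()
        bounds = sorted({p for p, _ in events})
        cov = 0
        cov_at = {}
        ei = 0
        for p in bounds:
            while ei < len(events) and events[ei][0] == p:
                cov += events[ei][1]
                ei += 1
            cov_at[p] = cov
        run_start, run_support = None, 0
        for k, p in enumerate(bounds):
            c = cov_at[p]
            nxt = bounds[k + 1] - 1 if k + 1 < len(bounds) else p
            if c >= min_samples:
                if run_start is None:
                    run_start = p
                run_support = max(run_support, c)
                run_end = nxt
            elif run_start is not None:
                rows.append(
                    {"chrom": chrom, "start": run_start, "end": run_end,
                     "direction": direction, "support": run_support}
                )
                run_start, run_support = None, 0
        if run_start is not None:
            rows.append(
                {"chrom": chrom, "start": run_start, "end": run_end,
                 "direction": direction, "support": run_support}
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "direction", "support"]
    )


def overlap_dmrs(cnvs: pd.DataFrame, dmrs: pd.DataFrame) -> pd.DataFrame:
    """Join recurrent CNVs with overlapping DMRs (>= 1 bp, inclusive).

    The concordance flag marks copy-gained regions that are also
    hypermethylated (positive DMR delta-beta).
    """
    rows = []
    for _, cnv in cnvs.iterrows():
        for _, d in dmrs.iterrows():
            if d["chrom"] != cnv["chrom"]:
                continue
            ov = _overlap_bp(cnv["start"], cnv["end"], d["start"], d["end"])
            if ov < 1:
                continue
            rows.append(
                {
                    "chrom": cnv["chrom"],
                    "cnv_start": cnv["start"], "cnv_end": cnv["end"],
                    "direction": cnv["direction"], "support": cnv.get("support"),
                    "dmr_start": d["start"], "dmr_end": d["end"],
                    "dmr_value": d["value"], "overlap_bp": ov,
                    "hyper_concordant": bool(
                        cnv["direction"] == "gain" and d["value"] > 0
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "cnv_start", "cnv_end", "direction", "support",
            "dmr_start", "dmr_end", "dmr_value", "overlap_bp",
            "hyper_concordant",
        ],
    )
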