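"""Per-probe differential methylation against tumor cellularity.

Each probe's M-values are regressed on a single continuous covariate —
the specimen's tumor-cell fraction (normals enter at 0) — so the slope
measures the methylation change per unit cellularity. Residual variances
are shrunk toward a scaled inverse-chi-square prior fitted to all probes
by moment matching on the log scale, yielding a moderated t statistic
with ``d0 + df`` degrees of freedom. Calls combine a Bonferroni-corrected
p-value with a group-mean beta difference (delta-beta) cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import digamma, polygamma
from scipy.stats import pearsonr
from scipy.stats import t as t_dist
from sklearn.metrics import adjusted_rand_score

DMP_COLUMNS = [
    "slope", "sigma2", "df_resid", "se_unit",
    "t_mod", "p_raw", "p_adj", "delta_beta", "significant",
]


@dataclass
class ModerationPrior:
    """Hyperparameters of the scaled inverse-chi-square variance prior."""

    d0: float  # prior degrees of freedom; may be inf
    s0_sq: float  # prior variance

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("d0 must be positive")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be positive")


def fit_probe_regressions(M: pd.DataFrame, x) -> pd.DataFrame:
    """Ordinary least squares of every probe's M-values on intercept + x.

    Returns a frame with ``slope``, ``sigma2`` (= RSS / (n - 2)),
    ``df_resid`` and ``se_unit`` (the unit standard error
    ``1 / sqrt(sum((x - mean x)^2))``, so that
    ``se(slope) = sqrt(sigma2) * se_unit``).
    """
    x = np.asarray(x, dtype=float)
    if len(x) != M.shape[1]:
        raise ValueError("x length must match number of samples")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate: design not estimable")
    values = M.to_numpy(dtype=float)
    n = len(x)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    yc = values - values.mean(axis=1, keepdims=True)
    slope = (yc @ xc) / sxx
    rss = (yc**2).sum(axis=1) - slope**2 * sxx
    df_resid = n - 2
    if df_resid <= 0:
        raise ValueError("need at least 3 samples")
    sigma2 = np.maximum(rss, 0.0) / df_resid
    return pd.DataFrame(
        {
            "slope": slope,
            "sigma2": sigma2,
            "df_resid": df_resid,
            "se_unit": 1.0 / np.sqrt(sxx),
        },
        index=M.index,
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def estimate_prior(sigma2, df_resid: int, var_floor_quantile: float = 0.01
                   ) -> ModerationPrior:
    """Moment-matching fit of the variance prior on the log scale.

    Under the scaled inverse-chi-square model, ``log(s^2)`` has mean
    ``log(s0^2) + digamma(df/2) - log(df/2)`` plus a prior-driven spread;
    matching the sample mean and variance of ``log(s^2)`` (via digamma /
    trigamma) gives ``s0^2`` and ``d0``, with ``d0 = inf`` when the
    observed spread does not exceed the pure chi-square contribution.
    Zero variances are floored at the ``var_floor_quantile`` quantile of
    the positive ones.
    """
    s2 = np.asarray(sigma2, dtype=float).copy()
    if len(s2) < 10:
        raise ValueError("need >= 10 probes to fit the prior")
    positive = s2[s2 > 0]
    if len(positive) == 0:
        raise ValueError("all variances are zero")
    floor = float(np.quantile(positive, var_floor_quantile))
    s2[s2 <= 0] = floor

    if np.ptp(s2) == 0:  # degenerate: a point-mass prior
        return ModerationPrior(d0=np.inf, s0_sq=float(s2[0]))

    df = float(df_resid)
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(np.mean(e) + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(np.mean(e)))
    return ModerationPrior(d0=d0, s0_sq=s0_sq)


def moderated_t(fits: pd.DataFrame, prior: ModerationPrior) -> pd.DataFrame:
    """Moderated t and two-sided p per probe.

    Posterior variance ``(d0*s0^2 + df*s^2) / (d0 + df)``; the statistic
    is referred to a t distribution on ``d0 + df`` degrees of freedom
    (large-df t when ``d0`` is infinite). ``d0 = 0`` reduces to the
    ordinary t test.
    """
    df = fits["df_resid"].to_numpy(dtype=float)
    s2 = fits["sigma2"].to_numpy(dtype=float)
    slope = fits["slope"].to_numpy(dtype=float)
    se_unit = fits["se_unit"].to_numpy(dtype=float)
    if np.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = np.full_like(df, 1e9)
    else:
        s2_post = (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)
        df_total = prior.d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = slope / (np.sqrt(s2_post) * se_unit)
    t_mod = np.nan_to_num(t_mod, nan=0.0, posinf=np.inf, neginf=-np.inf)
    p_raw = 2.0 * t_dist.sf(np.abs(t_mod), df_total)
    out = fits.copy()
    out["t_mod"] = t_mod
    out["p_raw"] = p_raw
    return out


def delta_beta(beta: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Group-mean beta difference, tumor minus normal, per probe."""
    groups = groups.reindex(beta.columns)
    tumor = beta.loc[:, (groups == "tumor").to_numpy()]
    normal = beta.loc[:, (groups == "normal").to_numpy()]
    if tumor.shape[1] == 0 or normal.shape[1] == 0:
        raise ValueError("both tumor and normal samples are required")
    return tumor.mean(axis=1) - normal.mean(axis=1)


def call_dmps(
    stats: pd.DataFrame,
    beta: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.01,
    delta: float = 0.2,
) -> pd.DataFrame:
    """Bonferroni-corrected significance calls with an effect-size gate.

    A probe is significant when the Bonferroni-adjusted p-value (over the
    tested probe set) is below ``alpha`` and the absolute group-mean beta
    difference exceeds ``delta``. Sorted by adjusted p, then |delta-beta|
    descending, then probe id.
    """
    if not (0 < alpha < 1 and 0 < delta < 1):
        raise ValueError("alpha and delta must lie in (0, 1)")
    db = delta_beta(beta.loc[stats.index], groups)
    n_tested = len(stats)
    out = stats.copy()
    out["p_adj"] = np.minimum(1.0, out["p_raw"] * n_tested)
    out["delta_beta"] = db
    out["significant"] = (out["p_adj"] < alpha) & (out["delta_beta"].abs() > delta)
    # deterministic order: p_adj asc, |delta_beta| desc, probe id asc
    out = (
        out.rename_axis("probe_id")
        .assign(_absdb=out["delta_beta"].abs())
        .sort_values(["p_adj", "_absdb", "probe_id"],
                     ascending=[True, False, True], kind="mergesort")
        .drop(columns="_absdb")
    )
    return out[DMP_COLUMNS]


def profile_correlation(beta: pd.DataFrame, dmp_ids, x) -> float:
    """Pearson r between per-sample mean beta over ``dmp_ids`` and x.

    Returns NaN (flagged missing) when either vector has zero variance.
    """
    dmp_ids = list(dmp_ids)
    if len(dmp_ids) == 0:
        raise ValueError("need >= 1 probe")
    x = np.asarray(x, dtype=float)
    if beta.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    profile = beta.loc[dmp_ids].mean(axis=0).to_numpy()
    if np.ptp(profile) == 0 or np.ptp(x) == 0:
        return float("nan")
    return float(pearsonr(profile, x)[0])


def cluster_samples(beta_sig: pd.DataFrame, groups: pd.Series
                    ) -> tuple[pd.Series, float]:
    """Two-group agglomerative clustering of samples on significant probes.

    Complete linkage on Euclidean distances between sample beta profiles,
    cut at two clusters; agreement with the true labels is the adjusted
    Rand index.
    """
    if beta_sig.shape[0] < 2:
        raise ValueError("need >= 2 significant probes")
    groups = groups.reindex(beta_sig.columns)
    if min((groups == "tumor").sum(), (groups == "normal").sum()) < 2:
        raise ValueError("need >= 2 samples per group")
    z = linkage(beta_sig.to_numpy().T, method="complete", metric="euclidean")
    labels = fcluster(z, t=2, criterion="maxclust")
    partition = pd.Series(labels, index=beta_sig.columns, name="cluster")
    score = float(adjusted_rand_score(groups.to_numpy(), labels))
    return partition, score
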