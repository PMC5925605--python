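"""Minimal CpG diagnostic panel via L1-regularized logistic regression.

Feature selection proceeds in three stages over the significant probes:
(1) exclusion of probes inside recurrent copy-number intervals (their
beta values confound methylation with dosage), (2) retention of fully
differentiating probes (rank AUC of exactly 1, in either direction),
(3) greedy redundancy pruning at an R-squared cutoff. The surviving
probes enter a LASSO-penalized logistic regression fitted by cyclic
coordinate descent on an iteratively reweighted least-squares
approximation, with the penalty weight chosen by repeated stratified
cross-validation. Scores are probabilities in (0, 1); a sample is called
a tumor when its score strictly exceeds the threshold (default 0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

_W_FLOOR = 1e-5


def _as_binary(labels) -> np.ndarray:
    """Coerce labels to a boolean tumor mask ('tumor'/'normal' or 0/1)."""
    arr = np.asarray(labels)
    if arr.dtype.kind in ("U", "S", "O"):
        return arr == "tumor"
    return arr.astype(bool)


@dataclass
class PanelModel:
    """A fitted CpG panel: probes, coefficients (beta scale), and metadata."""

    probe_ids: list[str]
    intercept: float
    coefficients: list[float]
    lambda_: float
    standardization: dict[str, tuple[float, float]]  # probe -> (mean, sd)
    threshold: float = 0.5
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.probe_ids) != len(self.coefficients):
            raise ValueError("one coefficient per probe required")

    def to_dict(self) -> dict:
        return {
            "probe_ids": self.probe_ids,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "lambda": self.lambda_,
            "standardization": {k: list(v) for k, v in self.standardization.items()},
            "threshold": self.threshold,
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PanelModel":
        return cls(
            probe_ids=list(d["probe_ids"]),
            intercept=float(d["intercept"]),
            coefficients=[float(c) for c in d["coefficients"]],
            lambda_=float(d["lambda"]),
            standardization={k: tuple(v) for k, v in d["standardization"].items()},
            threshold=float(d.get("threshold", 0.5)),
            meta=d.get("meta", {}),
        )


def probe_auc(values, labels, two_sided: bool = False) -> float:
    """Rank-statistic AUC: P(tumor value > normal value), ties count 0.5.

    With ``two_sided=True`` the orientation-agnostic ``max(a, 1 - a)`` is
    returned, so probes that separate perfectly in either direction score
    1.0.
    """
    v = np.asarray(values, dtype=float)
    y = _as_binary(labels)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(v, method="average")
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n0)
    return float(max(auc, 1.0 - auc)) if two_sided else float(auc)


def lasso_objective(X_std: np.ndarray, y: np.ndarray, b0: float,
                    coef: np.ndarray, lam: float) -> float:
    """Penalized deviance (standardized scale): mean NLL + lam * ||coef||_1."""
    eta = b0 + X_std @ coef
    nll = np.mean(np.logaddexp(0.0, eta) - y * eta)
    return float(nll + lam * np.abs(coef).sum())


def lambda_max(X_std: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which every coefficient is zero."""
    ybar = y.mean()
    return float(np.max(np.abs(X_std.T @ (y - ybar))) / len(y))


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance columns", int((~keep).sum()))
    Xs = (X[:, keep] - mean[keep]) / sd[keep]
    return Xs, mean, sd, keep


def _fit_std(
    Xs: np.ndarray,
    y: np.ndarray,
    lam: float,
    max_iter: int = 200,
    tol: float = 1e-7,
    coef_init: np.ndarray | None = None,
    dev_stop: float = 1e-3,
) -> tuple[float, np.ndarray]:
    """Core coordinate-descent solver on pre-standardized columns.

    Returns ``(intercept, coefficients)`` on the standardized scale;
    raises when the IRLS outer loop fails to converge. Two practical
    devices keep separable problems tractable: sweeps cycle over the
    active (nonzero) set between full KKT-checking passes, and the fit
    stops once 99.9% of the null deviance is explained (coefficients are
    then on the separation ray and further growth cannot change any
    classification).
    """
    n, pk = Xs.shape
    b = np.zeros(pk) if coef_init is None else coef_init.copy()
    ybar = y.mean()
    b0 = float(logit(min(max(ybar, 1e-12), 1 - 1e-12)))
    eta = np.clip(b0 + Xs @ b, -30.0, 30.0)
    null_dev = -2.0 * n * (ybar * np.log(max(ybar, 1e-12))
                           + (1 - ybar) * np.log(max(1 - ybar, 1e-12)))

    converged = False
    for _ in range(max_iter):
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), _W_FLOOR)
        z = eta + (y - mu) / w
        # coordinate descent on the weighted quadratic approximation,
        # with the weighted Gram matrix precomputed so each coordinate
        # update is O(p) (covariance updates)
        H = (Xs * w[:, None]).T @ Xs / n
        hdiag = np.diag(H).copy()
        h0 = Xs.T @ w / n
        wsum = float(w.sum())
        r = z - b0 - Xs @ b
        u = Xs.T @ (w * r) / n
        swr = float((w * r).sum())

        def update(j):
            nonlocal swr
            rho = u[j] + hdiag[j] * b[j]
            new = np.sign(rho) * max(abs(rho) - lam, 0.0) / hdiag[j]
            d = new - b[j]
            if d != 0.0:
                u[:] -= H[:, j] * d
                swr -= n * h0[j] * d
                b[j] = new
            return abs(d)

        def update_b0():
            nonlocal b0, swr
            d = swr / wsum
            if d != 0.0:
                b0 += d
                u[:] -= h0 * d
                swr -= wsum * d
            return abs(d)

        delta_full = np.inf
        for _pass in range(200):
            delta_full = max((update(j) for j in range(pk)), default=0.0)
            delta_full = max(delta_full, update_b0())
            if delta_full < tol:
                break
            for _inner in range(200):
                active = np.flatnonzero(b)
                delta = max((update(j) for j in active), default=0.0)
                delta = max(delta, update_b0())
                if delta < tol:
                    break

        new_eta = np.clip(b0 + Xs @ b, -30.0, 30.0)
        mu_new = expit(new_eta)
        dev = -2.0 * float(
            y @ np.log(np.maximum(mu_new, 1e-12))
            + (1 - y) @ np.log(np.maximum(1 - mu_new, 1e-12))
        )
        if np.max(np.abs(new_eta - eta)) < tol * 10 or (
            null_dev > 0 and dev / null_dev < dev_stop
        ):
            eta = new_eta
            converged = True
            break
        eta = new_eta
    if not converged:
        raise RuntimeError(
            f"coordinate descent did not converge in {max_iter} IRLS steps "
            f"(lam={lam:.4g}, p={pk})"
        )
    return b0, b


def lasso_logistic_fit(
    X,
    y,
    lam: float,
    max_iter: int = 200,
    tol: float = 1e-7,
    probe_ids=None,
):
    """Coordinate-descent fit of the L1-penalized logistic regression.

    Minimizes ``(1/n) * sum(logistic deviance) + lam * sum(|coef|)`` on
    internally standardized columns (intercept unpenalized): each outer
    iteration forms the IRLS quadratic approximation at the current
    linear predictor, and cyclic soft-thresholding updates solve the
    penalized weighted least squares until the largest coefficient change
    falls below ``tol``. Coefficients are returned on the input scale.
    """
    if isinstance(X, pd.DataFrame):
        probe_ids = list(X.columns) if probe_ids is None else probe_ids
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    n, p = X.shape
    Xs, mean, sd, keep = _standardize(X)
    b0, b = _fit_std(Xs, y, lam, max_iter, tol)

    # back-transform to the input (beta-value) scale
    coef = np.zeros(p)
    coef[keep] = b / sd[keep]
    intercept = b0 - float((b * mean[keep] / sd[keep]).sum())
    if probe_ids is None:
        probe_ids = [f"x{j}" for j in range(p)]
    standardization = {
        pid: (float(m), float(s)) for pid, m, s in zip(probe_ids, mean, sd)
    }
    return PanelModel(
        probe_ids=list(probe_ids),
        intercept=float(intercept),
        coefficients=coef.tolist(),
        lambda_=float(lam),
        standardization=standardization,
    )


def default_lambda_grid(X, y, n_values: int = 50, decades: float = 3.0) -> np.ndarray:
    """Log-spaced grid from lambda_max down ``decades`` orders of magnitude."""
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    Xs, *_ = _standardize(np.asarray(X, dtype=float))
    lmax = lambda_max(Xs, np.asarray(y, dtype=float))
    return np.logspace(np.log10(lmax), np.log10(lmax) - decades, n_values)


def select_lambda(
    X,
    y,
    n_rep: int = 25,
    n_folds: int = 5,
    lambda_grid=None,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Choose the penalty by repeated stratified k-fold cross-validation.

    Misclassification at threshold 0.5 is averaged over all held-out
    predictions across ``n_rep`` re-randomized fold assignments; the
    largest lambda attaining the minimum mean error wins (parsimony
    tie-break). Returns ``(lambda, cv_table)``.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if isinstance(X, pd.DataFrame):
        Xarr = X.to_numpy(dtype=float)
    else:
        Xarr = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    grid = (
        np.asarray(sorted(lambda_grid, reverse=True), dtype=float)
        if lambda_grid is not None
        else default_lambda_grid(Xarr, y)
    )
    min_class = int(min((y == 0).sum(), (y == 1).sum()))
    folds = min(n_folds, min_class)
    if folds < n_folds:
        logger.warning("reducing folds to %d (smallest class size)", folds)
    if folds < 2:
        raise ValueError("each class needs >= 2 samples for cross-validation")

    errors = np.zeros((n_rep, len(grid)))
    counts = np.zeros((n_rep, len(grid)))
    rng = np.random.default_rng(seed)
    for rep in range(n_rep):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        for train_idx, test_idx in skf.split(Xarr, y):
            if len(np.unique(y[train_idx])) < 2:  # pragma: no cover
                continue
            Xs, mean, sd, keep = _standardize(Xarr[train_idx])
            Xt = (Xarr[test_idx][:, keep] - mean[keep]) / sd[keep]
            y_tr = y[train_idx]
            warm = None
            # descending lambda path with warm starts; the loose tolerance
            # is ample for held-out misclassification counts
            for gi, lam in enumerate(grid):
                b0, b = _fit_std(Xs, y_tr, lam, coef_init=warm, tol=1e-4,
                                 dev_stop=0.05)
                warm = b
                scores = expit(b0 + Xt @ b)
                pred = (scores > 0.5).astype(float)
                errors[rep, gi] += float((pred != y[test_idx]).sum())
                counts[rep, gi] += len(test_idx)
    mean_err = errors.sum(axis=0) / counts.sum(axis=0)
    best = mean_err.min()
    # grid is descending: first index at the minimum is the largest lambda
    chosen = float(grid[int(np.argmax(mean_err == best))])
    table = pd.DataFrame({"lambda": grid, "cv_error": mean_err})
    return chosen, table


def predict_scores_array(model: PanelModel, X: np.ndarray) -> np.ndarray:
    eta = model.intercept + X @ np.asarray(model.coefficients)
    return expit(eta)


def predict_scores(model: PanelModel, beta: pd.DataFrame) -> pd.DataFrame:
    """Probability scores and tumor/normal calls for each sample.

    ``beta`` is a probe-by-sample matrix; every panel probe must be
    present (a missing probe raises, naming it). A sample is called tumor
    when its score strictly exceeds the model threshold.
    """
    missing = [p for p in model.probe_ids if p not in beta.index]
    if missing:
        raise KeyError(f"panel probes missing from beta matrix: {missing}")
    sub = beta.loc[model.probe_ids]
    vals = sub.to_numpy(dtype=float)
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("beta values out of [0, 1]")
    scores = predict_scores_array(model, vals.T)
    return pd.DataFrame(
        {
            "score": scores,
            "call": np.where(scores > model.threshold, "tumor", "normal"),
        },
        index=beta.columns,
    )


def select_features(
    dmps: pd.DataFrame,
    cnv_regions: pd.DataFrame,
    beta: pd.DataFrame,
    labels,
    manifest: pd.DataFrame,
    auc_keep: float = 1.0,
    r2_cut: float = 0.9,
) -> list[str]:
    """Three-stage candidate selection for the panel.

    1. significant probes outside every recurrent CNV interval;
    2. fully differentiating probes (two-sided rank AUC equal to
       ``auc_keep``, default exactly 1.00);
    3. greedy redundancy pruning in descending |delta-beta| order (ties
       by probe id): a probe is kept only if its squared Pearson
       correlation with every kept probe is <= ``r2_cut``.
    """
    if len(dmps) == 0:
        raise ValueError("empty DMP table")
    sig = dmps[dmps["significant"]]
    if len(sig) == 0:
        raise ValueError("feature selection stage 1: no significant probes")

    pos = manifest.loc[sig.index, ["chrom", "pos"]]
    inside = np.zeros(len(sig), dtype=bool)
    for _, seg in cnv_regions.iterrows():
        hit = (
            (pos["chrom"] == seg["chrom"])
            & (pos["pos"] >= seg["start"])
            & (pos["pos"] <= seg["end"])
        ).to_numpy()
        inside |= hit
    stage1 = sig.index[~inside]
    if len(stage1) == 0:
        raise ValueError("feature selection stage 1: all probes inside CNVs")

    y = _as_binary(labels)
    stage2 = [
        pid
        for pid in stage1
        if abs(probe_auc(beta.loc[pid].to_numpy(), y, two_sided=True) - auc_keep)
        < 1e-12
    ]
    if len(stage2) == 0:
        raise ValueError("feature selection stage 2: no fully differentiating probes")

    order = (
        dmps.loc[stage2, "delta_beta"]
        .abs()
        .rename("absdb")
        .reset_index()
        .sort_values(["absdb", "probe_id"], ascending=[False, True], kind="mergesort")
        ["probe_id"]
        .tolist()
    )
    kept: list[str] = []
    for pid in order:
        v = beta.loc[pid].to_numpy(dtype=float)
        redundant = False
        for kpid in kept:
            r = np.corrcoef(v, beta.loc[kpid].to_numpy(dtype=float))[0, 1]
            if r * r > r2_cut:
                redundant = True
                break
        if not redundant:
            kept.append(pid)
    if len(kept) == 0:  # pragma: no cover - pruning always keeps the first probe
        raise ValueError("feature selection stage 3: all probes pruned")
    return kept


def evaluate(scores, true_labels, threshold: float = 0.5) -> dict:
    """Confusion counts and the four performance metrics at a threshold.

    Sensitivity = TP / (TP + FN) over tumors, specificity = TN / (TN + FP)
    over non-tumors, accuracy over all samples, and rank AUC of the
    scores. Metrics are NaN-flagged when a class is absent.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(true_labels)
    pred = s > threshold
    tp = int((pred & y).sum())
    fn = int((~pred & y).sum())
    tn = int((~pred & ~y).sum())
    fp = int((pred & ~y).sum())
    n1, n0 = tp + fn, tn + fp
    report = {
        "tp": tp, "fn": fn, "tn": tn, "fp": fp,
        "sensitivity": tp / n1 if n1 else float("nan"),
        "specificity": tn / n0 if n0 else float("nan"),
        "accuracy": (tp + tn) / len(y),
        "auc": probe_auc(s, y) if n1 and n0 else float("nan"),
        "scores": s.tolist(),
    }
    return report


def train_panel(
    beta: pd.DataFrame,
    labels,
    dmps: pd.DataFrame,
    cnv_regions: pd.DataFrame,
    manifest: pd.DataFrame,
    n_rep: int = 25,
    n_folds: int = 5,
    seed: int = 0,
    auc_keep: float = 1.0,
    r2_cut: float = 0.9,
) -> PanelModel:
    """Feature selection + cross-validated LASSO fit; returns the panel."""
    features = select_features(
        dmps, cnv_regions, beta, labels, manifest, auc_keep, r2_cut
    )
    X = beta.loc[features].T
    y = _as_binary(labels).astype(float)
    lam, cv_table = select_lambda(X, y, n_rep=n_rep, n_folds=n_folds, seed=seed)
    model = lasso_logistic_fit(X, y, lam)
    active = [
        (pid, c) for pid, c in zip(model.probe_ids, model.coefficients) if c != 0.0
    ]
    pruned = PanelModel(
        probe_ids=[pid for pid, _ in active],
        intercept=model.intercept,
        coefficients=[c for _, c in active],
        lambda_=lam,
        standardization={
            pid: model.standardization[pid] for pid, _ in active
        },
        meta={
            "n_candidates": len(features),
            "cv_error": float(cv_table.loc[cv_table["lambda"] == lam, "cv_error"].iloc[0]),
            "seed": seed,
        },
    )
    return pruned
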