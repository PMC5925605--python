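"""Packaged simulation studies: recovery, calibration, and analytic anchors.

Each function runs one of the package's standard validation experiments on
synthetic cohorts with known ground truth and returns a flat dict of
metrics. They are used by the test suite and by ``scripts/acceptance.py``,
and are convenient entry points for anyone re-examining the pipeline's
operating characteristics at different settings.
"""

from __future__ import annotations

import tempfile

import numpy as np
import pandas as pd

from . import classify, cnv, diffmeth, dmr, preprocess, synth
from .pipeline import RunConfig, run_pipeline


def _spawn_seeds(seed: int, n: int) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(ss.generate_state(1)[0] % (2**31 - 1)) for ss in children]


def cn_anchor_study() -> dict:
    """Analytic copy-number anchor on a noise-free cohort.

    A clonal one-copy loss halves total intensity, so its log ratio is
    log10(1/2) = -0.301 — consistent to one decimal with the conventional
    loss threshold of -0.3; a two-copy gain doubles it (+0.301).
    """
    manifest = synth.generate_manifest(2000, n_chrom=1, seed=0)
    # per-measurement noise off; probe-level brightness differences stay,
    # as rank normalization needs them to preserve dosage (they are shared
    # across samples, so the cohort is still deterministic given the seed)
    noise = synth.NoiseModel(beta_logit_sd=0.0, intensity_log_sd=0.0,
                             det_fail_rate=0.0)
    out = {}
    for label, cn_state in (("one_copy_loss", 1), ("two_copy_gain", 4)):
        design = synth.TruthDesign(n_dmp=0, n_dmr=0, n_cnv=1,
                                   cnv_states=(cn_state,), cnv_probes=20,
                                   cnv_recurrence=1)
        signal, sheet, truth = synth.generate_cohort(
            manifest, 4, 4, design, seed=1, noise=noise
        )
        T = cnv.total_intensity(signal)
        L = cnv.log_ratio(T, sheet.index[sheet["group"] == "normal"])
        chrom, start, end, sid, _cn = truth.cnv_segments[0]
        man = manifest.loc[L.index]
        inside = ((man["chrom"] == chrom) & (man["pos"] >= start)
                  & (man["pos"] <= end)).to_numpy()
        out[f"{label}_log_ratio"] = float(L.loc[inside, sid].mean())
    return out


def _region_jaccard(regions: pd.DataFrame, truth_probes: set,
                    chrom: str, start: int, end: int) -> float:
    """Probe-level Jaccard between a truth interval and the union of
    detected regions overlapping it."""
    found: set = set()
    for _, r in regions.iterrows():
        if r["chrom"] == chrom and r["start"] <= end and r["end"] >= start:
            found |= set(r["probe_ids"])
    union = found | truth_probes
    return len(found & truth_probes) / len(union) if union else 0.0


def recovery_study(seed: int, scratch_dir: str | None = None) -> dict:
    """End-to-end recovery on the canonical spiked cohort.

    16 normals / 31 tumors over 20k probes with 500 spiked DMPs
    (delta 0.3), ten 10-probe DMRs, and five recurrent two-copy-gain CNV
    segments overlapping 50 of the DMPs. The full pipeline runs at its
    defaults; a 100-sample cohort drawn independently from the same
    population (30 normals / 70 tumors) serves as external validation of
    the trained panel.
    """
    s_run, s_val = _spawn_seeds(seed, 2)
    outdir = scratch_dir or tempfile.mkdtemp(prefix="methylforge_recovery_")
    config = RunConfig(seed=s_run, outdir=outdir)
    art = run_pipeline(config)

    manifest = art["manifest"]
    truth = art["truth"]
    dmps = art["dmps"]
    beta = art["beta"]
    sheet = art["sheet"]

    # --- DMP recovery -------------------------------------------------
    called = set(dmps.index[dmps["significant"]])
    truth_dmps = truth.dmp_probes
    dmr_truth_probes: set = set()
    for s in truth.dmr_probe_sets(manifest):
        dmr_truth_probes |= s
    recall = len(called & truth_dmps) / len(truth_dmps)
    false_pos = len(called - truth_dmps - dmr_truth_probes)

    # --- DMR recovery (union-of-overlaps probe Jaccard) ---------------
    jaccards = [
        _region_jaccard(
            art["dmrs"],
            set(manifest.index[
                (manifest["chrom"] == chrom)
                & (manifest["pos"] >= start) & (manifest["pos"] <= end)
            ]) & set(beta.index),
            chrom, start, end,
        )
        for chrom, start, end, _delta in truth.dmr_intervals
    ]

    # --- panel / CNV exclusion ----------------------------------------
    model = art["model"]
    cnv_truth_probes: set = set()
    for chrom, start, end, _sid, _cn in truth.cnv_segments:
        hit = manifest[
            (manifest["chrom"] == chrom)
            & (manifest["pos"] >= start) & (manifest["pos"] <= end)
        ]
        cnv_truth_probes |= set(hit.index)
    panel_in_cnv = len(set(model.probe_ids) & cnv_truth_probes)

    # --- profile correlation with cellularity -------------------------
    profile_r = diffmeth.profile_correlation(
        beta, sorted(called & set(beta.index)),
        sheet["cellularity"].to_numpy(),
    )

    # --- external validation cohort -----------------------------------
    design = synth.TruthDesign(
        n_dmp=config.n_dmp, dmp_delta=config.dmp_delta,
        frac_hyper=config.frac_hyper, n_dmr=config.n_dmr,
        dmr_probes=config.dmr_probes, dmr_delta=config.dmr_delta,
        n_cnv=config.n_cnv, cnv_probes=config.cnv_probes,
        cnv_states=tuple(config.cnv_states),
        cnv_recurrence=config.cnv_recurrence,
        n_dmp_in_cnv=config.n_dmp_in_cnv,
    )
    val_signal, val_sheet, _val_truth = synth.generate_cohort(
        manifest, 30, 70, design, seed=s_val,
        baseline_seed=config.stage_seeds()["simulate"],
    )
    # external scoring needs only the panel probes; beta computed directly
    val_beta = preprocess.compute_beta(
        val_signal.meth, val_signal.unmeth, config.offset
    )
    scores = classify.predict_scores(model, val_beta)
    val_labels = (val_sheet["group"] == "tumor").to_numpy()
    val_report = classify.evaluate(scores["score"].to_numpy(), val_labels)

    return {
        "dmp_recall": recall,
        "dmp_false_positives": false_pos,
        "dmp_significant": int(dmps["significant"].sum()),
        "dmr_jaccard_min": float(min(jaccards)),
        "dmr_jaccard_mean": float(np.mean(jaccards)),
        "n_dmrs_detected": len(art["dmrs"]),
        "n_recurrent_cnvs": len(art["cnv_recurrent"]),
        "panel_size": len(model.probe_ids),
        "panel_probes_in_cnv": panel_in_cnv,
        "profile_correlation": float(profile_r),
        "training_accuracy": art["evaluation"]["accuracy"],
        "training_auc": art["evaluation"]["auc"],
        "validation_sensitivity": val_report["sensitivity"],
        "validation_specificity": val_report["specificity"],
        "validation_accuracy": val_report["accuracy"],
        "validation_auc": val_report["auc"],
    }


def cnv_recovery_study(seed: int) -> dict:
    """Segmentation-level recovery of CN 1 and CN 3 segments.

    Spiked clonal segments of >= 20 probes at purity 1 under default
    noise; recovery is scored on the segmentation output (boundary offset
    in probes, marker-weighted mean log ratio) rather than the
    gain/loss-thresholded calls, since log10(3/2) = 0.176 lies below the
    0.2 gain cut and log10(1/2) = -0.301 sits exactly on the loss cut.
    """
    s_man, s_cohort, s_seg = _spawn_seeds(seed, 3)
    manifest = synth.generate_manifest(6000, n_chrom=2, seed=s_man)
    design = synth.TruthDesign(
        n_dmp=0, n_dmr=0, n_cnv=4, cnv_probes=20, cnv_states=(3, 1),
        cnv_recurrence=2,
    )
    signal, sheet, truth = synth.generate_cohort(
        manifest, 8, 15, design, seed=s_cohort
    )
    filtered, _ = preprocess.filter_probes(signal, manifest)
    T = cnv.total_intensity(filtered)
    L = cnv.log_ratio(T, sheet.index[sheet["group"] == "normal"])
    L = cnv.smooth_outliers(L, manifest.loc[L.index])
    man = manifest.loc[L.index]
    segs = cnv.segment_matrix(L, man, alpha=0.01, n_perm=200, seed=s_seg)

    pos_by_chrom = {
        chrom: man.loc[man["chrom"] == chrom, "pos"].to_numpy()
        for chrom in man["chrom"].unique()
    }
    boundary_errors, mean_errors, missed = [], [], 0
    for chrom, start, end, sid, cn_state in truth.cnv_segments:
        hits = segs[
            (segs["sample_id"] == sid) & (segs["chrom"] == chrom)
            & (segs["start"] <= end) & (segs["end"] >= start)
            & (segs["mean_log_ratio"].abs() > 0.08)
        ]
        if hits.empty:
            missed += 1
            continue
        pos = pos_by_chrom[chrom]
        # boundary offset measured in probes on each side
        got_start = int(hits["start"].min())
        got_end = int(hits["end"].max())
        err_start = abs(int(np.searchsorted(pos, got_start))
                        - int(np.searchsorted(pos, start)))
        err_end = abs(int(np.searchsorted(pos, got_end, side="right"))
                      - int(np.searchsorted(pos, end, side="right")))
        boundary_errors.append(max(err_start, err_end))
        mean_lr = float(
            (hits["mean_log_ratio"] * hits["n_markers"]).sum()
            / hits["n_markers"].sum()
        )
        mean_errors.append(abs(mean_lr - np.log10(cn_state / 2.0)))
    return {
        "cnv_segments_spiked": len(truth.cnv_segments),
        "cnv_segments_missed": missed,
        "cnv_boundary_error_max": float(max(boundary_errors)) if boundary_errors else float("nan"),
        "cnv_mean_log_ratio_error_max": float(max(mean_errors)) if mean_errors else float("nan"),
    }


def prior_recovery_study(seed: int, n_probes: int = 50_000,
                         d0: float = 4.0, s0_sq: float = 2.0,
                         df: int = 20) -> dict:
    """Hyperparameter recovery for the variance-moderation prior."""
    rng = np.random.default_rng(seed)
    sigma_g = s0_sq * d0 / rng.chisquare(d0, n_probes)
    s2 = sigma_g * rng.chisquare(df, n_probes) / df
    prior = diffmeth.estimate_prior(s2, df_resid=df)
    return {"prior_d0_estimate": float(prior.d0),
            "prior_s0_sq_estimate": float(prior.s0_sq)}


def dmp_null_study(seed: int, n_runs: int = 3, n_probes: int = 20_000) -> dict:
    """Significant calls on cohorts with no spiked truth (type-I control)."""
    seeds = _spawn_seeds(seed, 2 * n_runs)
    counts = []
    for k in range(n_runs):
        manifest = synth.generate_manifest(n_probes, 4, seed=seeds[2 * k])
        design = synth.TruthDesign(n_dmp=0, n_dmr=0, n_cnv=0)
        signal, sheet, _ = synth.generate_cohort(
            manifest, 16, 31, design, seed=seeds[2 * k + 1]
        )
        filtered, _ = preprocess.filter_probes(signal, manifest)
        beta = preprocess.compute_beta(filtered.meth, filtered.unmeth, 100.0)
        mvals = preprocess.beta_to_m(beta)
        fits = diffmeth.fit_probe_regressions(
            mvals, sheet["cellularity"].to_numpy()
        )
        prior = diffmeth.estimate_prior(
            fits["sigma2"], int(fits["df_resid"].iloc[0])
        )
        stats = diffmeth.moderated_t(fits, prior)
        out = diffmeth.call_dmps(stats, beta, sheet["group"])
        counts.append(int(out["significant"].sum()))
    return {"dmp_null_mean_calls": float(np.mean(counts)),
            "dmp_null_max_calls": int(max(counts))}


def dmr_null_study(seed: int, n_datasets: int = 50, B: int = 100,
                   n_probes: int = 2000) -> dict:
    """Fraction of null cohorts producing any region at FWER < 0.05."""
    seeds = _spawn_seeds(seed, 2 * n_datasets)
    hits = 0
    for k in range(n_datasets):
        manifest = synth.generate_manifest(n_probes, 2, seed=seeds[2 * k])
        design = synth.TruthDesign(n_dmp=0, n_dmr=0, n_cnv=0)
        signal, sheet, _ = synth.generate_cohort(
            manifest, 8, 15, design, seed=seeds[2 * k + 1]
        )
        beta = preprocess.compute_beta(signal.meth, signal.unmeth, 100.0)
        candidates = dmr.resampling_fwer(
            beta, sheet["group"], manifest, B=B, seed=seeds[2 * k + 1],
        )
        if len(candidates) and (candidates["fwer"] < 0.05).any():
            hits += 1
    return {"dmr_null_datasets": n_datasets,
            "dmr_null_fraction_with_region": hits / n_datasets}


def segmentation_null_study(seed: int, n_tracks: int = 50,
                            length: int = 100) -> dict:
    """False-split rate of the change-point test on pure-noise tracks."""
    seeds = _spawn_seeds(seed, n_tracks)
    false_splits = 0
    for k in range(n_tracks):
        rng = np.random.default_rng(seeds[k])
        v = rng.normal(0.0, 0.1, length)
        if cnv.segment(v, alpha=0.01, n_perm=200, seed=seeds[k]):
            false_splits += 1
    return {"segmentation_null_tracks": n_tracks,
            "segmentation_false_split_fraction": false_splits / n_tracks}


def confusion_arithmetic_study() -> dict:
    """Metric arithmetic on the canonical external-validation confusion
    structure: 225 of 234 tumors and 88 of 90 non-tumors correct."""
    scores = np.concatenate(
        [np.full(225, 0.9), np.full(9, 0.1),
         np.full(88, 0.1), np.full(2, 0.9)]
    )
    labels = np.concatenate([np.ones(234), np.zeros(90)])
    report = classify.evaluate(scores, labels)
    return {
        "sensitivity_from_counts": report["sensitivity"],
        "specificity_from_counts": report["specificity"],
        "accuracy_from_counts": report["accuracy"],
    }
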