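"""End-to-end orchestration: simulate -> QC -> DMP -> DMR -> CNV -> panel.

Every stage reads and writes plain-text artifacts (TSV/JSON), so a run
can be resumed from any stage's files. A single top-level seed is split
into per-stage sub-seeds through ``numpy.random.SeedSequence(seed).spawn``
(stage order fixed: simulate, dmr, cnv, train), making each stage
independently reproducible. Outputs are stamped with the seed and a hash
of the canonical config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, cnv, diffmeth, dmr, io, preprocess, synth

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "dmp", "dmr", "cnv", "train", "evaluate")


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run."""

    seed: int = 0
    outdir: str = "methylforge_run"
    scale: str = "desk"  # desk: reduced resampling counts; full: paper-scale

    # simulate
    n_probes: int = 20_000
    n_chrom: int = 4
    n_normal: int = 16
    n_tumor: int = 31
    island_fraction: float = 0.8
    n_dmp: int = 500
    dmp_delta: float = 0.3
    frac_hyper: float = 0.99
    n_dmr: int = 10
    dmr_probes: int = 10
    dmr_delta: float = 0.3
    n_cnv: int = 5
    cnv_probes: int = 30
    # gains only by default: a pure one-copy loss (log10(1/2) = -0.301)
    # sits exactly on the -0.3 loss cut and is called only by luck
    cnv_states: tuple[int, ...] = (4,)
    cnv_recurrence: int = 3
    n_dmp_in_cnv: int = 50

    # preprocess
    det_threshold: float = 0.01
    det_policy: str = "any"
    offset: float = 100.0
    normalize: bool = False  # optional quantile normalization of intensities

    # dmp
    dmp_alpha: float = 0.01
    dmp_effect: float = 0.2

    # dmr
    maxgap: int = 500
    window: int = 3
    dmr_cutoff: float = 0.2
    dmr_min_probes: int = 3
    dmr_B: int = 1000
    fwer_threshold: float = 0.01

    # cnv
    cnv_min_markers: int = 5
    gain_cut: float = 0.2
    loss_cut: float = -0.3
    cnv_alpha: float = 0.01
    cnv_n_perm: int = 10_000
    blacklist: list = field(default_factory=list)

    # classify
    auc_keep: float = 1.0
    r2_cut: float = 0.9
    cv_reps: int = 25
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if self.scale == "desk":
            self.dmr_B = min(self.dmr_B, 200)
            self.cnv_n_perm = min(self.cnv_n_perm, 200)
            self.cv_reps = min(self.cv_reps, 10)
        self.validate()

    def validate(self) -> None:
        for name in ("dmp_alpha", "dmp_effect", "fwer_threshold", "cnv_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1); got {v}")
        if self.scale not in ("desk", "full"):
            raise ValueError("scale must be 'desk' or 'full'")
        if self.gain_cut <= 0 or self.loss_cut >= 0:
            raise ValueError("gain_cut must be positive, loss_cut negative")

    def canonical(self) -> str:
        d = asdict(self)
        d.pop("outdir")  # a location, not a parameter of the computation
        d["cnv_states"] = list(d["cnv_states"])
        return json.dumps(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:12]

    def stage_seeds(self) -> dict[str, int]:
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("simulate", "dmr", "cnv", "train")
        return {
            name: int(ss.generate_state(1)[0] % (2**31 - 1))
            for name, ss in zip(names, children)
        }


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages in order; returns the in-memory artifact bundle.

    Artifacts are also written under ``config.outdir``; rerunning with
    the same config is bit-identical.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    stamp = {"seed": config.seed, "config_hash": config.config_hash()}

    # ---- simulate ----------------------------------------------------
    manifest = synth.generate_manifest(
        config.n_probes, config.n_chrom, config.island_fraction,
        seed=seeds["simulate"],
    )
    design = synth.TruthDesign(
        n_dmp=config.n_dmp, dmp_delta=config.dmp_delta,
        frac_hyper=config.frac_hyper, n_dmr=config.n_dmr,
        dmr_probes=config.dmr_probes, dmr_delta=config.dmr_delta,
        n_cnv=config.n_cnv, cnv_probes=config.cnv_probes,
        cnv_states=tuple(config.cnv_states),
        cnv_recurrence=config.cnv_recurrence,
        n_dmp_in_cnv=config.n_dmp_in_cnv,
    )
    signal, sheet, truth = synth.generate_cohort(
        manifest, config.n_normal, config.n_tumor, design,
        seed=seeds["simulate"],
    )
    io.write_manifest(manifest, out / "manifest.tsv")
    io.write_samplesheet(sheet, out / "samples.tsv")
    io.write_signal(signal, out / "signal")
    io.write_truth(truth, out / "truth.json")
    logger.info("simulate: %d probes x %d samples", *signal.meth.shape)

    # ---- preprocess --------------------------------------------------
    filtered, qc = preprocess.filter_probes(
        signal, manifest, config.det_threshold, config.det_policy
    )
    meth, unmeth = filtered.meth, filtered.unmeth
    if config.normalize:
        meth = preprocess.quantile_normalize(meth)
        unmeth = preprocess.quantile_normalize(unmeth)
    beta = preprocess.compute_beta(meth, unmeth, config.offset)
    mvals = preprocess.beta_to_m(beta)
    sample_report = preprocess.sample_qc(beta)
    qc.sample_flags = sample_report.sample_flags
    io.write_matrix(beta, out / "beta.tsv")
    io.write_matrix(mvals, out / "mvals.tsv")
    io.write_json({**qc.to_dict(), **stamp}, out / "qc.json")
    logger.info(
        "preprocess: %d probes kept, %d dropped",
        beta.shape[0], len(qc.dropped_probes),
    )

    # ---- dmp ---------------------------------------------------------
    groups = sheet["group"]
    x = sheet["cellularity"].to_numpy(dtype=float)
    fits = diffmeth.fit_probe_regressions(mvals, x)
    prior = diffmeth.estimate_prior(fits["sigma2"], int(fits["df_resid"].iloc[0]))
    stats = diffmeth.moderated_t(fits, prior)
    dmps = diffmeth.call_dmps(
        stats, beta, groups, config.dmp_alpha, config.dmp_effect
    )
    dmps.to_csv(out / "dmp.tsv", sep="\t")
    logger.info("dmp: %d significant of %d tested", int(dmps["significant"].sum()),
                len(dmps))

    # ---- dmr ---------------------------------------------------------
    kept_manifest = manifest.loc[beta.index]
    candidates = dmr.resampling_fwer(
        beta, groups, kept_manifest,
        maxgap=config.maxgap, window=config.window,
        cutoff=config.dmr_cutoff, min_probes=config.dmr_min_probes,
        B=config.dmr_B, seed=seeds["dmr"],
    )
    regions = dmr.significant_regions(
        candidates, config.fwer_threshold, B=config.dmr_B
    )
    io.write_bed_regions(
        regions.assign(
            name=[f"dmr_{i}" for i in range(len(regions))]
        ),
        out / "dmr.tsv",
        extra_cols=["n_probes", "fwer"],
    )
    logger.info("dmr: %d regions at FWER < %g", len(regions),
                config.fwer_threshold)

    # ---- cnv ---------------------------------------------------------
    T = cnv.total_intensity(filtered)
    L = cnv.log_ratio(T, sheet.index[groups == "normal"])
    L = cnv.smooth_outliers(L, kept_manifest)
    segs = cnv.segment_matrix(
        L, kept_manifest, alpha=config.cnv_alpha, n_perm=config.cnv_n_perm,
        seed=seeds["cnv"],
    )
    calls = cnv.call_segments(
        segs, config.cnv_min_markers, config.gain_cut, config.loss_cut
    )
    tumor_ids = set(sheet.index[groups == "tumor"])
    tumor_calls = calls[calls["sample_id"].isin(tumor_ids)]
    normal_calls = calls[~calls["sample_id"].isin(tumor_ids)]
    clean = cnv.filter_shared_and_blacklist(
        tumor_calls, normal_calls,
        [(c, int(s), int(e)) for c, s, e in config.blacklist],
    )
    recurrent = cnv.recurrent_segments(clean) if len(clean) else pd.DataFrame(
        columns=["chrom", "start", "end", "direction", "support"]
    )
    calls.to_csv(out / "cnv_segments.tsv", sep="\t", index=False)
    recurrent.to_csv(out / "cnv_recurrent.tsv", sep="\t", index=False)
    overlap = cnv.overlap_dmrs(recurrent, regions)
    overlap.to_csv(out / "cnv_dmr_overlap.tsv", sep="\t", index=False)
    logger.info("cnv: %d calls, %d recurrent intervals", len(calls),
                len(recurrent))

    # ---- train -------------------------------------------------------
    labels = (groups == "tumor").astype(int).to_numpy()
    model = classify.train_panel(
        beta, labels, dmps, recurrent, kept_manifest,
        n_rep=config.cv_reps, n_folds=config.cv_folds, seed=seeds["train"],
        auc_keep=config.auc_keep, r2_cut=config.r2_cut,
    )
    model.meta.update(stamp)
    io.write_json(model.to_dict(), out / "model.json")
    logger.info("train: panel of %d probes (lambda=%.4g)",
                len(model.probe_ids), model.lambda_)

    # ---- evaluate ----------------------------------------------------
    pred = classify.predict_scores(model, beta)
    report = classify.evaluate(pred["score"].to_numpy(), labels)
    report.update(stamp)
    io.write_json(report, out / "evaluation.json")
    pred.to_csv(out / "scores.tsv", sep="\t", index_label="sample_id")
    logger.info("evaluate: accuracy %.3f, auc %.3f", report["accuracy"],
                report["auc"])

    return {
        "manifest": manifest, "signal": signal, "sheet": sheet, "truth": truth,
        "qc": qc, "beta": beta, "mvals": mvals, "dmps": dmps,
        "dmr_candidates": candidates, "dmrs": regions,
        "cnv_calls": calls, "cnv_recurrent": recurrent, "cnv_dmr": overlap,
        "model": model, "evaluation": report,
    }
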