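"""Synthetic methylation-array cohorts with known ground truth.

The generator emulates the statistical structure of a two-group (tumor vs.
adjacent-normal) 450k-style experiment:

* bimodal baseline beta values (unmethylated mode near 0.1, methylated
  mode near 0.85), with probes organised into island-like blocks so that
  regional (multi-probe) methylation events are meaningful;
* tumor-specific methylation shifts diluted linearly by tumor cellularity
  — a specimen with cellularity ``c`` shows
  ``c * clip(beta + delta, 0, 1) + (1 - c) * beta``;
* total probe intensity drawn log-normal and scaled by ``CN / 2`` inside
  a carrier sample's copy-number segments;
* sporadic probe-by-sample detection failures.

Ground truth (which probes, regions and segments were spiked) is returned
as a :class:`~methylforge.datatypes.TruthSet` so downstream recovery can
be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datatypes import SignalMatrix, TruthSet, validate_manifest
from .dmr import cluster_probes

_LOGIT_EPS = 1e-6


@dataclass
class TruthDesign:
    """Parameters of the spiked ground truth.

    ``n_dmp`` isolated differential probes with beta shift ``dmp_delta`` at
    full cellularity (a fraction ``frac_hyper`` of them hypermethylated);
    ``n_dmr`` regional events, each spiking one whole probe block of
    ``dmr_probes``..``dmr_probes + 4`` probes; ``n_cnv`` copy-number
    segments of ``cnv_probes`` consecutive probes, each carried by
    ``cnv_recurrence`` distinct tumors with copy numbers cycled from
    ``cnv_states``. ``n_dmp_in_cnv`` of the isolated DMPs are placed inside
    CNV segments (to exercise the classifier's CNV-exclusion stage).
    """

    n_dmp: int = 500
    dmp_delta: float = 0.3
    frac_hyper: float = 0.99
    n_dmr: int = 10
    dmr_probes: int = 10
    dmr_delta: float = 0.3
    n_cnv: int = 5
    cnv_probes: int = 30
    cnv_states: tuple[int, ...] = (4, 1)
    cnv_recurrence: int = 3
    n_dmp_in_cnv: int = 0


@dataclass
class NoiseModel:
    """Technical-noise settings.

    ``beta_logit_sd``: additive Gaussian noise on the logit(beta) scale,
    back-transformed — keeps beta in (0, 1) without clipping.
    ``intensity_log_sd``: sd of the natural-log per-measurement intensity
    noise (log-normal multiplicative). ``probe_intensity_log_sd``: sd of
    the per-probe baseline intensity effect shared by all samples —
    array probes differ in brightness by orders of magnitude, which is
    what makes rank-based normalization dosage-preserving.
    ``det_fail_rate``: probability that a single probe-by-sample
    measurement fails (detection p drawn large).
    """

    beta_logit_sd: float = 0.3
    intensity_log_sd: float = 0.15
    probe_intensity_log_sd: float = 1.0
    det_fail_rate: float = 1e-4


def generate_manifest(
    n_probes: int,
    n_chrom: int = 4,
    island_fraction: float = 0.8,
    seed: int = 0,
    close_fraction: float = 0.7,
    gene_fraction: float = 0.7,
    snp_fraction: float = 0.02,
    enhancer_fraction: float = 0.32,
) -> pd.DataFrame:
    """Simulate an array manifest: ordered probes in island-like blocks.

    ``close_fraction`` of adjacent probe pairs are <= 500 bp apart (drawn
    20–400 bp), the rest 600–10000 bp, producing geometric block sizes
    with mean ``1 / (1 - close_fraction)`` probes. Deterministic for a
    fixed seed.
    """
    if n_probes <= 0 or n_chrom <= 0:
        raise ValueError("n_probes and n_chrom must be positive")
    if n_probes < n_chrom:
        raise ValueError("need at least one probe per chromosome")
    rng = np.random.default_rng(seed)

    base, extra = divmod(n_probes, n_chrom)
    counts = [base + (1 if i < extra else 0) for i in range(n_chrom)]

    chroms, positions = [], []
    for ci, count in enumerate(counts):
        close = rng.random(count - 1) < close_fraction if count > 1 else np.array([])
        gaps = np.where(
            close,
            rng.integers(20, 401, size=close.shape),
            rng.integers(600, 10001, size=close.shape),
        )
        pos = 10_000 + np.concatenate([[0], np.cumsum(gaps)]).astype(np.int64)
        chroms.extend([f"chr{ci + 1}"] * count)
        positions.extend(pos.tolist())

    n = n_probes
    relation = np.where(
        rng.random(n) < island_fraction,
        "island",
        rng.choice(["shore", "shelf", "open_sea"], size=n),
    )
    manifest = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "gene": "",
            "island_relation": relation,
            "enhancer": rng.random(n) < enhancer_fraction,
            "snp_flag": rng.random(n) < snp_fraction,
        },
        index=pd.Index([f"cg{i:08d}" for i in range(n)], name="probe_id"),
    )

    # gene names assigned block-wise so regional events map to one gene
    clusters = cluster_probes(manifest, maxgap=500)
    gene_no = 0
    genes = pd.Series("", index=manifest.index, dtype=object)
    for cl in clusters:
        if rng.random() < gene_fraction:
            gene_no += 1
            genes.loc[cl.probe_ids] = f"GENE{gene_no:05d}"
    manifest["gene"] = genes
    return validate_manifest(manifest)


def mixture_beta(beta_base, delta, cellularity):
    """Observed beta of a cellularity-``c`` specimen at a spiked probe.

    ``c * clip(beta_base + delta, 0, 1) + (1 - c) * beta_base`` — the
    two-population mixture of tumor cells (shifted) and contaminating
    normal cells (baseline). With ``c = 0`` or ``delta = 0`` this is the
    baseline itself.
    """
    target = np.clip(np.asarray(beta_base, dtype=float) + delta, 0.0, 1.0)
    return cellularity * target + (1.0 - np.asarray(cellularity)) * np.asarray(
        beta_base, dtype=float
    )


def _logit_noise(beta: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd <= 0:
        return beta
    z = logit(np.clip(beta, _LOGIT_EPS, 1 - _LOGIT_EPS))
    return expit(z + rng.normal(0.0, sd, size=beta.shape))


def _pick_truth_probes(
    manifest: pd.DataFrame, design: TruthDesign, rng: np.random.Generator
):
    """Choose disjoint probe sets for CNV segments, DMR blocks and DMPs."""
    order = {pid: i for i, pid in enumerate(manifest.index)}
    taken = np.zeros(len(manifest), dtype=bool)
    snp = manifest["snp_flag"].to_numpy()

    # CNV segments: runs of consecutive probes within one chromosome
    cnv_ranges: list[tuple[str, int, int]] = []  # chrom, start iloc, end iloc (incl.)
    chrom_bounds = {}
    for chrom in manifest["chrom"].unique():
        ilocs = np.flatnonzero((manifest["chrom"] == chrom).to_numpy())
        chrom_bounds[chrom] = (ilocs[0], ilocs[-1])
    chrom_cycle = list(chrom_bounds)
    attempts = 0
    while len(cnv_ranges) < design.n_cnv and attempts < 1000 * max(design.n_cnv, 1):
        attempts += 1
        chrom = chrom_cycle[rng.integers(len(chrom_cycle))]
        lo, hi = chrom_bounds[chrom]
        if hi - lo + 1 < design.cnv_probes:
            continue
        start = int(rng.integers(lo, hi - design.cnv_probes + 2))
        stop = start + design.cnv_probes - 1
        if taken[start : stop + 1].any():
            continue
        taken[start : stop + 1] = True
        cnv_ranges.append((chrom, start, stop))
    if len(cnv_ranges) < design.n_cnv:
        raise ValueError("manifest too small for the requested CNV design")

    # DMR blocks: whole probe clusters of a suitable size, outside CNVs
    clusters = cluster_probes(manifest, maxgap=500)
    eligible = [
        cl
        for cl in clusters
        if design.dmr_probes <= len(cl.probe_ids) <= design.dmr_probes + 4
        and not any(taken[order[p]] or snp[order[p]] for p in cl.probe_ids)
    ]
    if len(eligible) < design.n_dmr:
        raise ValueError("not enough probe blocks for the requested DMR design")
    idx = rng.choice(len(eligible), size=design.n_dmr, replace=False)
    dmr_clusters = [eligible[int(i)] for i in sorted(idx)]
    for cl in dmr_clusters:
        for p in cl.probe_ids:
            taken[order[p]] = True

    # isolated DMPs: n_dmp_in_cnv inside CNV segments, the rest elsewhere
    inside = np.zeros(len(manifest), dtype=bool)
    for _chrom, start, stop in cnv_ranges:
        inside[start : stop + 1] = True
    in_pool = np.flatnonzero(inside & ~snp)
    out_pool = np.flatnonzero(~inside & ~taken & ~snp)
    if design.n_dmp_in_cnv > len(in_pool):
        raise ValueError("CNV segments hold fewer probes than n_dmp_in_cnv")
    n_out = design.n_dmp - design.n_dmp_in_cnv
    if n_out > len(out_pool):
        raise ValueError("manifest too small for the requested DMP count")
    dmp_ilocs = np.concatenate(
        [
            rng.choice(in_pool, size=design.n_dmp_in_cnv, replace=False),
            rng.choice(out_pool, size=n_out, replace=False),
        ]
    ).astype(int)
    return cnv_ranges, dmr_clusters, dmp_ilocs


def generate_cohort(
    manifest: pd.DataFrame,
    n_normal: int,
    n_tumor: int,
    design: TruthDesign | None = None,
    intensity_scale: float = 2000.0,
    seed: int = 0,
    noise: NoiseModel | None = None,
    cellularity_range: tuple[float, float] = (0.8, 0.9),
    cnv_purity: float = 1.0,
    beta_modes: tuple[float, float] = (0.1, 0.85),
    high_mode_fraction: float = 0.45,
    n_replicates: int = 0,
    baseline_seed: int | None = None,
) -> tuple[SignalMatrix, pd.DataFrame, TruthSet]:
    """Simulate a tumor/normal cohort over ``manifest``.

    Tumor cellularity is drawn uniformly from ``cellularity_range``
    (default 0.8–0.9, emulating macrodissected specimens of high tumor
    content; the range keeps the canonical spiked effect detectably above
    the 20% delta-beta call threshold after dilution and logit-noise
    attenuation — see the methods note's power analysis). Copy-number events are treated as clonal at ``cnv_purity``
    (default 1), independent of the methylation cellularity. Technical
    replicates re-draw only the noise terms of existing tumor samples.

    Population-level structure — which loci are spiked, their effect
    signs, per-probe baseline beta and probe brightness — is drawn from
    ``baseline_seed`` (defaulting to ``seed``), while cohort-level draws
    (cellularity, CNV carrier assignment, all noise) come from ``seed``.
    Two cohorts generated with the same manifest and ``baseline_seed``
    but different ``seed`` therefore share the same underlying truth and
    locus baselines — an independent validation cohort from the same
    population.

    Returns ``(SignalMatrix, sample_sheet, TruthSet)``; deterministic for
    a fixed seed pair.
    """
    validate_manifest(manifest)
    if n_normal < 2:
        raise ValueError("need >= 2 normal samples (median-of-normals undefined)")
    if n_tumor < 1:
        raise ValueError("need >= 1 tumor sample")
    design = design or TruthDesign()
    noise = noise or NoiseModel()
    if intensity_scale <= 0:
        raise ValueError("intensity_scale must be positive")
    rng = np.random.default_rng(seed)
    rng_pop = np.random.default_rng(seed if baseline_seed is None else baseline_seed)
    n_probes = len(manifest)

    cnv_ranges, dmr_clusters, dmp_ilocs = _pick_truth_probes(
        manifest, design, rng_pop
    )

    # signed effect per probe (beta shift at full cellularity)
    delta = np.zeros(n_probes)
    hyper = rng_pop.random(len(dmp_ilocs)) < design.frac_hyper
    delta[dmp_ilocs] = np.where(hyper, design.dmp_delta, -design.dmp_delta)
    order = {pid: i for i, pid in enumerate(manifest.index)}
    dmr_intervals = []
    for cl in dmr_clusters:
        sign = 1.0 if rng_pop.random() < design.frac_hyper else -1.0
        ilocs = [order[p] for p in cl.probe_ids]
        delta[ilocs] = sign * design.dmr_delta
        pos = manifest["pos"].to_numpy()
        dmr_intervals.append(
            (cl.chrom, int(pos[ilocs[0]]), int(pos[ilocs[-1]]), sign * design.dmr_delta)
        )

    # baseline beta: bimodal; spiked probes start in the mode that leaves
    # room for the shift (hypermethylation events start unmethylated)
    low, high = beta_modes
    mode_high = rng_pop.random(n_probes) < high_mode_fraction
    high_draw = rng_pop.beta(17.0, 3.0, size=n_probes)
    low_draw = rng_pop.beta(2.0, 18.0, size=n_probes)
    # Beta(2,18) has mean 0.1 and Beta(17,3) mean 0.85; rescale to the requested modes
    beta_base = np.where(mode_high, high_draw * (high / 0.85), low_draw * (low / 0.1))
    beta_base = np.clip(beta_base, 0.01, 0.99)
    spiked = delta != 0
    beta_base[spiked & (delta > 0)] = np.clip(
        rng_pop.beta(2.0, 18.0, size=int((spiked & (delta > 0)).sum()))
        * (low / 0.1),
        0.01,
        0.5,
    )
    beta_base[spiked & (delta < 0)] = np.clip(
        rng_pop.beta(17.0, 3.0, size=int((spiked & (delta < 0)).sum()))
        * (high / 0.85),
        0.5,
        0.99,
    )

    # sample sheet
    sample_ids = [f"normal_{i + 1:02d}" for i in range(n_normal)] + [
        f"tumor_{i + 1:02d}" for i in range(n_tumor)
    ]
    lo_c, hi_c = cellularity_range
    cellularity = np.concatenate(
        [np.zeros(n_normal), rng.uniform(lo_c, hi_c, size=n_tumor)]
    )
    groups = ["normal"] * n_normal + ["tumor"] * n_tumor
    replicate_of = [""] * (n_normal + n_tumor)

    # expected beta per probe x sample from the cellularity mixture
    beta_obs = mixture_beta(
        beta_base[:, None], delta[:, None], cellularity[None, :]
    )

    # copy-number truth: assign carriers and per-probe scale factors
    tumor_ids = sample_ids[n_normal:]
    col_of = {sid: j for j, sid in enumerate(sample_ids)}
    cn_factor = np.ones((n_probes, len(sample_ids)))
    cnv_segments = []
    pos = manifest["pos"].to_numpy()
    for k, (chrom, start, stop) in enumerate(cnv_ranges):
        cn = int(design.cnv_states[k % len(design.cnv_states)])
        carriers = rng.choice(
            len(tumor_ids), size=min(design.cnv_recurrence, len(tumor_ids)),
            replace=False,
        )
        factor = (cnv_purity * cn + (1 - cnv_purity) * 2) / 2.0
        for ci in carriers:
            sid = tumor_ids[int(ci)]
            cn_factor[start : stop + 1, col_of[sid]] = factor
            cnv_segments.append(
                (chrom, int(pos[start]), int(pos[stop]), sid, cn)
            )

    probe_effect = np.exp(
        rng_pop.normal(0.0, noise.probe_intensity_log_sd, size=n_probes)
    )

    def draw_noise(beta_expected, cn_fac, n_cols):
        b = _logit_noise(beta_expected, noise.beta_logit_sd, rng)
        t = intensity_scale * probe_effect[:, None] * np.exp(
            rng.normal(0.0, noise.intensity_log_sd, size=(n_probes, n_cols))
        )
        t = t * cn_fac
        meth = b * t
        unmeth = (1.0 - b) * t
        detp = rng.uniform(1e-6, 0.005, size=(n_probes, n_cols))
        fails = rng.random((n_probes, n_cols)) < noise.det_fail_rate
        detp[fails] = rng.uniform(0.02, 1.0, size=int(fails.sum()))
        return meth, unmeth, detp

    meth, unmeth, detp = draw_noise(beta_obs, cn_factor, len(sample_ids))

    # technical replicates: same expected signal, fresh noise draw
    if n_replicates > 0:
        src = [tumor_ids[int(i)] for i in
               rng.choice(len(tumor_ids), size=n_replicates, replace=n_replicates > len(tumor_ids))]
        cols = [col_of[s] for s in src]
        r_meth, r_unmeth, r_detp = draw_noise(
            beta_obs[:, cols], cn_factor[:, cols], len(cols)
        )
        meth = np.concatenate([meth, r_meth], axis=1)
        unmeth = np.concatenate([unmeth, r_unmeth], axis=1)
        detp = np.concatenate([detp, r_detp], axis=1)
        for r, s in enumerate(src):
            sample_ids.append(f"rep_{r + 1:02d}")
            groups.append("tumor")
            cellularity = np.append(cellularity, cellularity[col_of[s]])
            replicate_of.append(s)

    cols = pd.Index(sample_ids, name="sample_id")
    signal = SignalMatrix(
        meth=pd.DataFrame(meth, index=manifest.index, columns=cols),
        unmeth=pd.DataFrame(unmeth, index=manifest.index, columns=cols),
        detection_p=pd.DataFrame(detp, index=manifest.index, columns=cols),
    )
    sheet = pd.DataFrame(
        {"group": groups, "cellularity": cellularity, "replicate_of": replicate_of},
        index=cols,
    )
    truth = TruthSet(
        dmp_effects={
            manifest.index[i]: float(delta[i]) for i in sorted(dmp_ilocs.tolist())
        },
        dmr_intervals=dmr_intervals,
        cnv_segments=cnv_segments,
    )
    return signal, sheet, truth
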