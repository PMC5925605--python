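"""Shared fixtures: small synthetic cohorts generated at session start."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methylforge import preprocess, synth


@pytest.fixture(scope="session")
def small_manifest():
    return synth.generate_manifest(2000, n_chrom=2, seed=101)


@pytest.fixture(scope="session")
def small_cohort():
    """5k-probe cohort with spiked DMPs/DMRs/CNVs, 8 normals / 15 tumors."""
    manifest = synth.generate_manifest(5000, n_chrom=2, seed=1)
    design = synth.TruthDesign(
        n_dmp=100, n_dmr=4, n_cnv=2, n_dmp_in_cnv=10, cnv_states=(4, 1)
    )
    signal, sheet, truth = synth.generate_cohort(
        manifest, n_normal=8, n_tumor=15, design=design, seed=2
    )
    return {
        "manifest": manifest,
        "signal": signal,
        "sheet": sheet,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_beta(small_cohort):
    """Filtered beta / M matrices of the small cohort."""
    filtered, qc = preprocess.filter_probes(
        small_cohort["signal"], small_cohort["manifest"]
    )
    beta = preprocess.compute_beta(filtered.meth, filtered.unmeth, 100.0)
    return {
        "beta": beta,
        "mvals": preprocess.beta_to_m(beta),
        "qc": qc,
        "filtered": filtered,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
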