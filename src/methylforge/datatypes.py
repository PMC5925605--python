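"""Shared in-memory containers and their invariants.

Matrices are pandas DataFrames with probe identifiers as rows and sample
identifiers as columns; manifests and sample sheets are DataFrames too, so
every container round-trips through plain TSV (see :mod:`methylforge.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ISLAND_RELATIONS = ("island", "shore", "shelf", "open_sea")

MANIFEST_COLUMNS = ["chrom", "pos", "gene", "island_relation", "enhancer", "snp_flag"]
SAMPLESHEET_COLUMNS = ["group", "cellularity", "replicate_of"]


@dataclass
class SignalMatrix:
    """Paired methylated/unmethylated intensities plus detection p-values.

    All three frames share the same probe index and sample columns;
    intensities are finite and non-negative, detection p-values lie in
    [0, 1].
    """

    meth: pd.DataFrame
    unmeth: pd.DataFrame
    detection_p: pd.DataFrame

    def __post_init__(self) -> None:
        for name in ("unmeth", "detection_p"):
            other = getattr(self, name)
            if not (
                other.index.equals(self.meth.index)
                and other.columns.equals(self.meth.columns)
            ):
                raise ValueError(f"{name} index/columns do not match meth")
        for name in ("meth", "unmeth"):
            arr = getattr(self, name).to_numpy()
            if not np.isfinite(arr).all() or (arr < 0).any():
                raise ValueError(f"{name} intensities must be finite and >= 0")
        dp = self.detection_p.to_numpy()
        if ((dp < 0) | (dp > 1)).any():
            raise ValueError("detection_p values must lie in [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.meth.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.meth.columns

    def subset_probes(self, probe_ids) -> "SignalMatrix":
        return SignalMatrix(
            self.meth.loc[probe_ids],
            self.unmeth.loc[probe_ids],
            self.detection_p.loc[probe_ids],
        )


@dataclass
class TruthSet:
    """Ground truth of a synthetic cohort, used only by recovery tests.

    ``dmp_effects`` maps probe_id to the signed beta shift at full
    cellularity; ``dmr_intervals`` are (chrom, start, end, delta) tuples
    (1-based inclusive); ``cnv_segments`` are
    (chrom, start, end, sample_id, copy_number) tuples with copy_number in
    {0,1,3,4} (never the diploid 2).
    """

    dmp_effects: dict[str, float] = field(default_factory=dict)
    dmr_intervals: list[tuple[str, int, int, float]] = field(default_factory=list)
    cnv_segments: list[tuple[str, int, int, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for seg in self.cnv_segments:
            if int(seg[4]) == 2:
                raise ValueError("cnv_segments must not contain the diploid state 2")

    @property
    def dmp_probes(self) -> set[str]:
        return set(self.dmp_effects)

    def dmr_probe_sets(self, manifest: pd.DataFrame) -> list[set[str]]:
        """Probe ids of the manifest falling inside each truth DMR interval."""
        out = []
        for chrom, start, end, _delta in self.dmr_intervals:
            on = manifest[manifest["chrom"] == chrom]
            hit = on[(on["pos"] >= start) & (on["pos"] <= end)]
            out.append(set(hit.index))
        return out


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Check the probe-manifest invariants; returns the manifest unchanged.

    Probe ids (the index) must be unique; positions are 1-based and
    strictly increasing within each chromosome.
    """
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if not manifest.index.is_unique:
        raise ValueError("probe_ids must be unique")
    if (manifest["pos"] < 1).any():
        raise ValueError("positions must be >= 1")
    for chrom, sub in manifest.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if not (np.diff(pos) > 0).all():
            raise ValueError(f"positions not strictly increasing on {chrom}")
    bad = set(manifest["island_relation"]) - set(ISLAND_RELATIONS)
    if bad:
        raise ValueError(f"unknown island_relation values: {bad}")
    return manifest


def validate_samplesheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Normals sit at cellularity 0; tumor cellularity lies in (0, 0.9]."""
    missing = [c for c in SAMPLESHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    bad_group = set(sheet["group"]) - {"normal", "tumor"}
    if bad_group:
        raise ValueError(f"unknown groups: {bad_group}")
    normals = sheet[sheet["group"] == "normal"]
    if (normals["cellularity"] != 0).any():
        raise ValueError("normal samples must have cellularity 0")
    tumors = sheet[sheet["group"] == "tumor"]
    c = tumors["cellularity"].to_numpy(dtype=float)
    if ((c <= 0) | (c > 0.9)).any():
        raise ValueError("tumor cellularity must lie in (0, 0.9]")
    return sheet
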