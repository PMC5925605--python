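"""Plain-text serialization: TSV matrices, BED-style region tables, JSON.

Every artifact the pipeline produces round-trips through these functions,
so any stage can be resumed from files alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .datatypes import SignalMatrix, TruthSet, validate_manifest, validate_samplesheet


def write_manifest(manifest: pd.DataFrame, path) -> None:
    validate_manifest(manifest)
    manifest.to_csv(path, sep="\t", index_label="probe_id")


def read_manifest(path) -> pd.DataFrame:
    manifest = pd.read_csv(
        path, sep="\t", index_col="probe_id",
        dtype={"gene": "string"},
    )
    manifest["gene"] = manifest["gene"].fillna("")
    return validate_manifest(manifest)


def write_samplesheet(sheet: pd.DataFrame, path) -> None:
    validate_samplesheet(sheet)
    sheet.to_csv(path, sep="\t", index_label="sample_id")


def read_samplesheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(
        path, sep="\t", index_col="sample_id", dtype={"replicate_of": "string"}
    )
    sheet["replicate_of"] = sheet["replicate_of"].fillna("")
    return validate_samplesheet(sheet)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="probe_id")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id")


def write_signal(signal: SignalMatrix, directory) -> None:
    """Write meth/unmeth/detection_p as three wide TSVs in ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_matrix(signal.meth, directory / "meth.tsv")
    write_matrix(signal.unmeth, directory / "unmeth.tsv")
    write_matrix(signal.detection_p, directory / "detection_p.tsv")


def read_signal(directory) -> SignalMatrix:
    directory = Path(directory)
    return SignalMatrix(
        meth=read_matrix(directory / "meth.tsv"),
        unmeth=read_matrix(directory / "unmeth.tsv"),
        detection_p=read_matrix(directory / "detection_p.tsv"),
    )


def write_truth(truth: TruthSet, path) -> None:
    payload = {
        "dmp_effects": truth.dmp_effects,
        "dmr_intervals": [list(t) for t in truth.dmr_intervals],
        "cnv_segments": [list(t) for t in truth.cnv_segments],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> TruthSet:
    payload = json.loads(Path(path).read_text())
    return TruthSet(
        dmp_effects={k: float(v) for k, v in payload["dmp_effects"].items()},
        dmr_intervals=[
            (str(c), int(s), int(e), float(d))
            for c, s, e, d in payload["dmr_intervals"]
        ],
        cnv_segments=[
            (str(c), int(s), int(e), str(sid), int(cn))
            for c, s, e, sid, cn in payload["cnv_segments"]
        ],
    )


def write_bed_regions(regions: pd.DataFrame, path, extra_cols=()) -> None:
    """BED-compatible TSV: chrom, 0-based half-open start, end, name, value.

    Internal coordinates are 1-based inclusive; the exported start is
    ``start - 1``.
    """
    out = pd.DataFrame(
        {
            "chrom": regions["chrom"],
            "start": regions["start"].astype(int) - 1,
            "end": regions["end"].astype(int),
            "name": regions.get(
                "name", pd.Series([f"region_{i}" for i in range(len(regions))],
                                  index=regions.index)
            ),
            "value": regions["value"] if "value" in regions else 0.0,
        }
    )
    for col in extra_cols:
        out[col] = regions[col].values
    out.to_csv(path, sep="\t", index=False)


def read_bed_regions(path) -> pd.DataFrame:
    regions = pd.read_csv(path, sep="\t")
    regions["start"] = regions["start"].astype(int) + 1  # back to 1-based inclusive
    return regions


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_json(path):
    return json.loads(Path(path).read_text())
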