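"""Tab-delimited and JSON artifact readers/writers.

All files are UTF-8, header row, '.' decimal separator, "NA" for missing
Ct values.  Writers are deterministic (stable row/column order, repr float
formatting, sorted JSON keys) so identically-seeded runs are bitwise equal.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .quantify import CtDataset, ExpressionMatrix


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index=index)


def write_samples(table: pd.DataFrame, path) -> None:
    _write_tsv(table, Path(path))


def read_samples(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str,
                                              "source_id": str,
                                              "stage": str})


def write_ct_dataset(ct: CtDataset, out_dir) -> list[Path]:
    out = Path(out_dir)
    paths = []
    _write_tsv(ct.measurements, out / "ct_long.tsv")
    paths.append(out / "ct_long.tsv")
    _write_tsv(ct.spikein_measurements, out / "spikein_ct.tsv")
    paths.append(out / "spikein_ct.tsv")
    curve = ct.curve_measurements.rename(columns={"assay_id": "mirna_id"})
    _write_tsv(curve, out / "curve_ct.tsv")
    paths.append(out / "curve_ct.tsv")
    return paths


def read_ct_dataset(ct_path, spikes_path, curves_path) -> CtDataset:
    meas = pd.read_csv(ct_path, sep="\t", na_values=["NA"])
    spikes = pd.read_csv(spikes_path, sep="\t", na_values=["NA"])
    curve = pd.read_csv(curves_path, sep="\t", na_values=["NA"])
    curve = curve.rename(columns={"mirna_id": "assay_id"})
    return CtDataset(measurements=meas, spikein_measurements=spikes,
                     curve_measurements=curve)


def write_truth(truth: pd.DataFrame, path) -> None:
    _write_tsv(truth.reset_index(), Path(path))


def write_expression(expr: ExpressionMatrix, out_dir,
                     name: str = "expression.tsv") -> None:
    out = Path(out_dir)
    _write_tsv(expr.values, out / name, index=True)
    flags_long = (expr.flags.stack().rename("flag").rename_axis(
        ["sample_id", "mirna_id"]).reset_index())
    flags_long = flags_long[flags_long["flag"] != "interpolated"]
    _write_tsv(flags_long, out / "flags.tsv")


def read_expression_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
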