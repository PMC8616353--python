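"""Table readers/writers with strict schemas.

All tables are UTF-8 text with a header and a decimal point. Matrices
(abundance, trait, expression) are TSV with samples in rows and a leading
``# units: ...`` comment line; long-format tables (quant, annotation,
metadata) are CSV. Every reader validates its schema and reports the
offending file/column on failure; write->read round-trips are identities up
to float formatting.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .quant_qc import QUANT_COLUMNS
from .synthetic_cohort import GroundTruth, SimulatedCohort
from .trait_engine import TraitMatrix

__all__ = [
    "read_quant_table", "write_quant_table",
    "read_matrix", "write_matrix",
    "read_expression", "write_expression",
    "read_metadata", "write_metadata",
    "write_trait_matrix", "write_cohort",
]


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    cols = list(df.columns)
    dupes = {c for c in cols if cols.count(c) > 1}
    if dupes:
        raise ValueError(f"{path}: duplicated column(s) {sorted(dupes)}")
    missing = [c for c in required if c not in cols]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")


def read_quant_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, QUANT_COLUMNS, path)
    try:
        df["area"] = df["area"].astype(float)
        df["idotp"] = df["idotp"].astype(float)
        df["snr"] = df["snr"].astype(float)
        df["rt_match"] = df["rt_match"].astype(int).astype(bool)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: type coercion failed ({exc})") from exc
    if (df["area"] < 0).any():
        bad = df.index[df["area"] < 0].tolist()
        raise ValueError(f"{path}: negative peak area at row(s) {bad[:5]}")
    if ((df["idotp"] < 0) | (df["idotp"] > 1)).any():
        raise ValueError(f"{path}: idotp outside [0, 1]")
    return df


def write_quant_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["rt_match"] = out["rt_match"].astype(int)
    out[QUANT_COLUMNS].to_csv(path, index=False)


def write_matrix(df: pd.DataFrame, path: str | Path, units: str = "percent") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# units: {units}\n")
        df.to_csv(fh, sep="\t", index_label="sample")


def read_matrix(path: str | Path) -> tuple[pd.DataFrame, str]:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    units, skip = "", 0
    if first.startswith("# units:"):
        units, skip = first.split(":", 1)[1].strip(), 1
    with open(path, encoding="utf-8") as fh:
        for _ in range(skip):
            fh.readline()
        header = fh.readline().rstrip("\n").split("\t")
    dupes = {c for c in header if header.count(c) > 1}
    if dupes:
        raise ValueError(f"{path}: duplicated glycan/feature column(s) {sorted(dupes)}")
    df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip)
    df.index.name = None
    return df.astype(float), units


def write_trait_matrix(tm: TraitMatrix, path: str | Path) -> None:
    """TSV of trait values plus a sidecar ``<path>.meta.json`` of trait metadata."""
    write_matrix(tm.values, path, units="percent_or_ratio")
    meta = tm.metadata().to_dict(orient="records")
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_expression(path: str | Path) -> pd.DataFrame:
    df, _ = read_matrix(path)
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    write_matrix(df, path, units="log2_expression")


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, ["sample", "fab"], path)
    return df.set_index("sample")


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.reset_index().to_csv(path, index=False)


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated cohort in the dialects the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "quant": outdir / "quant.csv",
        "annotation": outdir / "annotation.csv",
        "expression": outdir / "expression.tsv",
        "metadata": outdir / "metadata.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_quant_table(cohort.quant, paths["quant"])
    cohort.annotation.to_csv(paths["annotation"], index=False)
    write_expression(cohort.expression, paths["expression"])
    write_metadata(cohort.metadata, paths["metadata"])
    cohort.truth.to_json(paths["ground_truth"])
    return paths
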