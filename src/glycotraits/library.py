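"""Loading and writing glycan annotation tables, plus the packaged library.

The annotation table is a flat CSV, one row per glycan, with the structural
annotation spread across fixed columns (booleans as 0/1). The packaged
default library is a curated synthetic reference set covering the glycan
types and derived traits seen in myeloid cell line panels: oligomannose
(incl. phosphorylated), paucimannose, hybrid, and complex N-glycans up to
tetra-antennary with bisection, core/antennary fucosylation, (s)Lewis x/a
epitopes and LacNAc repeats, and core 1 / core 2 O-glycans with T antigen,
sialyl-/disialyl-T, H antigen, sulfation and a2,3/a2,6/a2,8 sialylation.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .glycan_model import (
    GlycanRecord,
    StructureAnnotation,
    parse_glycan_name,
    validate_library,
)

ANNOTATION_COLUMNS = [
    "name",
    "glycan_class",
    "glycan_type",
    "antennae",
    "bisecting",
    "core_fucose",
    "antennary_fucose",
    "sia_a23",
    "sia_a26_gal",
    "sia_a26_core",
    "sia_a28",
    "sia_unknown",
    "lacnac_repeats",
    "sulfo_sites",
    "has_H_antigen",
    "has_T_antigen",
    "has_sLex_a",
    "has_Lex_a",
]

_BOOL_COLS = ["bisecting", "has_H_antigen", "has_T_antigen", "has_sLex_a", "has_Lex_a"]
_INT_COLS = [
    "antennae", "core_fucose", "antennary_fucose", "sia_a23", "sia_a26_gal",
    "sia_a26_core", "sia_a28", "sia_unknown", "lacnac_repeats", "sulfo_sites",
]


def records_from_frame(df: pd.DataFrame, validate: bool = True) -> list[GlycanRecord]:
    """Build GlycanRecords from an annotation table (see ANNOTATION_COLUMNS)."""
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        rec = parse_glycan_name(str(row["name"]), glycan_class=str(row["glycan_class"]))
        ann = StructureAnnotation(
            glycan_type=str(row["glycan_type"]),
            **{c: int(row[c]) for c in _INT_COLS},
            **{c: bool(int(row[c])) for c in _BOOL_COLS},
        )
        records.append(GlycanRecord(
            name=rec.name, composition=rec.composition,
            glycan_class=rec.glycan_class, isomer=rec.isomer, annotation=ann,
        ))
    if validate:
        violations = [v for v in validate_library(records) if "warning" not in v]
        if violations:
            raise ValueError("invalid annotation table:\n" + "\n".join(violations))
    return records


def frame_from_records(records: list[GlycanRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        ann = rec.annotation
        if ann is None:
            raise ValueError(f"{rec.name}: record has no annotation")
        row = {"name": rec.name, "glycan_class": rec.glycan_class, "glycan_type": ann.glycan_type}
        for c in _INT_COLS:
            row[c] = getattr(ann, c)
        for c in _BOOL_COLS:
            row[c] = int(getattr(ann, c))
        rows.append(row)
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def read_annotation_table(path: str | Path) -> list[GlycanRecord]:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return records_from_frame(pd.read_csv(path, sep=sep))


def write_annotation_table(records: list[GlycanRecord], path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    frame_from_records(records).to_csv(path, sep=sep, index=False)


def default_library() -> list[GlycanRecord]:
    """The packaged curated glycan library (41 N-glycans, 20 O-glycans)."""
    with resources.files("glycotraits.data").joinpath("glycan_library.csv").open() as fh:
        return records_from_frame(pd.read_csv(fh))
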