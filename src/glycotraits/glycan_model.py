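"""Glycan compositions, structural annotations, and the curated glycan library.

Glycan species are abbreviated by monosaccharide composition: hexose (H),
N-acetylhexosamine (N), fucose/deoxyhexose (F), N-acetylneuraminic acid (S),
phosphorylation (P), and sulfation (Su), e.g. ``H5N4F1S2``. Co-eluting
compositional isomers resolved by chromatography carry a single lowercase
letter suffix in elution order (``H5N4S2a``, ``H5N4S2b``).

Structural information beyond the composition (glycan type, antennarity,
sialic acid linkages, Lewis-type epitopes, ...) lives in a
:class:`StructureAnnotation` that is curated per glycan, since the
composition alone cannot encode linkage-level detail. Consistency between a
composition and its annotation is enforced by :func:`validate_annotation`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields, replace
from typing import Iterable

__all__ = [
    "GlycanComposition",
    "StructureAnnotation",
    "GlycanRecord",
    "GlycanParseError",
    "parse_glycan_name",
    "emit_glycan_name",
    "alditol_mass",
    "classify_by_composition",
    "validate_annotation",
    "N_GLYCAN_TYPES",
    "O_GLYCAN_TYPES",
]

# Monoisotopic residue masses (Da) of glycan building blocks as incorporated
# in a chain (condensed, i.e. free monosaccharide minus water), plus the
# termini of a borohydride-reduced (alditol) free glycan.
RESIDUE_MASS = {
    "hex": 162.0528234315,      # Hex (C6H10O5)
    "hexnac": 203.0793725337,   # HexNAc (C8H13NO5)
    "fuc": 146.0579088094,      # dHex (C6H10O4)
    "neuac": 291.0954165066,    # NeuAc (C11H17NO8)
    "phospho": 79.9663304084,   # HPO3
    "sulfo": 79.9568145563,     # SO3
}
MASS_H2O = 18.0105646863
MASS_H2 = 2.0156500642
#: terminus mass of a reduced free glycan: condensation water + 2H from reduction
ALDITOL_TERMINUS = MASS_H2O + MASS_H2

N_GLYCAN_TYPES = ("oligomannose", "paucimannose", "hybrid", "complex")
O_GLYCAN_TYPES = ("core1", "core2")

# token -> composition slot; "Su" must be tried before "S"
_TOKEN_SLOT = {"H": "hex", "N": "hexnac", "F": "fuc", "S": "neuac", "P": "phospho", "Su": "sulfo"}
_EMIT_ORDER = ("H", "N", "F", "S", "P", "Su")
_TOKEN_RE = re.compile(r"(Su|H|N|F|S|P)(\d+)")


class GlycanParseError(ValueError):
    """Raised when a glycan name does not parse as a composition string."""


@dataclass(frozen=True)
class GlycanComposition:
    """Monosaccharide/modification counts of one glycan.

    All counts are non-negative; any real glycan has at least one HexNAc
    (N-glycans at least two, for the chitobiose core).
    """

    hex: int = 0
    hexnac: int = 0
    fuc: int = 0
    neuac: int = 0
    phospho: int = 0
    sulfo: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"composition count {f.name!r} must be a non-negative integer, got {v!r}")

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        return GlycanComposition(**{f.name: getattr(self, f.name) + getattr(other, f.name) for f in fields(self)})

    def total_residues(self) -> int:
        return self.hex + self.hexnac + self.fuc + self.neuac


@dataclass(frozen=True)
class StructureAnnotation:
    """Curated structural features of a glycan beyond its composition.

    For N-glycans ``glycan_type`` is one of oligomannose / paucimannose /
    hybrid / complex; for O-glycans core1 / core2. Sialic acid counts are
    split by glycosidic linkage (a2,3 and a2,6 onto terminal galactose or,
    for O-glycans, the core GalNAc; a2,8 extending another sialic acid;
    linkages unresolvable by chromatography or digestion go to
    ``sia_unknown``). Fucoses are split into core vs antennary; the latter
    underlie Lewis-type and H antigens.
    """

    glycan_type: str
    antennae: int = 0
    bisecting: bool = False
    core_fucose: int = 0
    antennary_fucose: int = 0
    sia_a23: int = 0
    sia_a26_gal: int = 0
    sia_a26_core: int = 0
    sia_a28: int = 0
    sia_unknown: int = 0
    lacnac_repeats: int = 0
    sulfo_sites: int = 0
    has_H_antigen: bool = False
    has_T_antigen: bool = False
    has_sLex_a: bool = False
    has_Lex_a: bool = False

    def sia_total(self) -> int:
        return self.sia_a23 + self.sia_a26_gal + self.sia_a26_core + self.sia_a28 + self.sia_unknown


@dataclass(frozen=True)
class GlycanRecord:
    """One curated glycan: name, composition, class, and optional annotation."""

    name: str
    composition: GlycanComposition
    glycan_class: str  # "N" or "O"
    isomer: str | None = None
    annotation: StructureAnnotation | None = None
    retention_order_key: float | None = None

    def __post_init__(self) -> None:
        if self.glycan_class not in ("N", "O"):
            raise ValueError(f"glycan_class must be 'N' or 'O', got {self.glycan_class!r}")

    @property
    def column_id(self) -> str:
        """Class-qualified identifier (``N:H5N4S2a``); the same composition
        string may name both an N- and an O-glycan."""
        return f"{self.glycan_class}:{self.name}"

    @property
    def glycan_type(self) -> str | None:
        """Curated glycan type if annotated, else the composition default."""
        if self.annotation is not None:
            return self.annotation.glycan_type
        try:
            return classify_by_composition(self.composition, self.glycan_class)
        except ValueError:
            return None


def parse_glycan_name(name: str, glycan_class: str = "N") -> GlycanRecord:
    """Parse a composition string such as ``H5N4F1S2a`` into a record.

    Tokens (H, N, F, S, P, Su) may appear in any order, each at most once,
    each with a positive count; an optional single lowercase letter suffix
    names the isomer. The returned record has no structural annotation.

    Raises
    ------
    GlycanParseError
        On unknown tokens, duplicated tokens, zero counts, or a suffix
        longer than one letter.
    """
    if not isinstance(name, str) or not name:
        raise GlycanParseError("empty glycan name")
    body, isomer = name, None
    # strip one trailing lowercase isomer letter; two or more is an error
    m = re.search(r"[a-z]+$", body)
    if m:
        if len(m.group(0)) > 1:
            raise GlycanParseError(f"{name!r}: multi-letter isomer suffix {m.group(0)!r}")
        isomer = m.group(0)
        body = body[: m.start()]
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(body):
        m = _TOKEN_RE.match(body, pos)
        if m is None:
            raise GlycanParseError(f"{name!r}: unrecognized token at {body[pos:]!r}")
        tok, cnt = m.group(1), int(m.group(2))
        slot = _TOKEN_SLOT[tok]
        if slot in counts:
            raise GlycanParseError(f"{name!r}: duplicated token {tok!r}")
        if cnt <= 0:
            raise GlycanParseError(f"{name!r}: non-positive count for token {tok!r}")
        counts[slot] = cnt
        pos = m.end()
    comp = GlycanComposition(**counts)
    return GlycanRecord(name=name, composition=comp, glycan_class=glycan_class, isomer=isomer)


def emit_glycan_name(composition: GlycanComposition, isomer: str | None = None) -> str:
    """Format a composition (plus optional isomer letter) in canonical H,N,F,S,P,Su order."""
    parts = []
    for tok in _EMIT_ORDER:
        cnt = getattr(composition, _TOKEN_SLOT[tok])
        if cnt:
            parts.append(f"{tok}{cnt}")
    return "".join(parts) + (isomer or "")


def alditol_mass(composition: GlycanComposition) -> float:
    """Monoisotopic mass (Da) of the reduced (alditol) free glycan.

    The analyte form in porous graphitized carbon LC-MS of released glycans
    is the borohydride-reduced alditol; its mass is the sum of condensed
    residue masses plus water plus two reduction hydrogens.
    """
    total = ALDITOL_TERMINUS
    for slot, mass in RESIDUE_MASS.items():
        total += getattr(composition, slot) * mass
    return total


def classify_by_composition(composition: GlycanComposition, glycan_class: str) -> str:
    """Default glycan type from composition alone.

    N-glycans: paucimannose (truncated, HexNAc2 Hex<=3, optional single core
    fucose, no sialic acid), oligomannose (HexNAc2 Hex4-9, unfucosylated,
    nonsialylated; phosphorylated species stay oligomannose), hybrid
    (HexNAc3 with Hex>=4), else complex. O-glycans: core1 (single HexNAc,
    the core GalNAc) vs core2 (branching GlcNAc present); core 3/4 are not
    modeled.

    Used only when no curated annotation is available; curation based on
    fragmentation evidence overrides it.
    """
    c = composition
    if glycan_class == "N":
        if c.hexnac < 2:
            raise ValueError("N-glycan requires hexnac >= 2 (chitobiose core)")
        if c.hexnac == 2 and c.hex <= 3 and c.fuc <= 1 and c.neuac == 0:
            return "paucimannose"
        if c.hexnac == 2 and 4 <= c.hex <= 9 and c.fuc == 0 and c.neuac == 0:
            return "oligomannose"
        if c.hexnac == 3 and c.hex >= 4:
            return "hybrid"
        return "complex"
    if glycan_class == "O":
        if c.hexnac < 1:
            raise ValueError("O-glycan requires hexnac >= 1 (core GalNAc)")
        return "core1" if c.hexnac == 1 else "core2"
    raise ValueError(f"unknown glycan class {glycan_class!r}")


def validate_annotation(record: GlycanRecord) -> list[str]:
    """Check a record's annotation against its composition and class.

    Returns a list of human-readable violation messages (empty if the record
    is internally consistent). All violations are reported, not just the
    first; a curated glycan_type that disagrees with the composition-based
    default where the composition is decisive is reported as a warning-level
    violation rather than an error, since curation may rest on fragmentation
    evidence the composition cannot encode.
    """
    ann = record.annotation
    if ann is None:
        raise ValueError(f"{record.name}: no annotation to validate")
    comp = record.composition
    out: list[str] = []

    allowed = N_GLYCAN_TYPES if record.glycan_class == "N" else O_GLYCAN_TYPES
    if ann.glycan_type not in allowed:
        out.append(f"{record.name}: glycan_type {ann.glycan_type!r} invalid for class {record.glycan_class}")

    if ann.sia_total() != comp.neuac:
        out.append(
            f"{record.name}: sialic-linkage counts sum to {ann.sia_total()} "
            f"but composition has {comp.neuac} NeuAc"
        )
    if ann.core_fucose + ann.antennary_fucose != comp.fuc:
        out.append(
            f"{record.name}: fucose split {ann.core_fucose}+{ann.antennary_fucose} "
            f"!= composition {comp.fuc}"
        )
    if ann.sulfo_sites != comp.sulfo:
        out.append(f"{record.name}: sulfo_sites {ann.sulfo_sites} != composition {comp.sulfo}")
    if record.glycan_class == "O":
        if ann.bisecting:
            out.append(f"{record.name}: O-glycans cannot be bisected")
        if ann.antennae:
            out.append(f"{record.name}: O-glycans carry no antenna count")
        if ann.sia_a26_gal:
            out.append(f"{record.name}: a2,6 sialylation on terminal Gal is an N-glycan slot")
    else:
        if ann.sia_a26_core:
            out.append(f"{record.name}: a2,6 sialylation on core GalNAc is an O-glycan slot")
        if ann.has_T_antigen:
            out.append(f"{record.name}: T antigen is an O-glycan (core 1) feature")
    if ann.has_sLex_a and (ann.antennary_fucose < 1 or comp.neuac < 1):
        out.append(f"{record.name}: sLex/a requires antennary fucose and sialic acid")
    if ann.has_Lex_a and ann.antennary_fucose < 1:
        out.append(f"{record.name}: Lex/a requires antennary fucose")
    if ann.has_T_antigen and (comp.neuac > 0 or comp.hexnac != 1 or comp.hex != 1):
        out.append(f"{record.name}: T antigen is the nonsialylated core 1 disaccharide")
    if ann.has_H_antigen and ann.antennary_fucose < 1:
        out.append(f"{record.name}: H antigen requires a terminal (non-core) fucose")
    if ann.antennae < 0 or ann.lacnac_repeats < 0:
        out.append(f"{record.name}: negative structural counts")

    # agreement with the composition default where the composition is decisive
    try:
        default = classify_by_composition(comp, record.glycan_class)
    except ValueError as exc:
        out.append(f"{record.name}: composition invalid for class ({exc})")
    else:
        decisive = record.glycan_class == "O" or default in ("oligomannose", "paucimannose", "hybrid")
        if record.glycan_class == "N" and default == "complex" and comp.hexnac >= 4:
            decisive = True
        if decisive and ann.glycan_type != default and ann.glycan_type in allowed:
            out.append(
                f"{record.name}: warning: curated type {ann.glycan_type!r} disagrees with "
                f"composition default {default!r}"
            )
    return out


def validate_library(records: Iterable[GlycanRecord]) -> list[str]:
    """Validate a whole library: per-record annotation checks plus uniqueness
    of names and of isomer letters within each (composition, class) group."""
    records = list(records)
    out: list[str] = []
    seen_names: set[tuple[str, str]] = set()
    seen_isomers: dict[tuple, set[str]] = {}
    for rec in records:
        if (rec.glycan_class, rec.name) in seen_names:
            out.append(f"duplicate glycan name {rec.name!r} in class {rec.glycan_class}")
        seen_names.add((rec.glycan_class, rec.name))
        key = (emit_glycan_name(rec.composition), rec.glycan_class)
        group = seen_isomers.setdefault(key, set())
        iso = rec.isomer or ""
        if iso in group:
            out.append(f"{rec.name}: duplicate isomer label within {key[0]} ({rec.glycan_class})")
        group.add(iso)
        if rec.annotation is not None:
            out.extend(validate_annotation(rec))
    return out
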