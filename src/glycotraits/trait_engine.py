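"""Derived glycan traits: grouping individual glycans into structural features.

Individual glycan fractional abundances carry structural information only
implicitly; derived traits make it explicit by pooling glycans that share a
feature (a glycan type, an epitope such as sialyl-Lewis x/a, a linkage class
of sialylation, ...). A percentage trait is the summed abundance of its
member glycans over a denominator set, x100; a ratio trait (core1:core2)
divides two member sums directly.

Matrices are indexed by class-qualified glycan ids (``N:H5N4S2a``,
``O:H1N1S2``) because the same composition string can occur in both
classes. Trait names are likewise prefixed (``N_paucimannose``,
``O_sia_a28``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .glycan_model import GlycanRecord

__all__ = ["TraitDefinition", "TraitMatrix", "builtin_traits", "derive_traits", "fab_group_summary"]

Predicate = Callable[[GlycanRecord], int]


@dataclass(frozen=True)
class TraitDefinition:
    """One derived trait.

    ``count`` maps a glycan record to its number of trait occurrences
    (0 = not a member). With ``weight='presence'`` a member glycan
    contributes its full abundance once; with ``'count'`` the abundance is
    multiplied by the occurrence count (relevant for multiply sialylated
    glycans). ``denominator`` is one of ``total_class``, ``complex_only``,
    ``complex_hybrid``, or a predicate naming the denominator member set
    (used by ratio traits).
    """

    trait_name: str
    glycan_class: str  # "N" or "O"
    count: Predicate
    weight: str = "presence"  # or "count"
    denominator: str | Predicate = "total_class"
    output: str = "percentage"  # or "ratio"
    description: str = ""

    def occurrences(self, rec: GlycanRecord) -> int:
        if rec.glycan_class != self.glycan_class:
            return 0
        return int(self.count(rec))


@dataclass
class TraitMatrix:
    """Samples x derived-trait values with trait metadata attached."""

    values: pd.DataFrame
    traits: list[TraitDefinition] = field(default_factory=list)

    @property
    def trait_names(self) -> list[str]:
        return list(self.values.columns)

    def metadata(self) -> pd.DataFrame:
        rows = []
        for t in self.traits:
            denom = t.denominator if isinstance(t.denominator, str) else "member_set"
            rows.append({
                "trait_name": t.trait_name, "glycan_class": t.glycan_class,
                "weight": t.weight, "denominator": denom, "output": t.output,
                "description": t.description,
            })
        return pd.DataFrame(rows)


def _ann(rec: GlycanRecord):
    if rec.annotation is None:
        raise ValueError(f"{rec.name}: trait derivation requires an annotated record")
    return rec.annotation


def builtin_traits() -> list[TraitDefinition]:
    """The default derived-trait panel.

    N-glycans: the four glycan types, phosphorylation, bisection, core
    fucosylation, pooled (s)Lewis x/a, antennarity (glycans with >=3
    antennae), total sialylation, and linkage-resolved a2,3 / a2,6
    (terminal Gal) sialylation. O-glycans: core distribution (core1, core2
    and their ratio), T / sialyl-T / disialyl-T antigens, Lewis x/a and
    sialyl-Lewis x/a kept separate, H antigen, sulfation, LacNAc extension,
    and a2,3 / a2,6 (core GalNAc) / a2,8 sialylation.

    Sialic acids of undetermined linkage count toward total sialylation but
    toward no linkage-specific trait.
    """
    N = "N"
    O = "O"

    def d(name, cls, count, weight="presence", denominator="total_class", output="percentage", desc=""):
        return TraitDefinition(name, cls, count, weight, denominator, output, desc)

    is_type = lambda t: (lambda r: int(_ann(r).glycan_type == t))
    traits = [
        d("N_oligomannose", N, is_type("oligomannose"), desc="oligomannose-type glycans (incl. phosphorylated)"),
        d("N_paucimannose", N, is_type("paucimannose"), desc="truncated paucimannosidic glycans"),
        d("N_hybrid", N, is_type("hybrid"), desc="hybrid-type glycans"),
        d("N_complex", N, is_type("complex"), desc="complex-type glycans"),
        d("N_phosphorylation", N, lambda r: r.composition.phospho, desc="mannose-6-phosphate-type phosphorylation"),
        d("N_bisection", N, lambda r: int(_ann(r).bisecting), desc="bisecting GlcNAc"),
        d("N_core_fucosylation", N, lambda r: _ann(r).core_fucose, desc="core a1,6 fucosylation"),
        d("N_sLex_a", N, lambda r: int(_ann(r).has_sLex_a or _ann(r).has_Lex_a),
          desc="pooled (sialyl-)Lewis x/a epitopes on antennae"),
        d("N_antennarity", N, lambda r: int(_ann(r).antennae >= 3), desc="tri- and tetra-antennary glycans"),
        d("N_total_sialylation", N, lambda r: r.composition.neuac, desc="any sialylation, all linkages"),
        d("N_sia_a23", N, lambda r: _ann(r).sia_a23, desc="a2,3-linked sialylation"),
        d("N_sia_a26_gal", N, lambda r: _ann(r).sia_a26_gal, desc="a2,6 sialylation on terminal galactose"),
        d("O_core1", O, is_type("core1"), desc="core 1 O-glycans"),
        d("O_core2", O, is_type("core2"), desc="core 2 O-glycans"),
        d("O_core1_core2_ratio", O, is_type("core1"), denominator=is_type("core2"), output="ratio",
          desc="core1:core2 abundance ratio"),
        d("O_T_antigen", O, lambda r: int(_ann(r).has_T_antigen), desc="nonsialylated core 1 (T antigen)"),
        d("O_sialyl_T", O, lambda r: int(_ann(r).glycan_type == "core1" and r.composition.neuac == 1
                                         and r.composition.fuc == 0 and r.composition.sulfo == 0),
          desc="monosialylated core 1 (sialyl-T antigen)"),
        d("O_disialyl_T", O, lambda r: int(_ann(r).glycan_type == "core1" and r.composition.neuac == 2
                                           and _ann(r).sia_a28 == 0 and r.composition.fuc == 0),
          desc="disialylated core 1 (disialyl-T antigen)"),
        d("O_Lex_a", O, lambda r: int(_ann(r).has_Lex_a), desc="neutral Lewis x/a epitopes"),
        d("O_sLex_a", O, lambda r: int(_ann(r).has_sLex_a), desc="sialyl-Lewis x/a epitopes"),
        d("O_H_antigen", O, lambda r: int(_ann(r).has_H_antigen), desc="H (blood group O) antigen"),
        d("O_sulfation", O, lambda r: r.composition.sulfo, desc="sulfated glycans"),
        d("O_lacnac_extension", O, lambda r: int(_ann(r).lacnac_repeats >= 1), desc="LacNAc repeat extension"),
        d("O_sia_a23", O, lambda r: _ann(r).sia_a23, desc="a2,3-linked sialylation"),
        d("O_sia_a26_core", O, lambda r: _ann(r).sia_a26_core, desc="a2,6 sialylation on the core GalNAc"),
        d("O_sia_a28", O, lambda r: _ann(r).sia_a28, desc="a2,8 sialylation extending another sialic acid"),
    ]
    return traits


def _denominator_ids(trait: TraitDefinition, records: dict[str, GlycanRecord]) -> list[str]:
    same_class = [cid for cid, r in records.items() if r.glycan_class == trait.glycan_class]
    if callable(trait.denominator):
        return [cid for cid in same_class if trait.denominator(records[cid])]
    if trait.denominator == "total_class":
        return same_class
    if trait.denominator == "complex_only":
        return [cid for cid in same_class if _ann(records[cid]).glycan_type == "complex"]
    if trait.denominator == "complex_hybrid":
        return [cid for cid in same_class if _ann(records[cid]).glycan_type in ("complex", "hybrid")]
    raise ValueError(f"unknown denominator spec {trait.denominator!r}")


def derive_traits(
    abundances: pd.DataFrame,
    library: list[GlycanRecord],
    traits: list[TraitDefinition] | None = None,
) -> TraitMatrix:
    """Compute the derived-trait matrix from per-glycan fractional abundances.

    Parameters
    ----------
    abundances : DataFrame
        Samples x glycans, fractional abundances in percent; columns are
        class-qualified glycan ids present in ``library``. Glycans missing
        from a sample (NaN) contribute zero.
    library : list of GlycanRecord
        Annotated records for at least every abundance column.
    traits : list of TraitDefinition, optional
        Defaults to :func:`builtin_traits`.

    Ratio traits with a zero denominator yield NaN (undefined), not an error.
    """
    if traits is None:
        traits = builtin_traits()
    records = {rec.column_id: rec for rec in library}
    unknown = [c for c in abundances.columns if c not in records]
    if unknown:
        raise KeyError(f"abundance columns not in the glycan library: {unknown}")
    A = abundances.fillna(0.0)

    cols = {}
    for trait in traits:
        occ = np.array([trait.occurrences(records[c]) for c in A.columns], dtype=float)
        w = occ if trait.weight == "count" else (occ > 0).astype(float)
        num = A.to_numpy(dtype=float) @ w
        denom_ids = _denominator_ids(trait, records)
        dmask = np.array([c in set(denom_ids) for c in A.columns], dtype=float)
        den = A.to_numpy(dtype=float) @ dmask
        with np.errstate(invalid="ignore", divide="ignore"):
            if trait.output == "ratio":
                val = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
            else:
                val = np.where(den > 0, num / np.where(den > 0, den, 1.0) * 100.0, np.nan)
        cols[trait.trait_name] = val
    values = pd.DataFrame(cols, index=A.index)
    return TraitMatrix(values=values, traits=list(traits))


def fab_group_summary(traits: TraitMatrix | pd.DataFrame, fab_labels: pd.Series) -> pd.DataFrame:
    """Mean trait value per FAB group (groups x traits).

    Every sample must carry a label; single-sample groups return that
    sample's values unchanged. Labels with no matching sample are dropped
    with a warning.
    """
    values = traits.values if isinstance(traits, TraitMatrix) else traits
    fab_labels = fab_labels.reindex(values.index)
    if fab_labels.isna().any():
        missing = list(values.index[fab_labels.isna()])
        raise ValueError(f"samples without FAB label: {missing}")
    if isinstance(fab_labels.dtype, pd.CategoricalDtype):
        unused = set(fab_labels.cat.categories) - set(fab_labels.dropna())
        if unused:
            warnings.warn(f"FAB groups with no samples excluded: {sorted(unused)}")
    return values.groupby(fab_labels, observed=True).mean().sort_index()
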