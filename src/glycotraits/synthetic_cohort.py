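"""Synthetic FAB-structured glycomics + transcriptomics cohorts.

The generator emulates the data model of a released-glycan LC-MS study of a
leukemia cell line panel: per-sample fractional glycan abundances over the
packaged library, peak areas with QC metrics (retention-time match, isotope
dot product, signal-to-noise), a log-scale gene expression table, and FAB
subtype labels - plus the ground truth needed to score every pipeline stage.

Class structure is imposed on the Dirichlet mean: each FAB class has a
target value for a handful of derived traits (e.g. elevated paucimannose
and sialyl-Lewis x/a in M5, elevated bisection/antennarity/a2,8 sialylation
in M6), and member-glycan weights are tilted by iterative proportional
fitting until the class mean attains those targets. Within-class biological
noise is Dirichlet; the concentration parameter sets its size. Gene
expression is generated as a linear response to a driving trait with
Gaussian noise scaled so the population correlation equals the planted
target.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .glycan_model import GlycanRecord
from .library import default_library, frame_from_records
from .trait_engine import TraitDefinition, builtin_traits, derive_traits

__all__ = ["CohortConfig", "GroundTruth", "SimulatedCohort", "simulate_cohort", "score_recovery"]


# Baseline fractional-abundance weights (percent; each class sums to 100)
# for the packaged library: an oligomannose-dominated N-glycome and a
# sialylated core1/core2 O-glycome typical of cultured myeloid cells.
BASELINE_WEIGHTS = {
    # N: paucimannose
    "N:H2N2": 1.5, "N:H2N2F1": 1.0, "N:H3N2": 2.5, "N:H3N2F1": 3.0,
    # N: oligomannose (+ phosphorylated)
    "N:H4N2": 2.0, "N:H5N2": 6.0, "N:H6N2": 9.0, "N:H7N2": 8.0, "N:H8N2": 10.0,
    "N:H9N2": 15.0, "N:H5N2P1": 2.0, "N:H6N2P1": 1.5,
    # N: hybrid
    "N:H4N3": 0.6, "N:H4N3S1": 0.8, "N:H5N3S1": 0.7,
    "N:H4N3F1S1a": 0.3, "N:H4N3F1S1b": 0.3, "N:H4N3F1S1c": 0.3,
    # N: complex
    "N:H3N4F1": 1.2, "N:H4N4F1": 1.3, "N:H5N4": 1.5, "N:H5N4F1": 2.5,
    "N:H5N4S1": 2.5, "N:H5N4S2a": 4.0, "N:H5N4S2b": 3.0, "N:H5N4F1S1": 2.5,
    "N:H5N4F1S2": 3.5, "N:H5N4F2": 0.5, "N:H5N4F2S1": 1.0, "N:H5N4F2S2": 0.7,
    "N:H5N5F1": 0.8, "N:H5N5F1S1": 0.7, "N:H5N5S2": 0.5,
    "N:H6N5S2": 1.5, "N:H6N5S3": 2.0, "N:H6N5F1S3": 0.8, "N:H6N5F2S2": 1.0,
    "N:H7N6S3": 1.2, "N:H7N6S4": 1.5, "N:H7N6F1S4": 0.6, "N:H8N7S4": 0.7,
    # O: core 1
    "O:H1N1": 6.0, "O:H1N1F1": 0.5, "O:H1N1S1a": 18.0, "O:H1N1S1b": 8.0,
    "O:H1N1S2": 25.0, "O:H1N1S3": 1.0,
    # O: core 2
    "O:H2N2": 3.0, "O:H2N2S1a": 6.0, "O:H2N2S1b": 3.0, "O:H2N2S2": 18.0,
    "O:H2N2S3": 1.0, "O:H2N2F1a": 1.0, "O:H2N2F1b": 0.5, "O:H2N2F1S1": 2.0,
    "O:H2N2F1S2": 1.0, "O:H2N2Su1": 0.8, "O:H2N2S1Su1": 1.2,
    "O:H3N3S1": 2.5, "O:H3N3F1": 0.5, "O:H3N3F1S1": 1.0,
}

#: default per-class derived-trait targets (percent on the total-class
#: denominator), encoding the qualitative FAB contrasts: monocytic classes
#: (M4/M5) high in paucimannose, hybrid and (s)Lewis x/a; erythroid M6 high
#: in bisection, antennarity, sialylation and a2,8 sialylation (absent in
#: M2/M3); promyelocytic M3 high in phosphorylation and H antigen; the
#: megakaryoblastic M7 line with striking O-glycan sialyl-Lewis x/a.
DEFAULT_TRAIT_EFFECTS: dict[str, dict[str, float]] = {
    "M2": {"N_sLex_a": 1.5, "N_bisection": 3.0, "O_sia_a28": 0.0,
           "O_core1": 55.0, "O_Lex_a": 1.8, "O_T_antigen": 7.0},
    "M3": {"N_phosphorylation": 12.1, "N_bisection": 4.2, "N_paucimannose": 4.2,
           "N_core_fucosylation": 16.2, "N_sLex_a": 0.8, "O_sia_a28": 0.0,
           "O_H_antigen": 1.2, "O_core1": 58.0},
    "M4": {"N_paucimannose": 12.0, "N_antennarity": 10.4, "N_sLex_a": 2.0,
           "O_sia_a28": 1.0, "O_sLex_a": 5.0, "O_core1": 50.0},
    "M5": {"N_paucimannose": 17.7, "N_hybrid": 5.0, "N_sLex_a": 2.5, "N_bisection": 0.5,
           "O_sLex_a": 8.0, "O_sia_a28": 1.5, "O_core1": 45.0},
    "M6": {"N_paucimannose": 7.0, "N_bisection": 7.3, "N_antennarity": 19.7,
           "N_total_sialylation": 40.0, "N_sLex_a": 0.9, "O_sia_a28": 5.4,
           "O_sia_a26_core": 48.0, "O_core1": 62.2, "O_sLex_a": 1.1, "O_T_antigen": 8.0},
    "M7": {"N_sLex_a": 2.8, "O_sLex_a": 12.3, "O_sia_a28": 2.0, "O_core1": 50.0},
}

#: (gene, driving trait, target correlation); glycosyltransferases first,
#: then hematopoietic transcription factors.
DEFAULT_GENE_LINKS: list[tuple[str, str, float]] = [
    ("ST8SIA6", "O_sia_a28", 0.96),
    ("ST6GALNAC1", "O_sia_a26_core", 0.48),
    ("ST6GALNAC5", "O_sia_a26_core", 0.52),
    ("ST3GAL1", "N_sia_a23", 0.24),
    ("FUT7", "N_sLex_a", 0.38),
    ("FUT9", "O_sLex_a", 0.51),
    ("FUT6", "O_sLex_a", -0.54),
    ("FUT1", "O_H_antigen", 0.45),
    ("MGAT5", "N_antennarity", 0.60),
    ("MGAT4A", "N_antennarity", 0.55),
    ("GCNT3", "O_core2", 0.44),
    ("TAL1", "O_sia_a28", 0.91),
    ("GATA1", "O_sia_a28", 0.89),
    ("SPI1", "O_sia_a28", -0.65),
    ("CEBPA", "O_sia_a28", -0.74),
    ("GATA2", "N_total_sialylation", 0.50),
    ("CBFA2T3", "N_total_sialylation", 0.45),
    ("GATA3", "N_sLex_a", -0.46),
]

#: genes emitted with no planted trait linkage (true correlation 0)
DEFAULT_UNLINKED_GENES = ["FUT3", "MAN1A1", "MAN2A1", "ST6GAL1", "MGAT3"]

DEFAULT_CLASS_SIZES = {"M2": 3, "M3": 1, "M4": 4, "M5": 7, "M6": 5, "M7": 1}


@dataclass
class CohortConfig:
    """Everything needed to draw one cohort; the seed makes it reproducible."""

    seed: int
    class_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_SIZES))
    trait_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRAIT_EFFECTS.items()})
    dirichlet_concentration: float = 500.0
    technical_concentration: float = 10000.0
    missingness_rate: float = 0.02
    qc_failure_rate: float = 0.05
    n_replicates: int = 3
    replicate_sample: str | None = None  # default: first sample of the largest class
    gene_links: list[tuple[str, str, float]] = field(
        default_factory=lambda: list(DEFAULT_GENE_LINKS))
    unlinked_genes: list[str] = field(default_factory=lambda: list(DEFAULT_UNLINKED_GENES))
    expression_baseline_range: tuple[float, float] = (3.0, 9.0)
    expression_spread: float = 1.0

    def __post_init__(self):
        if self.dirichlet_concentration <= 0 or self.technical_concentration <= 0:
            raise ValueError("Dirichlet concentrations must be > 0")
        for gene, trait, r in self.gene_links:
            if not -1 < r < 1:
                raise ValueError(f"target correlation for {gene} must be in (-1, 1), got {r}")
        for rate in (self.missingness_rate, self.qc_failure_rate):
            if not 0 <= rate < 1:
                raise ValueError("rates must be in [0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if "seed" not in data:
            raise ValueError("cohort config must specify a seed")
        if "gene_links" in data:
            data["gene_links"] = [tuple(x) for x in data["gene_links"]]
        return cls(**data)


@dataclass
class GroundTruth:
    """What the generator planted, serialized alongside the cohort."""

    fab_labels: dict[str, str]
    planted_correlations: list[dict]          # {gene, trait, r}
    class_trait_means: dict[str, dict[str, float]]   # achieved targets per class
    ipf_residuals: dict[str, dict[str, float]]
    missing_cells: list[tuple[str, str]]      # (sample, glycan id)
    qc_failed_cells: list[tuple[str, str]]
    replicate_sample: str | None
    seed: int

    def to_json(self, path: str | Path) -> None:
        data = asdict(self)
        data["missing_cells"] = [list(t) for t in self.missing_cells]
        data["qc_failed_cells"] = [list(t) for t in self.qc_failed_cells]
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        data["missing_cells"] = [tuple(t) for t in data["missing_cells"]]
        data["qc_failed_cells"] = [tuple(t) for t in data["qc_failed_cells"]]
        return cls(**data)


@dataclass
class SimulatedCohort:
    quant: pd.DataFrame          # long table: sample, replicate, glycan, area, rt_match, idotp, snr
    annotation: pd.DataFrame     # glycan annotation table
    expression: pd.DataFrame     # samples x genes, log-scale
    metadata: pd.DataFrame       # sample, fab
    truth: GroundTruth
    fractions: pd.DataFrame      # true per-sample fractional abundances (pre-noise floor)


# ---------------------------------------------------------------------------
# class-mean construction

def _trait_members(trait: TraitDefinition, records: dict[str, GlycanRecord]) -> list[str]:
    return [cid for cid, r in records.items()
            if r.glycan_class == trait.glycan_class and trait.occurrences(r) > 0]


def check_effect_feasibility(trait_effects: dict[str, dict[str, float]]) -> None:
    """Reject effect tables that violate closure before any sampling."""
    type_groups = {
        "N": ["N_oligomannose", "N_paucimannose", "N_hybrid", "N_complex"],
        "O": ["O_core1", "O_core2"],
    }
    for cls_label, targets in trait_effects.items():
        for name, val in targets.items():
            if not 0 <= val <= 100:
                raise ValueError(f"{cls_label}: target {name}={val} outside [0, 100]")
        for gclass, group in type_groups.items():
            named = [targets[t] for t in group if t in targets]
            if len(named) == len(group) and abs(sum(named) - 100.0) > 0.1:
                raise ValueError(f"{cls_label}: {gclass}-type targets do not close to 100%")
            if sum(named) > 100.0 + 1e-9:
                raise ValueError(f"{cls_label}: {gclass}-type targets exceed 100%")


def fit_class_weights(
    targets: dict[str, float],
    library: list[GlycanRecord],
    baseline: dict[str, float] | None = None,
    n_iter: int = 400,
) -> tuple[pd.Series, dict[str, float]]:
    """Tilt baseline glycan weights until derived traits hit their targets.

    Iterative proportional fitting: for each targeted trait, scale its
    member glycans toward the target share and the non-members toward the
    complement, renormalizing within glycan class; repeat until the largest
    deviation stalls. Returns the adjusted weights (percent per class) and
    the per-trait residuals (achieved - target, percentage points).
    """
    if baseline is None:
        baseline = BASELINE_WEIGHTS
    records = {r.column_id: r for r in library}
    traits = {t.trait_name: t for t in builtin_traits()}
    unknown = set(targets) - set(traits)
    if unknown:
        raise KeyError(f"unknown trait(s) in effect table: {sorted(unknown)}")
    ids = list(records)
    w = np.array([baseline.get(cid, 0.0) for cid in ids], dtype=float)
    class_masks = {cls: np.array([c.startswith(cls + ":") for c in ids]) for cls in ("N", "O")}

    def renorm(ws: np.ndarray) -> np.ndarray:
        for m in class_masks.values():
            tot = ws[m].sum()
            if tot > 0:
                ws[m] = ws[m] / tot * 100.0
        return ws

    w = renorm(w)
    pct_targets = {k: v for k, v in sorted(targets.items()) if traits[k].output == "percentage"
                   and traits[k].denominator == "total_class"}
    member_masks = {
        name: np.array([cid in set(_trait_members(traits[name], records)) for cid in ids])
        for name in pct_targets
    }

    for _ in range(n_iter):
        delta = 0.0
        for name, target in pct_targets.items():
            mem = member_masks[name]
            oth = class_masks[traits[name].glycan_class] & ~mem
            cur = w[mem].sum()
            delta = max(delta, abs(cur - target))
            if target <= 0:
                w[mem] = 0.0
            elif cur <= 0:
                raise ValueError(f"target {name}={target} unreachable: no member glycan has weight")
            else:
                w[mem] *= target / cur
                rest = w[oth].sum()
                if rest > 0:
                    w[oth] *= (100.0 - target) / rest
            w = renorm(w)
        if delta < 1e-10:
            break
    w = pd.Series(w, index=ids)

    achieved = derive_traits(w.to_frame().T.set_axis(["mean"]), library)
    residuals = {}
    for name, target in pct_targets.items():
        got = float(achieved.values.loc["mean", name])
        residuals[name] = got - target
        if abs(got - target) > 0.5:
            warnings.warn(f"IPF residual {name}: achieved {got:.2f} vs target {target:.2f}")
    return w, residuals


# ---------------------------------------------------------------------------
# cohort sampling

def simulate_cohort(config: CohortConfig, library: list[GlycanRecord] | None = None) -> SimulatedCohort:
    """Draw one cohort: quant table, annotation, expression, metadata, truth."""
    if library is None:
        library = default_library()
    check_effect_feasibility(config.trait_effects)
    rng = np.random.default_rng(config.seed)
    records = {r.column_id: r for r in library}
    columns = list(records)
    by_class = {"N": [c for c in columns if c.startswith("N:")],
                "O": [c for c in columns if c.startswith("O:")]}

    # per-class mean abundance vectors and achieved trait means
    class_weights: dict[str, pd.Series] = {}
    residuals: dict[str, dict[str, float]] = {}
    class_trait_means: dict[str, dict[str, float]] = {}
    for cls_label in sorted(config.class_sizes):
        targets = config.trait_effects.get(cls_label, {})
        wts, res = fit_class_weights(targets, library)
        class_weights[cls_label] = wts
        residuals[cls_label] = res
        achieved = derive_traits(wts.to_frame().T.set_axis(["mean"]), library)
        class_trait_means[cls_label] = {
            t: float(achieved.values.loc["mean", t]) for t in achieved.values.columns
        }

    # samples and their true fractional abundances
    sample_ids, fab_labels = [], {}
    for cls_label in sorted(config.class_sizes):
        for i in range(config.class_sizes[cls_label]):
            sid = f"{cls_label}_{i + 1:02d}"
            sample_ids.append(sid)
            fab_labels[sid] = cls_label

    frac = pd.DataFrame(0.0, index=sample_ids, columns=columns)
    for sid in sample_ids:
        w = class_weights[fab_labels[sid]]
        for cls, cols in by_class.items():
            p = w[cols].to_numpy() / 100.0
            pos = p > 0
            alpha = config.dirichlet_concentration * p[pos]
            draw = rng.dirichlet(alpha)
            vec = np.zeros(len(cols))
            vec[pos] = draw * 100.0
            frac.loc[sid, cols] = vec

    largest = max(sorted(config.class_sizes), key=lambda c: config.class_sizes[c])
    rep_sample = config.replicate_sample or f"{largest}_01"

    # long quant table with QC metrics, technical replicates, missingness
    rows = []
    missing_cells: list[tuple[str, str]] = []
    qc_failed: list[tuple[str, str]] = []
    for sid in sample_ids:
        n_reps = config.n_replicates if sid == rep_sample else 1
        for rep in range(1, n_reps + 1):
            rep_id = f"r{rep}"
            for cls, cols in by_class.items():
                base = frac.loc[sid, cols].to_numpy() / 100.0
                pos = base > 0
                if n_reps > 1:
                    vec = np.zeros(len(cols))
                    vec[pos] = rng.dirichlet(config.technical_concentration * base[pos])
                else:
                    vec = np.where(pos, base, 0.0)
                total_area = 10 ** rng.normal(8.0, 0.15)
                for cid, f in zip(cols, vec):
                    if f <= 0:
                        continue
                    if rng.random() < config.missingness_rate:
                        if rep_id == "r1":
                            missing_cells.append((sid, cid))
                        continue
                    fail = rng.random() < config.qc_failure_rate
                    if fail:
                        mode = rng.integers(3)
                        rt = mode != 0
                        idotp = rng.uniform(0.5, 0.849) if mode == 1 else rng.uniform(0.86, 1.0)
                        snr = rng.uniform(0.5, 5.9) if mode == 2 else 10 ** rng.uniform(0.9, 2.5)
                        if mode == 0:
                            idotp, snr = rng.uniform(0.86, 1.0), 10 ** rng.uniform(0.9, 2.5)
                        if rep_id == "r1":
                            qc_failed.append((sid, cid))
                    else:
                        rt, idotp, snr = True, rng.uniform(0.86, 1.0), 10 ** rng.uniform(0.9, 2.5)
                    rows.append({
                        "sample": sid, "replicate": rep_id, "glycan": cid,
                        "area": f * total_area, "rt_match": bool(rt),
                        "idotp": round(float(idotp), 4), "snr": round(float(snr), 2),
                    })
    quant = pd.DataFrame(rows)

    # expression: linear response to the driving trait + Gaussian noise
    traits_true = derive_traits(frac, library).values
    genes = {}
    lo, hi = config.expression_baseline_range
    for gene, trait_name, r in config.gene_links:
        t = traits_true[trait_name].to_numpy(dtype=float)
        sd = t.std(ddof=1)
        z = (t - t.mean()) / sd if sd > 0 else np.zeros_like(t)
        eps = rng.standard_normal(len(t))
        signal = r * z + np.sqrt(1 - r * r) * eps
        genes[gene] = rng.uniform(lo, hi) + config.expression_spread * signal
    for gene in config.unlinked_genes:
        genes[gene] = rng.uniform(lo, hi) + config.expression_spread * rng.standard_normal(len(sample_ids))
    expression = pd.DataFrame(genes, index=sample_ids)

    metadata = pd.DataFrame({"sample": sample_ids,
                             "fab": [fab_labels[s] for s in sample_ids]}).set_index("sample")
    truth = GroundTruth(
        fab_labels=fab_labels,
        planted_correlations=[{"gene": g, "trait": t, "r": r} for g, t, r in config.gene_links],
        class_trait_means=class_trait_means,
        ipf_residuals=residuals,
        missing_cells=missing_cells,
        qc_failed_cells=qc_failed,
        replicate_sample=rep_sample,
        seed=config.seed,
    )
    return SimulatedCohort(
        quant=quant, annotation=frame_from_records(library),
        expression=expression, metadata=metadata, truth=truth, fractions=frac,
    )


# ---------------------------------------------------------------------------
# recovery scoring

def score_recovery(
    truth: GroundTruth,
    correlations: pd.DataFrame | None = None,
    pca_scores: pd.DataFrame | None = None,
    trait_matrix: pd.DataFrame | None = None,
) -> dict:
    """Score pipeline outputs against the planted ground truth.

    Reports sign agreement and absolute error of estimated vs planted
    gene-trait correlations, the FAB-class silhouette on the first two PCA
    score dimensions, and the per-class trait-mean recovery error.
    """
    report: dict = {}
    if correlations is not None and len(truth.planted_correlations):
        idx = correlations.set_index(["trait", "gene"])["r"]
        errs, signs = [], []
        for link in truth.planted_correlations:
            key = (link["trait"], link["gene"])
            if key not in idx.index:
                continue
            est = float(idx.loc[key])
            errs.append(abs(est - link["r"]))
            if link["r"] != 0:
                signs.append(np.sign(est) == np.sign(link["r"]))
        report["correlation_abs_error_mean"] = float(np.mean(errs)) if errs else float("nan")
        report["correlation_sign_agreement"] = float(np.mean(signs)) if signs else float("nan")
    if pca_scores is not None:
        from sklearn.metrics import silhouette_score
        labels = pd.Series(truth.fab_labels).reindex(pca_scores.index)
        if labels.nunique() >= 2:
            report["pca_silhouette"] = float(
                silhouette_score(pca_scores.iloc[:, :2].to_numpy(), labels.to_numpy())
            )
    if trait_matrix is not None:
        labels = pd.Series(truth.fab_labels).reindex(trait_matrix.index)
        per_class = trait_matrix.groupby(labels, observed=True).mean()
        errs = []
        for cls_label, means in truth.class_trait_means.items():
            if cls_label not in per_class.index:
                continue
            for t, v in means.items():
                if t in per_class.columns and np.isfinite(per_class.loc[cls_label, t]) and np.isfinite(v):
                    errs.append(abs(float(per_class.loc[cls_label, t]) - v))
        report["trait_mean_abs_error"] = float(np.mean(errs)) if errs else float("nan")
    return report
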