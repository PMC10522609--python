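"""Synthetic pipeline inputs with known ground truth.

Generates negative-binomial miRNA count matrices with planted fold changes,
three-dialect interaction tables with brute-force-computable true node
strengths, Ct tables with planted group shifts, and per-animal echo tables
with the three-arm study structure.  Every generator is deterministic under
a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexpr import SignedMiRNASet
from .target_network import passes_threshold

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_counts",
    "generate_interactions",
    "generate_tiered_interactions",
    "generate_qpcr",
    "generate_echo",
    "write_all",
    "DEFAULT_GROUP_SIZES",
    "DEFAULT_ECHO_PROFILES",
]

#: Three-arm design: sham controls, banded-compensated, banded-failing.
DEFAULT_GROUP_SIZES = {"Sham": 8, "AB_LVH": 8, "AB_HF": 5}

#: Groups between which differential effects are planted (reference, test).
DE_PAIR = ("AB_LVH", "AB_HF")


@dataclass
class SimulationConfig:
    """Knobs for all synthetic generators.

    ``n_per_group`` may be a single int (applied to every arm) or a mapping
    of arm name to size.  ``source_mix`` gives the proportions of the
    validated/mirdb/mirsvr dialects and must sum to 1.
    """

    n_per_group: int | dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_mirnas: int = 200
    n_genes: int = 500
    frac_de: float = 0.25
    log2fc_range: tuple[float, float] = (1.0, 2.5)
    nb_dispersion: float = 0.1
    lib_size_range: tuple[float, float] = (8e5, 1.2e6)
    interactions_per_mirna: float = 10.0
    source_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    seed: int = 0
    qpcr_noise_sd: float = 0.15
    echo_noise_frac: float = 0.05

    def __post_init__(self) -> None:
        if isinstance(self.n_per_group, int):
            if self.n_per_group < 0:
                raise ValueError("n_per_group must be >= 0")
            self.n_per_group = {g: self.n_per_group for g in DEFAULT_GROUP_SIZES}
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("group sizes must be >= 0")
        if self.n_mirnas <= 0 or self.n_genes <= 0:
            raise ValueError("n_mirnas and n_genes must be positive")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must be in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.interactions_per_mirna < 0:
            raise ValueError("interactions_per_mirna must be >= 0")
        lo, hi = self.lib_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("lib_size_range must be a positive interval")
        if not np.isclose(sum(self.source_mix), 1.0):
            raise ValueError("source_mix must sum to 1")
        if any(p < 0 for p in self.source_mix):
            raise ValueError("source_mix proportions must be >= 0")

    @property
    def group_sizes(self) -> dict[str, int]:
        return dict(self.n_per_group)

    def rng(self, stream: int) -> np.random.Generator:
        """Independent child generator for one named stream."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(8)[stream])


@dataclass
class GroundTruth:
    """Planted effects, recoverable downstream.

    ``de_mirnas`` maps miRNA id to (direction, log2 fold change) of the test
    arm over the reference arm; ``true_node_strengths`` holds the integer
    strength each gene must receive from the emitted interaction tables
    under the one-edge-per-pair rule; ``de_genes`` maps gene to its planted
    Ct shift in the test arm.
    """

    de_mirnas: dict[str, tuple[str, float]] = field(default_factory=dict)
    true_node_strengths: dict[str, int] = field(default_factory=dict)
    de_genes: dict[str, float] = field(default_factory=dict)

    def signed_set(self) -> SignedMiRNASet:
        return SignedMiRNASet(
            up={m for m, (d, _) in self.de_mirnas.items() if d == "up"},
            down={m for m, (d, _) in self.de_mirnas.items() if d == "down"},
        )


def _mirna_ids(n: int) -> list[str]:
    return [f"rno-mir-{i:04d}-5p" for i in range(n)]


def _gene_ids(n: int) -> list[str]:
    return [f"Gene{i:04d}" for i in range(n)]


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with Var = mu + dispersion*mu^2.

    ``dispersion == 0`` yields deterministic rounded means (noise-free mode
    used by exact-recovery tests).
    """
    mu = np.maximum(mu, 1e-12)
    if dispersion == 0:
        return np.rint(mu).astype(np.int64)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p).astype(np.int64)


def generate_counts(config: SimulationConfig) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """miRNA × sample count matrix with planted differential miRNAs.

    Planted miRNAs differ in expectation between the reference and test arms
    by the planted log2 fold change; all other miRNAs (and the control arm)
    share means.  Returns the counts, the per-sample group labels and the
    ground truth.
    """
    rng = config.rng(0)
    mirnas = _mirna_ids(config.n_mirnas)
    sizes = config.group_sizes

    samples, labels = [], []
    for group, n in sizes.items():
        for k in range(n):
            samples.append(f"{group}_{k + 1}")
            labels.append(group)
    groups = pd.Series(labels, index=samples, name="group")

    base_mean = rng.lognormal(mean=np.log(80.0), sigma=1.2, size=config.n_mirnas)

    n_de = int(round(config.frac_de * config.n_mirnas))
    de_idx = rng.choice(config.n_mirnas, size=n_de, replace=False)
    lo, hi = config.log2fc_range
    magnitudes = rng.uniform(lo, hi, size=n_de)
    signs = rng.choice([1.0, -1.0], size=n_de)

    truth = GroundTruth()
    fold = np.ones(config.n_mirnas)
    for idx, mag, sign in zip(de_idx, magnitudes, signs):
        log2fc = float(mag * sign)
        fold[idx] = 2.0**log2fc
        truth.de_mirnas[mirnas[idx]] = ("up" if sign > 0 else "down", log2fc)

    ref_group, test_group = DE_PAIR
    lib_lo, lib_hi = config.lib_size_range
    mean_lib = base_mean.sum()
    columns = {}
    for sample, group in groups.items():
        lib_factor = rng.uniform(lib_lo, lib_hi) / (mean_lib * 1.0)
        mu = base_mean * (fold if group == test_group else 1.0) * lib_factor
        columns[sample] = _nb_draw(rng, mu, config.nb_dispersion)
    counts = pd.DataFrame(columns, index=pd.Index(mirnas, name="mirna_id"))
    return counts, groups, truth


def _brute_force_strengths(tables: dict[str, pd.DataFrame],
                           signed: SignedMiRNASet) -> dict[str, int]:
    """Recount strengths directly from the emitted tables (dedup + thresholds)."""
    kept: set[tuple[str, str]] = set()
    for dialect, df in tables.items():
        for row in df.itertuples():
            score = getattr(row, "score", None) if dialect == "mirdb" else (
                getattr(row, "mirsvr_score", None) if dialect == "mirsvr" else None)
            if passes_threshold(dialect, score):
                kept.add((row.mirna, row.gene))
    strengths: dict[str, int] = {}
    for mirna, gene in kept:
        d = signed.direction(mirna)
        if d is None:
            continue
        strengths[gene] = strengths.get(gene, 0) + (1 if d == "up" else -1)
    return strengths


_DIALECT_COLUMNS = {
    "validated": ["mirna", "gene", "evidence"],
    "mirdb": ["mirna", "gene", "score"],
    "mirsvr": ["mirna", "gene", "mirsvr_score"],
}


def _as_tables(rows: dict[str, list[dict]]) -> dict[str, pd.DataFrame]:
    return {d: pd.DataFrame(rows[d], columns=_DIALECT_COLUMNS[d]) for d in _DIALECT_COLUMNS}


def generate_interactions(
    config: SimulationConfig,
    mirna_ids: list[str],
    gene_ids: list[str],
    truth: GroundTruth,
) -> dict[str, pd.DataFrame]:
    """Emit three interaction tables and record true node strengths.

    Prediction dialects include decoy rows on the failing side of their
    thresholds (miRDB score <= 80.0, mirSVR score >= -1.2) which must not
    contribute to strengths.  ``truth.true_node_strengths`` is updated by
    brute-force recount against the planted signed set.
    """
    if not mirna_ids or not gene_ids:
        raise ValueError("mirna_ids and gene_ids must be non-empty")
    rng = config.rng(1)
    rows: dict[str, list[dict]] = {d: [] for d in _DIALECT_COLUMNS}
    dialects = list(_DIALECT_COLUMNS)

    for mirna in mirna_ids:
        k = min(rng.poisson(config.interactions_per_mirna), len(gene_ids))
        if k == 0:
            continue
        genes = rng.choice(gene_ids, size=k, replace=False)
        choice = rng.choice(3, size=k, p=config.source_mix)
        for gene, c in zip(genes, choice):
            dialect = dialects[c]
            if dialect == "validated":
                rows["validated"].append(
                    {"mirna": mirna, "gene": gene, "evidence": "reporter_assay"})
            elif dialect == "mirdb":
                rows["mirdb"].append(
                    {"mirna": mirna, "gene": gene,
                     "score": round(float(rng.uniform(80.01, 100.0)), 2)})
            else:
                rows["mirsvr"].append(
                    {"mirna": mirna, "gene": gene,
                     "mirsvr_score": round(float(rng.uniform(-8.0, -1.21)), 3)})
        # decoys: sub-threshold prediction rows that must be filtered out
        decoy_rate = max(config.interactions_per_mirna * 0.2, 0.5) \
            if config.interactions_per_mirna > 0 else 0.0
        n_decoys = rng.poisson(decoy_rate)
        for _ in range(n_decoys):
            gene = str(rng.choice(gene_ids))
            if rng.random() < 0.5:
                rows["mirdb"].append(
                    {"mirna": mirna, "gene": gene,
                     "score": round(float(rng.uniform(0.0, 80.0)), 2)})
            else:
                rows["mirsvr"].append(
                    {"mirna": mirna, "gene": gene,
                     "mirsvr_score": round(float(rng.uniform(-1.2, 0.0)), 3)})

    tables = _as_tables(rows)
    truth.true_node_strengths = _brute_force_strengths(tables, truth.signed_set())
    return tables


def generate_tiered_interactions(
    signed: SignedMiRNASet,
    truth: GroundTruth,
    n_tier1: int = 4,
    tier1_strength: int = 7,
    n_tier2: int = 10,
    tier2_strength: int = 6,
    n_background: int = 50,
    background_max_strength: int = 5,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Interaction tables with a constructed strength hierarchy.

    Wires ``n_tier1`` genes to ``tier1_strength`` distinct upregulated
    miRNAs, ``n_tier2`` genes unidirectionally to ``tier2_strength`` of
    them, and background genes to strictly fewer regulators.  Each edge is
    written to a random dialect; some edges are duplicated across dialects
    to exercise deduplication.  Updates ``truth.true_node_strengths``.
    """
    rng = np.random.default_rng(seed)
    ups = sorted(signed.up)
    if len(ups) < max(tier1_strength, tier2_strength):
        raise ValueError("not enough upregulated miRNAs for the requested tiers")

    rows: dict[str, list[dict]] = {d: [] for d in _DIALECT_COLUMNS}

    def emit(mirna: str, gene: str, dialect: str) -> None:
        if dialect == "validated":
            rows["validated"].append({"mirna": mirna, "gene": gene,
                                      "evidence": "reporter_assay"})
        elif dialect == "mirdb":
            rows["mirdb"].append({"mirna": mirna, "gene": gene,
                                  "score": round(float(rng.uniform(80.01, 100.0)), 2)})
        else:
            rows["mirsvr"].append({"mirna": mirna, "gene": gene,
                                   "mirsvr_score": round(float(rng.uniform(-8.0, -1.21)), 3)})

    def wire(gene: str, regulators: list[str]) -> None:
        for m in regulators:
            dialect = ("validated", "mirdb", "mirsvr")[rng.integers(3)]
            emit(m, gene, dialect)
            if rng.random() < 0.3:  # duplicate support in a second dialect
                other = ("validated", "mirdb", "mirsvr")[rng.integers(3)]
                if other != dialect:
                    emit(m, gene, other)

    genes = []
    for i in range(n_tier1):
        gene = f"T1_{i:02d}"
        wire(gene, list(rng.choice(ups, size=tier1_strength, replace=False)))
        genes.append(gene)
    for i in range(n_tier2):
        gene = f"T2_{i:02d}"
        wire(gene, list(rng.choice(ups, size=tier2_strength, replace=False)))
        genes.append(gene)
    pool = ups + sorted(signed.down)
    cap = min(background_max_strength, tier2_strength - 1)
    for i in range(n_background):
        gene = f"BG_{i:02d}"
        k = int(rng.integers(1, cap + 1))
        wire(gene, list(rng.choice(pool, size=min(k, len(pool)), replace=False)))
        genes.append(gene)

    tables = _as_tables(rows)
    truth.true_node_strengths = _brute_force_strengths(tables, signed)
    return tables


def generate_qpcr(
    config: SimulationConfig,
    gene_ids: list[str],
    truth: GroundTruth,
    shifts: dict[str, float] | None = None,
    groups: tuple[str, str] = DE_PAIR,
    noise_sd: float | None = None,
    housekeeping_ct: float = 18.0,
    blacklist: set[str] | None = None,
) -> pd.DataFrame:
    """Long-format Ct table with planted shifts in the test arm.

    ``shifts`` maps gene to the Ct shift applied in the test (second) group;
    it defaults to, and is recorded into, ``truth.de_genes``.  Housekeeping
    Ct carries no group shift.  ``blacklist`` drops named samples, modeling
    technical exclusions.
    """
    unknown = set(shifts or {}) - set(gene_ids)
    if unknown:
        raise ValueError(f"shifted genes not in gene_ids: {sorted(unknown)}")
    if shifts is None:
        shifts = dict(truth.de_genes)
    else:
        truth.de_genes = dict(shifts)
    sd = config.qpcr_noise_sd if noise_sd is None else noise_sd
    rng = config.rng(2)
    sizes = config.group_sizes
    baseline = {g: float(rng.uniform(20.0, 28.0)) for g in gene_ids}

    ref_group, test_group = groups
    rows = []
    for group in groups:
        for k in range(sizes.get(group, 0)):
            sample = f"{group}_{k + 1}"
            if blacklist and sample in blacklist:
                continue
            hk = housekeeping_ct + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            for gene in gene_ids:
                ct = baseline[gene]
                if group == test_group:
                    ct += shifts.get(gene, 0.0)
                if sd > 0:
                    ct += rng.normal(0.0, sd)
                rows.append({"sample_id": sample, "group": group, "gene_id": gene,
                             "ct_target": ct, "ct_housekeeping": hk})
    return pd.DataFrame(rows, columns=[
        "sample_id", "group", "gene_id", "ct_target", "ct_housekeeping"])


#: Group mean profiles of measured echo quantities by week.  Volumes are
#: targets from which the long-axis lengths are back-computed so the
#: noise-free ellipsoid volumes reproduce them exactly.  Necropsy and blood
#: pressure values are plausible pass-through measurements.
DEFAULT_ECHO_PROFILES: dict[str, dict[int, dict[str, float]]] = {
    "Sham": {
        6: dict(body_weight=460, heart_rate=360, AWTd=1.92, AWTs=3.44, PWTd=2.00,
                PWTs=3.24, LVEDD=8.05, LVESD=4.68, LVEDV=460, LVESV=202),
        12: dict(body_weight=549, heart_rate=356, AWTd=1.99, AWTs=3.57, PWTd=2.00,
                 PWTs=3.19, LVEDD=8.32, LVESD=4.83, LVEDV=511, LVESV=211),
    },
    "AB_LVH": {
        6: dict(body_weight=480, heart_rate=349, AWTd=2.55, AWTs=4.50, PWTd=2.73,
                PWTs=4.24, LVEDD=8.56, LVESD=4.97, LVEDV=518, LVESV=243),
        12: dict(body_weight=576, heart_rate=353, AWTd=2.65, AWTs=4.25, PWTd=2.50,
                 PWTs=4.13, LVEDD=8.87, LVESD=5.53, LVEDV=572, LVESV=307),
    },
    "AB_HF": {
        6: dict(body_weight=450, heart_rate=365, AWTd=2.69, AWTs=3.84, PWTd=2.60,
                PWTs=3.53, LVEDD=8.71, LVESD=6.14, LVEDV=551, LVESV=369),
        12: dict(body_weight=543, heart_rate=340, AWTd=2.78, AWTs=3.92, PWTd=2.46,
                 PWTs=3.26, LVEDD=9.93, LVESD=7.59, LVEDV=734, LVESV=605),
    },
}

_NECROPSY = {
    "Sham": dict(heart_weight=1.40, lung_weight=1.60, tibial_length=42.0,
                 SBP=146, DBP=116, MAP=126),
    "AB_LVH": dict(heart_weight=1.95, lung_weight=1.70, tibial_length=42.0,
                   SBP=218, DBP=153, MAP=174),
    "AB_HF": dict(heart_weight=2.05, lung_weight=2.60, tibial_length=42.0,
                  SBP=214, DBP=155, MAP=174),
}

_EF_CUTOFF = 30.0
_MAX_REDRAWS = 1000


def _long_axis(volume_ul: float, diameter_mm: float) -> float:
    return 6.0 * volume_ul / (np.pi * diameter_mm**2)


def generate_echo(
    config: SimulationConfig,
    profiles: dict[str, dict[int, dict[str, float]]] | None = None,
    noise_frac: float | None = None,
) -> pd.DataFrame:
    """Per-animal measurement table at weeks 6 and 12.

    Gaussian relative noise is applied to each measured quantity
    independently; derived indices are left to the phenotyping stage.
    Week-12 draws are resampled until the failing arm's implied EF is below
    the cutoff and the compensated arm's is at or above it.
    """
    profiles = profiles or DEFAULT_ECHO_PROFILES
    frac = config.echo_noise_frac if noise_frac is None else noise_frac
    rng = config.rng(3)
    sizes = config.group_sizes

    measured = ["body_weight", "heart_rate", "AWTd", "AWTs", "PWTd", "PWTs",
                "LVEDD", "LVESD", "LVEDV", "LVESV"]

    def draw(means: dict[str, float], group: str, week: int) -> dict[str, float]:
        for _ in range(_MAX_REDRAWS):
            vals = {k: means[k] * (1.0 + rng.normal(0.0, frac)) if frac > 0 else means[k]
                    for k in measured}
            if any(v <= 0 for v in vals.values()):
                continue
            ef = 100.0 * (vals["LVEDV"] - vals["LVESV"]) / vals["LVEDV"]
            if week == 12 and group == "AB_HF" and ef >= _EF_CUTOFF:
                continue
            if week == 12 and group == "AB_LVH" and ef < _EF_CUTOFF:
                continue
            return vals
        raise RuntimeError(f"could not satisfy EF constraint for {group} week {week}")

    rows = []
    for group, n in sizes.items():
        if group not in profiles:
            raise ValueError(f"no echo profile for group {group!r}")
        nec = _NECROPSY.get(group, _NECROPSY["Sham"])
        for k in range(n):
            animal = f"{group}_{k + 1}"
            nec_vals = {c: v * (1.0 + rng.normal(0.0, frac)) if frac > 0 else v
                        for c, v in nec.items()}
            for week, means in sorted(profiles[group].items()):
                vals = draw(means, group, week)
                rows.append({
                    "animal_id": animal,
                    "surgery": "sham" if group == "Sham" else "AB",
                    "survived": True,
                    "timepoint": week,
                    **{c: vals[c] for c in measured if c not in ("LVEDV", "LVESV")},
                    "long_axis_d": _long_axis(vals["LVEDV"], vals["LVEDD"]),
                    "long_axis_s": _long_axis(vals["LVESV"], vals["LVESD"]),
                    **nec_vals,
                })
    columns = ["animal_id", "surgery", "survived", "timepoint", "body_weight",
               "heart_rate", "AWTd", "AWTs", "PWTd", "PWTs", "LVEDD", "LVESD",
               "long_axis_d", "long_axis_s", "heart_weight", "lung_weight",
               "tibial_length", "SBP", "DBP", "MAP"]
    return pd.DataFrame(rows, columns=columns)


def write_all(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Generate every input table and write them as TSV plus a manifest.

    Returns the mapping of artifact name to path.  The manifest records the
    config and seed; the ground truth is written as JSON for oracle use.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    counts, groups, truth = generate_counts(config)
    tables = generate_interactions(config, list(counts.index),
                                   _gene_ids(config.n_genes), truth)
    qpcr = generate_qpcr(config, _gene_ids(min(config.n_genes, 17)), truth)
    echo = generate_echo(config)

    paths: dict[str, Path] = {}

    def save(name: str, df: pd.DataFrame, index: bool = False) -> None:
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=index)
        paths[name] = p

    save("counts", counts, index=True)
    save("groups", groups.rename_axis("sample_id").reset_index())
    for dialect, df in tables.items():
        save(dialect, df)
    save("qpcr", qpcr)
    save("echo", echo)

    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps({
        "de_mirnas": truth.de_mirnas,
        "true_node_strengths": truth.true_node_strengths,
        "de_genes": truth.de_genes,
    }, indent=1, sort_keys=True))
    paths["truth"] = truth_path

    cfg = dataclasses.asdict(config)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps({"config": cfg, "seed": config.seed},
                                        indent=1, sort_keys=True, default=list))
    paths["manifest"] = manifest_path
    return paths
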