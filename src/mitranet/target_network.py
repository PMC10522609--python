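"""Signed bipartite miRNA-target network and node-strength scoring.

Interactions come from three source dialects: a validated catalog (kept
unconditionally), a prediction database with a 0-100 confidence score (kept
when score > 80.0, strict) and a prediction score where more negative means
stronger repression (kept when score < -1.2, strict).  Edges take weight +1
from upregulated and -1 from downregulated miRNAs; a gene's node strength is
the sum of its incident edge weights, so positive strength predicts target
downregulation.  Duplicate (miRNA, gene) pairs across sources collapse to a
single edge with merged provenance, so |strength| counts distinct regulators.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .diffexpr import SignedMiRNASet, canonical_mirna

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionRecord",
    "TargetNetwork",
    "read_interactions",
    "build_network",
    "node_strengths",
    "select_targets",
    "export_network",
    "read_edgelist",
]

DIALECTS = ("validated", "mirdb", "mirsvr")
DEFAULT_MIRDB_MIN = 80.0
DEFAULT_MIRSVR_MAX = -1.2

#: TSV score column per prediction dialect.
_SCORE_COLUMN = {"mirdb": "score", "mirsvr": "mirsvr_score"}


@dataclass(frozen=True)
class InteractionRecord:
    """One miRNA→gene interaction from one source database."""

    mirna_id: str
    gene_id: str
    source: str  # validated | mirdb | mirsvr
    score: float | None = None  # absent for the validated dialect
    species: str = "rno"

    def __post_init__(self) -> None:
        if self.source not in DIALECTS:
            raise ValueError(f"unknown source {self.source!r}")
        if self.source == "validated" and self.score is not None:
            raise ValueError("validated records carry no score")
        if self.source != "validated" and self.score is None:
            raise ValueError(f"{self.source} records require a score")


@dataclass
class _Edge:
    weight: int
    sources: set[str] = field(default_factory=set)


@dataclass
class TargetNetwork:
    """Signed bipartite graph: signed miRNA nodes, gene nodes, ±1 edges."""

    mirna_direction: dict[str, str] = field(default_factory=dict)
    edges: dict[tuple[str, str], _Edge] = field(default_factory=dict)

    @property
    def genes(self) -> set[str]:
        return {g for _, g in self.edges}

    @property
    def mirnas(self) -> set[str]:
        return set(self.mirna_direction)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for m, d in self.mirna_direction.items():
            g.add_node(m, kind="mirna", direction=d)
        for (m, t), e in self.edges.items():
            g.add_node(t, kind="gene")
            g.add_edge(m, t, weight=e.weight, sources=",".join(sorted(e.sources)))
        return g


def passes_threshold(source: str, score: float | None,
                     mirdb_min: float = DEFAULT_MIRDB_MIN,
                     mirsvr_max: float = DEFAULT_MIRSVR_MAX) -> bool:
    """Strict per-dialect inclusion rule."""
    if source == "validated":
        return True
    if score is None:
        return False
    if source == "mirdb":
        return score > mirdb_min
    if source == "mirsvr":
        return score < mirsvr_max
    raise ValueError(f"unknown source {source!r}")


def read_interactions(path, dialect: str,
                      mirdb_min: float = DEFAULT_MIRDB_MIN,
                      mirsvr_max: float = DEFAULT_MIRSVR_MAX,
                      species: str = "rno") -> list[InteractionRecord]:
    """Read one dialect's TSV and apply its score threshold.

    Columns: ``mirna, gene, evidence`` (validated), ``mirna, gene, score``
    (mirdb) or ``mirna, gene, mirsvr_score`` (mirsvr).  Malformed rows and
    prediction rows with missing scores are logged and skipped.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    records: list[InteractionRecord] = []
    n_dropped = n_bad = 0
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for i, row in enumerate(reader, start=2):
            mirna, gene = (row.get("mirna") or "").strip(), (row.get("gene") or "").strip()
            if not mirna or not gene:
                logger.warning("%s:%d malformed row skipped", path.name, i)
                n_bad += 1
                continue
            score = None
            if dialect != "validated":
                raw = (row.get(_SCORE_COLUMN[dialect]) or "").strip()
                try:
                    score = float(raw)
                except ValueError:
                    logger.warning("%s:%d missing/invalid score, row skipped", path.name, i)
                    n_bad += 1
                    continue
            if not passes_threshold(dialect, score, mirdb_min, mirsvr_max):
                n_dropped += 1
                continue
            records.append(InteractionRecord(
                canonical_mirna(mirna, species=species), gene, dialect, score, species,
            ))
    logger.info("%s (%s): %d kept, %d below threshold, %d malformed",
                path.name, dialect, len(records), n_dropped, n_bad)
    return records


def build_network(signed: SignedMiRNASet,
                  interactions: list[InteractionRecord]) -> TargetNetwork:
    """Assemble the signed bipartite network from thresholded interactions.

    Only interactions whose (canonical) miRNA is in the signed set become
    edges; duplicate pairs merge provenance onto one edge; genes without a
    surviving edge are absent.
    """
    if len(signed) == 0:
        raise ValueError("signed miRNA set is empty")
    net = TargetNetwork(mirna_direction={
        **{m: "up" for m in signed.up}, **{m: "down" for m in signed.down}
    })
    for rec in interactions:
        direction = signed.direction(rec.mirna_id)
        if direction is None:
            continue
        key = (rec.mirna_id, rec.gene_id)
        edge = net.edges.get(key)
        if edge is None:
            net.edges[key] = _Edge(weight=1 if direction == "up" else -1,
                                   sources={rec.source})
        else:
            edge.sources.add(rec.source)
    return net


def node_strengths(net: TargetNetwork) -> pd.DataFrame:
    """Per-gene signed strength table.

    strength = n_up_regulators − n_down_regulators; positive strength
    predicts downregulation of the target.  Sorted by |strength| descending,
    ties broken lexicographically by gene id.
    """
    tally: dict[str, list[int]] = {}
    for (m, gene), edge in net.edges.items():
        up_down = tally.setdefault(gene, [0, 0])
        up_down[0 if edge.weight > 0 else 1] += 1
    rows = []
    for gene, (n_up, n_down) in tally.items():
        strength = n_up - n_down
        rows.append({
            "gene_id": gene,
            "node_strength": strength,
            "n_up_regulators": n_up,
            "n_down_regulators": n_down,
            "predicted_direction": (
                "down" if strength > 0 else "up" if strength < 0 else "ambiguous"
            ),
            "unidirectional": n_up == 0 or n_down == 0,
        })
    table = pd.DataFrame(rows, columns=[
        "gene_id", "node_strength", "n_up_regulators", "n_down_regulators",
        "predicted_direction", "unidirectional",
    ])
    if len(table):
        table["_abs"] = table.node_strength.abs()
        table = (table.sort_values(["_abs", "gene_id"], ascending=[False, True])
                 .drop(columns="_abs").reset_index(drop=True))
    return table


def select_targets(table: pd.DataFrame,
                   unidirectional_strength: int | None = None,
                   n_random_strong: int = 0,
                   strong_floor: int = 1,
                   seed: int | None = None) -> pd.DataFrame:
    """Three-tier candidate selection from the strength table.

    Tier 1: every gene at the maximal |strength|.  Tier 2: unidirectional
    genes whose |strength| equals ``unidirectional_strength`` (excluding
    tier 1).  Tier 3: a seeded random sample of ``n_random_strong`` genes
    from the remainder with |strength| >= ``strong_floor``.  Tiers are
    disjoint; the result keeps the strength columns plus a ``tier`` label.
    """
    if table.empty:
        raise ValueError("strength table is empty")
    work = table.copy()
    work["_abs"] = work.node_strength.abs()
    max_abs = int(work["_abs"].max())

    tier1 = set(work.loc[work["_abs"] == max_abs, "gene_id"])
    tier2: set[str] = set()
    if unidirectional_strength is not None:
        if unidirectional_strength > max_abs:
            logger.warning("unidirectional_strength %d exceeds max |strength| %d; tier 2 empty",
                           unidirectional_strength, max_abs)
        mask = (work["_abs"] == unidirectional_strength) & work.unidirectional
        tier2 = set(work.loc[mask, "gene_id"]) - tier1

    pool = work.loc[
        ~work.gene_id.isin(tier1 | tier2) & (work["_abs"] >= strong_floor), "gene_id"
    ].tolist()
    tier3: set[str] = set()
    if n_random_strong > 0:
        rng = np.random.default_rng(seed)
        k = min(n_random_strong, len(pool))
        if k < n_random_strong:
            logger.warning("only %d genes above strong floor; tier 3 truncated", k)
        tier3 = set(rng.choice(sorted(pool), size=k, replace=False)) if k else set()

    def tier_of(g: str) -> str | None:
        if g in tier1:
            return "tier1"
        if g in tier2:
            return "tier2"
        if g in tier3:
            return "tier3"
        return None

    work["tier"] = work.gene_id.map(tier_of)
    return (work[work.tier.notna()]
            .drop(columns="_abs")
            .reset_index(drop=True))


def export_network(net: TargetNetwork, path, fmt: str,
                   strengths: pd.DataFrame | None = None) -> None:
    """Write the network as SIF, GraphML or an edge-list TSV.

    SIF lines are ``mirna<TAB>weight<TAB>gene``.  GraphML carries typed node
    attributes (miRNA direction; gene strength and predicted direction when
    ``strengths`` is given).  The edge-list TSV round-trips through
    :func:`read_edgelist`.
    """
    path = Path(path)
    keys = sorted(net.edges)
    if fmt == "sif":
        with path.open("w") as fh:
            for m, g in keys:
                fh.write(f"{m}\t{net.edges[(m, g)].weight}\t{g}\n")
    elif fmt == "graphml":
        g = net.to_networkx()
        if strengths is not None:
            for row in strengths.itertuples():
                if g.has_node(row.gene_id):
                    g.nodes[row.gene_id]["strength"] = int(row.node_strength)
                    g.nodes[row.gene_id]["predicted_direction"] = row.predicted_direction
        nx.write_graphml(g, path)
    elif fmt == "tsv":
        with path.open("w") as fh:
            fh.write("mirna\tgene\tweight\tmirna_direction\tsources\n")
            for m, gene in keys:
                e = net.edges[(m, gene)]
                fh.write(f"{m}\t{gene}\t{e.weight}\t{net.mirna_direction[m]}\t"
                         f"{','.join(sorted(e.sources))}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_edgelist(path) -> TargetNetwork:
    """Reconstruct a network from the edge-list TSV written by export."""
    net = TargetNetwork()
    with Path(path).open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            m, gene = row["mirna"], row["gene"]
            net.mirna_direction[m] = row["mirna_direction"]
            net.edges[(m, gene)] = _Edge(
                weight=int(row["weight"]),
                sources=set(filter(None, row["sources"].split(","))),
            )
    return net
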