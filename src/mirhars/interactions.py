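"""miRNA→mRNA target-interaction filtering, reciprocity calls, graph export.

Predicted interaction tables (TargetScan-style dumps, or any equivalent
table) are reduced to the pairs linking the candidate miRNA list with a
given mRNA list, restricted to predictions made on a chosen genome
(default human, taxon 9606).  Column names are mapped through a small
config rather than hard-coding one database dialect, so the same code runs
on a 22.9-million-row dump or a six-row fixture.  Collapsing family-level
database identifiers onto individual miRNA names is left to that mapping
layer.

Each surviving (miRNA, gene) pair keeps its strongest predicted repression
— the most negative cumulative weighted context++ score.  *Reciprocal*
expression (miRNA down while its target is up, or vice versa) is the
pattern expected from direct repression; non-reciprocal pairs may be
irrelevant to the phenotype or false-positive predictions.

The filtered set exports as a bipartite weighted graph (SIF or GraphML,
both Cytoscape-importable) with |context++ score| as edge weight.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "ColumnMap",
    "InteractionRecord",
    "filter_interactions",
    "classify_reciprocity",
    "export_graph",
]

#: Human NCBI taxon id — the default species filter.
HUMAN_TAXON = "9606"


@dataclass(frozen=True)
class ColumnMap:
    """Maps the roles the filter needs onto the input table's column names."""

    mirna: str = "mirna"
    gene: str = "gene"
    species: str = "species"
    score: str = "context_score"


@dataclass(frozen=True)
class InteractionRecord:
    """One predicted miRNA→mRNA interaction.

    ``context_score`` is the cumulative weighted context++ score (typically
    <= 0; more negative = stronger predicted repression).  Directions are
    filled by :func:`classify_reciprocity`; until then they are None and
    ``reciprocal`` undefined.  ``classified`` is False when a direction was
    unknown at classification time.
    """

    mirna_id: str
    gene_symbol: str
    species: str
    context_score: float
    mirna_direction: str | None = None
    mrna_direction: str | None = None
    reciprocal: bool | None = None
    classified: bool = False


def filter_interactions(
    table: pd.DataFrame | str | Path,
    mirnas: Sequence[str],
    mrnas: Sequence[str],
    species: str = HUMAN_TAXON,
    colmap: ColumnMap = ColumnMap(),
) -> list[InteractionRecord]:
    """Keep interactions linking the candidate lists on the chosen genome.

    A row survives iff its miRNA is in ``mirnas``, its gene in ``mrnas`` and
    its species equals ``species``.  Duplicate (miRNA, gene) pairs are
    collapsed to the most negative context++ score.  Output is ordered by
    (miRNA, gene).  Unmappable columns raise, listing the expected roles.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t", dtype=str, keep_default_na=False)
    needed = {
        "mirna": colmap.mirna,
        "gene": colmap.gene,
        "species": colmap.species,
        "score": colmap.score,
    }
    missing = {role: col for role, col in needed.items() if col not in table.columns}
    if missing:
        raise ValueError(
            "interaction table is missing mapped columns: "
            + ", ".join(f"{role} -> {col!r}" for role, col in missing.items())
            + f"; available columns: {list(table.columns)}"
        )

    mirna_set = set(mirnas)
    mrna_set = set(mrnas)
    best: dict[tuple[str, str], InteractionRecord] = {}
    cols = zip(
        table[colmap.mirna].astype(str),
        table[colmap.gene].astype(str),
        table[colmap.species].astype(str),
        table[colmap.score],
    )
    for mid, gene, sp, score in cols:
        if mid not in mirna_set or gene not in mrna_set or sp != species:
            continue
        score = float(score)
        prev = best.get((mid, gene))
        if prev is None or score < prev.context_score:
            best[(mid, gene)] = InteractionRecord(
                mirna_id=mid, gene_symbol=gene, species=sp, context_score=score
            )
    return [best[k] for k in sorted(best)]


def classify_reciprocity(
    record: InteractionRecord,
    mirna_dirs: Mapping[str, str],
    mrna_dirs: Mapping[str, str],
) -> InteractionRecord:
    """Attach expression directions and the reciprocity call to a record.

    Reciprocal means the miRNA and its target moved in opposite directions
    (e.g. miRNA down, target mRNA up — the pattern direct repression
    predicts).  A direction missing from either map leaves the record
    unclassified (``classified=False``, ``reciprocal=None``) rather than
    guessing.
    """
    mdir = mirna_dirs.get(record.mirna_id)
    gdir = mrna_dirs.get(record.gene_symbol)
    if mdir not in ("up", "down") or gdir not in ("up", "down"):
        return replace(
            record,
            mirna_direction=mdir,
            mrna_direction=gdir,
            reciprocal=None,
            classified=False,
        )
    return replace(
        record,
        mirna_direction=mdir,
        mrna_direction=gdir,
        reciprocal=mdir != gdir,
        classified=True,
    )


def to_graph(records: Sequence[InteractionRecord]) -> nx.Graph:
    """Bipartite miRNA/mRNA graph with |context++ score| edge weights."""
    g = nx.Graph()
    for r in records:
        g.add_node(r.mirna_id, kind="miRNA", direction=r.mirna_direction or "")
        g.add_node(r.gene_symbol, kind="mRNA", direction=r.mrna_direction or "")
        g.add_edge(
            r.mirna_id,
            r.gene_symbol,
            weight=abs(r.context_score),
            context_score=r.context_score,
            interaction="targets",
        )
    return g


def export_graph(
    records: Sequence[InteractionRecord],
    path: str | Path,
    format: str = "graphml",
) -> nx.Graph:
    """Write the interaction graph as SIF or GraphML; returns the graph.

    SIF carries one ``miRNA targets gene`` line per edge (layout only);
    GraphML carries node kind/direction and edge weight attributes and
    round-trips through networkx.  An empty record set raises.
    """
    if not records:
        raise ValueError("export_graph: no interaction records to export")
    g = to_graph(records)
    fmt = format.lower()
    if fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for r in records:
                fh.write(f"{r.mirna_id}\ttargets\t{r.gene_symbol}\n")
    elif fmt == "graphml":
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown graph format {format!r}; use 'sif' or 'graphml'")
    return g
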