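"""Gene/protein nomenclature alignment.

Proteomics studies report the same protein under synonymous gene symbols
(e.g. mouse RIKEN clone names vs official symbols) or under UniProt
accessions only.  To merge quantifications across studies we build a
co-listing graph: gene names are vertices, and two names are joined by an
edge whenever they appear together on one data entry or one row of an
offline UniProt-derived synonym table.  Each connected component is a
putative synonym group; the most frequently observed member (counted over
data entries) becomes the canonical symbol for the whole component.

Name comparison is case-insensitive and canonical output is uppercase, so
mouse-style ``Stxbp1`` and human-style ``STXBP1`` unify.  Ties on frequency
prefer names present in the mouse synonym table, then the lexicographically
smallest name — a deterministic stand-in for manual curation.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SynonymGraph",
    "SynonymTable",
    "IdentifierRecord",
    "Conflict",
    "build_synonym_graph",
    "canonicalize",
    "detect_conflicts",
    "fill_missing_identifiers",
]


def _norm(name: str) -> str:
    return name.strip().upper()


@dataclass
class IdentifierRecord:
    """One entry's identifiers before/after canonicalisation."""

    raw_gene_names: list[str] = field(default_factory=list)
    raw_accessions: list[str] = field(default_factory=list)
    canonical_gene: str | None = None
    canonical_accession: str | None = None
    conflict_flag: bool = False

    def __post_init__(self) -> None:
        if not self.raw_gene_names and not self.raw_accessions:
            raise ValueError("IdentifierRecord needs at least one gene name or accession")


class SynonymTable:
    """Offline accession <-> gene-name mapping (replaces live UniProt queries).

    File format: tab-separated with columns ``accession``, ``gene_names``
    (pipe-separated) and ``species``.
    """

    def __init__(self, rows: list[tuple[str, list[str], str]]):
        self.rows = rows
        self.accession_to_genes: dict[str, list[str]] = {}
        self.gene_to_accessions: dict[str, set[str]] = {}
        self.mouse_names: set[str] = set()
        for accession, genes, species in rows:
            genes = [_norm(g) for g in genes if g.strip()]
            acc = accession.strip()
            self.accession_to_genes.setdefault(acc, [])
            for g in genes:
                if g not in self.accession_to_genes[acc]:
                    self.accession_to_genes[acc].append(g)
                self.gene_to_accessions.setdefault(g, set()).add(acc)
                if species.strip().lower() == "mouse":
                    self.mouse_names.add(g)

    @classmethod
    def from_tsv(cls, path) -> "SynonymTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("accession", "gene_names", "species"):
            if col not in df.columns:
                raise ValueError(f"synonym table missing column {col}")
        rows = []
        for i, row in enumerate(df.itertuples(index=False), start=2):
            acc = (row.accession or "").strip() if isinstance(row.accession, str) else ""
            names_raw = row.gene_names if isinstance(row.gene_names, str) else ""
            if not acc or not names_raw.strip():
                raise ValueError(f"malformed synonym table row {i}: accession and gene_names required")
            names = [n for n in names_raw.split("|") if n.strip()]
            if not names:
                raise ValueError(f"malformed synonym table row {i}: no gene names")
            species = row.species if isinstance(row.species, str) else ""
            rows.append((acc, names, species))
        return cls(rows)

    def name_lists(self) -> list[list[str]]:
        """Gene-name co-listings contributed by the table (one list per row)."""
        return [genes for _, genes, _ in self.rows if len(genes) >= 1]


@dataclass
class SynonymGraph:
    """Co-listing graph over gene names with a canonical-name map.

    ``canonical_map`` is total on vertices and constant on every connected
    component; ``components`` partition the vertex set.
    """

    graph: nx.Graph
    components: list[frozenset[str]]
    canonical_map: dict[str, str]
    name_counts: Counter = field(default_factory=Counter)

    def __contains__(self, name: str) -> bool:
        return _norm(name) in self.canonical_map

    def canonical(self, name: str) -> str:
        return self.canonical_map[_norm(name)]


def _validate_name_lists(lists, what: str) -> list[list[str]]:
    cleaned = []
    for i, names in enumerate(lists):
        if not names:
            raise ValueError(f"empty name list at {what} index {i}")
        out = []
        for name in names:
            n = _norm(str(name))
            if not n:
                raise ValueError(f"blank name in {what} index {i}: {names!r}")
            out.append(n)
        cleaned.append(out)
    return cleaned


def build_synonym_graph(
    entries: list[list[str]],
    synonym_table: SynonymTable | list[list[str]] | None = None,
    mouse_names: set[str] | None = None,
) -> SynonymGraph:
    """Build the gene-name co-listing graph and assign canonical names.

    Parameters
    ----------
    entries:
        Gene-name lists from data entries; every co-listed pair becomes an
        edge, and occurrence counts (for canonical selection) are taken from
        these lists only.
    synonym_table:
        Optional offline synonym table (or plain name-lists); its rows add
        edges but do not contribute to occurrence counts.
    mouse_names:
        Names given preference on frequency ties.  Defaults to the mouse
        names of ``synonym_table`` when one is provided.
    """
    if not entries:
        raise ValueError("no entries")
    entry_lists = _validate_name_lists(entries, "entries")

    table_lists: list[list[str]] = []
    if isinstance(synonym_table, SynonymTable):
        table_lists = _validate_name_lists(synonym_table.name_lists(), "synonym_table")
        if mouse_names is None:
            mouse_names = synonym_table.mouse_names
    elif synonym_table:
        table_lists = _validate_name_lists(synonym_table, "synonym_table")
    mouse = {_norm(n) for n in (mouse_names or set())}

    g = nx.Graph()
    counts: Counter = Counter()
    for names in entry_lists:
        counts.update(names)
        g.add_nodes_from(names)
        g.add_edges_from((a, b) for i, a in enumerate(names) for b in names[i + 1 :] if a != b)
    for names in table_lists:
        g.add_nodes_from(names)
        g.add_edges_from((a, b) for i, a in enumerate(names) for b in names[i + 1 :] if a != b)

    components = [frozenset(c) for c in nx.connected_components(g)]
    canonical_map: dict[str, str] = {}
    for comp in components:
        # most frequent over entry occurrences; ties -> mouse names first,
        # then lexicographically smallest
        best = min(comp, key=lambda n: (-counts[n], n not in mouse, n))
        for name in comp:
            canonical_map[name] = best
    return SynonymGraph(graph=g, components=components, canonical_map=canonical_map, name_counts=counts)


def canonicalize(
    graph: SynonymGraph,
    record: IdentifierRecord,
    synonym_table: SynonymTable | None = None,
) -> IdentifierRecord:
    """Assign a canonical gene symbol to one record (idempotent).

    Resolution order: any raw gene name found in the graph; otherwise the
    first accession resolvable through the offline synonym table.  An
    unresolvable record is returned unchanged (``canonical_gene`` unset) —
    callers count these in a coverage report rather than raising.
    """
    if record.canonical_gene is not None:
        record.canonical_gene = _norm(record.canonical_gene)
        if record.canonical_gene in graph.canonical_map:
            record.canonical_gene = graph.canonical_map[record.canonical_gene]
        return record
    for name in record.raw_gene_names:
        n = _norm(name)
        if n in graph.canonical_map:
            record.canonical_gene = graph.canonical_map[n]
            return record
    if synonym_table is not None:
        for acc in record.raw_accessions:
            genes = synonym_table.accession_to_genes.get(acc.strip())
            if genes:
                g0 = genes[0]
                record.canonical_gene = graph.canonical_map.get(g0, g0)
                if record.canonical_accession is None:
                    record.canonical_accession = acc.strip()
                return record
    return record


@dataclass
class Conflict:
    """Two non-synonymous names (disjoint accession sets) in one component."""

    component: frozenset[str]
    name_a: str
    name_b: str
    accessions_a: frozenset[str]
    accessions_b: frozenset[str]


def detect_conflicts(graph: SynonymGraph, accession_map: dict[str, set[str]]) -> list[Conflict]:
    """Cross-validate components against accessions.

    Reports every pair of names within one component whose accession sets
    are both non-empty and disjoint — the signature of distinct proteins
    merged by an ambiguous co-listing.  Components are flagged, not split
    (manual-curation mirror).
    """
    amap = {_norm(k): frozenset(v) for k, v in accession_map.items() if v}
    conflicts: list[Conflict] = []
    for comp in graph.components:
        names = sorted(n for n in comp if n in amap)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if amap[a].isdisjoint(amap[b]):
                    conflicts.append(Conflict(comp, a, b, amap[a], amap[b]))
    return conflicts


def fill_missing_identifiers(
    records: list[IdentifierRecord],
    synonym_table: SynonymTable,
    graph: SynonymGraph | None = None,
) -> tuple[list[IdentifierRecord], dict[str, int]]:
    """Complete gene/accession identifiers via the offline synonym table.

    Returns the records (mutated in place) plus a coverage report with
    ``resolved`` / ``unresolved`` counts.  Unresolvable records are retained.
    """
    report = {"resolved": 0, "unresolved": 0}
    for rec in records:
        if rec.canonical_gene is None:
            for name in rec.raw_gene_names:
                n = _norm(name)
                if graph is not None and n in graph.canonical_map:
                    rec.canonical_gene = graph.canonical_map[n]
                    break
                if n in synonym_table.gene_to_accessions:
                    rec.canonical_gene = n
                    break
            if rec.canonical_gene is None:
                for acc in rec.raw_accessions:
                    genes = synonym_table.accession_to_genes.get(acc.strip())
                    if genes:
                        g0 = genes[0]
                        rec.canonical_gene = graph.canonical_map.get(g0, g0) if graph else g0
                        break
        if rec.canonical_accession is None:
            if rec.raw_accessions:
                rec.canonical_accession = rec.raw_accessions[0].strip()
            elif rec.canonical_gene is not None:
                accs = synonym_table.gene_to_accessions.get(rec.canonical_gene)
                if not accs:
                    for name in rec.raw_gene_names:
                        accs = synonym_table.gene_to_accessions.get(_norm(name))
                        if accs:
                            break
                if accs:
                    rec.canonical_accession = sorted(accs)[0]
        if rec.canonical_gene is not None and rec.canonical_accession is not None:
            report["resolved"] += 1
        else:
            report["unresolved"] += 1
            logger.warning("unresolved identifiers: %r", rec)
    return records, report
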