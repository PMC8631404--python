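"""End-to-end pipeline: ingest -> align names -> estimate -> normalize -> validate.

Stages run in a fixed order with per-stage record counts logged to stderr
and collected into a machine-readable run summary.  Processing is
order-deterministic: study files are enumerated sorted, and records are
sorted by (study, gene) before estimation.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as vstats
from .concentration import (
    ATLAS_COLUMNS,
    QuantInput,
    compute_reference_median,
    convert_reported_units,
    estimate_study,
    normalize_to_reference,
)
from .digest import ProteinSequence, detectability_factor, molecular_weight, read_fasta
from .io import PipelineConfig, read_housekeeping_list, read_study_table, write_atlas
from .nomenclature import SynonymGraph, SynonymTable, build_synonym_graph

logger = logging.getLogger(__name__)

__all__ = ["align_study_names", "estimate_atlas", "expand_sequence_index", "run_pipeline"]


def _split_names(cell: str) -> list[str]:
    return [p for p in str(cell).replace("|", ";").split(";") if p.strip()]


def align_study_names(
    studies: list[pd.DataFrame], synonym_table: SynonymTable | None
) -> tuple[list[pd.DataFrame], SynonymGraph, dict]:
    """Build the synonym graph over all studies and canonicalize labels.

    Returns the studies with a ``canonical_gene`` column, the graph itself
    (so other tables keyed by gene symbol can be joined through the same
    canonical map), and a coverage report (resolved via graph / via
    accession / unresolved counts).
    """
    entries: list[list[str]] = []
    for df in studies:
        if "gene" in df.columns:
            entries.extend(_split_names(c) for c in df["gene"] if str(c).strip())
    if not entries:
        raise ValueError("no entries")
    graph = build_synonym_graph(entries, synonym_table)
    report = {"via_graph": 0, "via_accession": 0, "unresolved": 0}
    aligned = []
    for df in studies:
        out = df.copy()
        canon = []
        for _, row in out.iterrows():
            names = _split_names(row["gene"]) if "gene" in out.columns else []
            resolved = None
            for name in names:
                key = name.strip().upper()
                if key in graph.canonical_map:
                    resolved = graph.canonical_map[key]
                    report["via_graph"] += 1
                    break
            if resolved is None and synonym_table is not None and "accession" in out.columns:
                genes = synonym_table.accession_to_genes.get(str(row["accession"]).strip())
                if genes:
                    resolved = graph.canonical_map.get(genes[0], genes[0])
                    report["via_accession"] += 1
            if resolved is None:
                report["unresolved"] += 1
            canon.append(resolved)
        out["canonical_gene"] = canon
        aligned.append(out[out["canonical_gene"].notna()])
    return aligned, graph, report


def expand_sequence_index(
    sequences: dict[str, ProteinSequence], synonym_table: SynonymTable | None
) -> dict[str, ProteinSequence]:
    """Index sequences under accessions and all registered synonyms too.

    A study may report a protein under a synonym or accession while the
    FASTA header carries the primary symbol (or vice versa); routing the
    lookup through the synonym table keeps detectability/weight available
    under whichever label became canonical.
    """
    out = dict(sequences)
    if synonym_table is None:
        return out
    for acc, genes in synonym_table.accession_to_genes.items():
        seq = out.get(acc)
        if seq is None:
            for g in genes:
                seq = out.get(g) or out.get(g.upper())
                if seq is not None:
                    break
        if seq is None:
            continue
        out.setdefault(acc, seq)
        for g in genes:
            out.setdefault(g, seq)
            out.setdefault(g.upper(), seq)
    return out


def estimate_atlas(
    studies: list[pd.DataFrame],
    sequences: dict[str, ProteinSequence],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Convert every study group to uM concentrations (un-normalized).

    MS signal types go through the total-protein-mass estimation with
    per-protein detectability and molecular weight from the sequence
    collection; already-absolute types are unit-converted directly.
    Proteins without a sequence (or with zero detectable peptides for
    peptide-scaled types) are excluded.
    """
    rows = []
    for df in studies:
        df = df.sort_values(["study_id", "canonical_gene"], kind="mergesort")
        for (study_id, value_type), group in df.groupby(["study_id", "value_type"], sort=True):
            meta_cols = ["species", "brain_region", "cell_type", "location", "condition", "age"]
            if value_type in {"molar", "mol_per_g_protein"}:
                unit = "uM" if value_type == "molar" else "mol_per_g_protein"
                for _, row in group.iterrows():
                    conc = convert_reported_units(float(row["value"]), unit, config.estimation)
                    rows.append([row["canonical_gene"], conc, False, value_type, study_id,
                                 *[row[c] for c in meta_cols]])
                continue
            inputs, metas = [], []
            n_no_seq = 0
            for _, row in group.iterrows():
                seq = sequences.get(row["canonical_gene"]) or sequences.get(str(row.get("gene", "")).strip().upper())
                if seq is None and "accession" in group.columns:
                    seq = sequences.get(str(row["accession"]).strip())
                if seq is None:
                    n_no_seq += 1
                    continue
                det = detectability_factor(seq, value_type, config.digest)
                if det is None:
                    continue
                inputs.append(QuantInput(
                    canonical_gene=row["canonical_gene"],
                    signal=float(row["value"]),
                    detectability=det,
                    mol_weight=molecular_weight(seq),
                    data_type=value_type,
                ))
                metas.append([row[c] for c in meta_cols])
            if n_no_seq:
                logger.warning("%s/%s: %d entries without sequence excluded",
                               study_id, value_type, n_no_seq)
            if not inputs:
                logger.warning("%s/%s: no estimable entries", study_id, value_type)
                continue
            result = estimate_study(inputs, config.estimation)
            meta_by_gene = {q.canonical_gene: m for q, m in zip(inputs, metas)}
            for gene, conc in zip(result.genes, result.concentrations_uM):
                rows.append([gene, float(conc), False, value_type, study_id,
                             *meta_by_gene[gene]])
    atlas = pd.DataFrame(rows, columns=ATLAS_COLUMNS)
    if atlas.empty:
        raise ValueError("estimation produced an empty atlas")
    return atlas


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write the atlas plus validation reports.

    Returns a dict with the normalized atlas, the reference median, the
    per-stage counts and paths of everything written.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}}

    synonym_table = SynonymTable.from_tsv(config.synonyms) if config.synonyms else None
    housekeeping = read_housekeeping_list(config.housekeeping) if config.housekeeping else set()
    sequences: dict[str, ProteinSequence] = {}
    if config.fasta:
        for seq in read_fasta(config.fasta):
            sequences[seq.identifier.upper()] = seq
            sequences[seq.identifier] = seq

    study_files = sorted(Path(config.studies_dir).glob("*.tsv"))
    if not study_files:
        raise RuntimeError(f"stage ingest: no study tables in {config.studies_dir}")
    studies = [read_study_table(p) for p in study_files]
    n_in = sum(len(s) for s in studies)
    summary["stages"]["ingest"] = {"files": len(study_files), "records": n_in}
    logger.info("ingest: %d files, %d records", len(study_files), n_in)

    try:
        aligned, _graph, align_report = align_study_names(studies, synonym_table)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage nomenclature: {exc}") from exc
    summary["stages"]["nomenclature"] = align_report
    logger.info("nomenclature: %s", align_report)

    sequences = expand_sequence_index(sequences, synonym_table)
    try:
        atlas = estimate_atlas(aligned, sequences, config)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage estimation: {exc}") from exc
    summary["stages"]["estimation"] = {"entries": len(atlas)}
    logger.info("estimation: %d atlas entries", len(atlas))

    try:
        reference_median = compute_reference_median(atlas, housekeeping, config.reference_filters)
        atlas = normalize_to_reference(atlas, housekeeping, reference_median)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage normalization: {exc}") from exc
    summary["stages"]["normalization"] = {"reference_median_uM": reference_median}
    logger.info("normalization: reference median %.6g uM", reference_median)

    atlas_path = out_dir / "atlas.tsv"
    write_atlas(atlas, atlas_path)

    # validation reports
    reports: dict[str, str] = {}
    study_groups = {
        str(sid): np.log(sub.loc[sub["concentration_uM"] > 0, "concentration_uM"]).to_numpy()
        for sid, sub in atlas.groupby("study_id")
    }
    if len(study_groups) >= 3 and all(len(v) >= 2 for v in study_groups.values()):
        med = vstats.median_equality_battery(study_groups, alpha=config.alpha)
        summary["stages"]["validation_median_equality"] = {
            "kw_h": med.h_statistic, "kw_p": med.p_value, "rejected": med.rejected,
        }
        if med.posthoc_holm is not None:
            p = out_dir / "conover_holm.tsv"
            med.posthoc_holm.to_csv(p, sep="\t")
            reports["conover_holm"] = str(p)
    if len(study_groups) >= 2:
        r, n = vstats.correlation_tables(atlas, "study_id")
        r.to_csv(out_dir / "correlation_r.tsv", sep="\t")
        n.to_csv(out_dir / "correlation_n.tsv", sep="\t")
        reports["correlation_r"] = str(out_dir / "correlation_r.tsv")
        reports["correlation_n"] = str(out_dir / "correlation_n.tsv")

    scores = []
    for (gene, dtype), sub in atlas.groupby(["canonical_gene", "data_type"]):
        s = vstats.variability_score(sub["concentration_uM"].to_numpy(), gene, dtype)
        if s is not None:
            scores.append((s.gene, s.data_type, s.score, s.n))
    if scores:
        vs = pd.DataFrame(scores, columns=["gene", "data_type", "variability_score", "n"])
        vs.to_csv(out_dir / "variability_scores.tsv", sep="\t", index=False)
        reports["variability_scores"] = str(out_dir / "variability_scores.tsv")

    summary_path = out_dir / "run_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, default=float))
    return {
        "atlas": atlas,
        "reference_median_uM": reference_median,
        "summary": summary,
        "paths": {"atlas": str(atlas_path), "summary": str(summary_path), **reports},
    }
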