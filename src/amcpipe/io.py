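"""Tabular readers/writers and pipeline configuration.

One tabular dialect everywhere: tab-separated UTF-8.  Study tables carry
one quantification per row with full provenance metadata; the atlas output
mirrors that layout with concentrations in uM.  Concentrations are
serialized with 12 significant digits so the write/read round trip is
lossless well beyond 1e-9 relative precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .concentration import ATLAS_COLUMNS, EstimationParams, ReferenceFilters
from .digest import DigestSpec
from .metabolite import ConversionConstants, TissueCompositionModel

__all__ = [
    "REQUIRED_STUDY_COLUMNS",
    "VALUE_TYPES",
    "read_study_table",
    "write_atlas",
    "read_atlas",
    "read_housekeeping_list",
    "PipelineConfig",
]

#: A study table needs these columns plus at least one of gene/accession.
REQUIRED_STUDY_COLUMNS = [
    "value", "value_type", "study_id", "species", "brain_region",
    "cell_type", "location", "condition", "age",
]
VALUE_TYPES = {"LFQ", "iBAQ", "TMT", "SILAC", "molar", "mol_per_g_protein"}
_VALUE_TYPE_LOOKUP = {v.upper(): v for v in VALUE_TYPES}
_METADATA_COLUMNS = ["species", "brain_region", "cell_type", "location", "condition", "age"]


def read_study_table(path: str | Path) -> pd.DataFrame:
    """Read and validate one per-study quantification table.

    Unknown value types are rejected, non-numeric values raise with the
    offending row number, and blank metadata cells become ``"unknown"``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in REQUIRED_STUDY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing column {col}")
    if "gene" not in df.columns and "accession" not in df.columns:
        raise ValueError("missing column gene (or accession)")

    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.isna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ValueError(f"non-numeric value {df.loc[bad.idxmax(), 'value']!r} at line {row} of {path}")
    df["value"] = values.astype(float)

    normalized_types = df["value_type"].str.strip().str.upper().map(_VALUE_TYPE_LOOKUP)
    if normalized_types.isna().any():
        offender = df.loc[normalized_types.isna(), "value_type"].iloc[0]
        raise ValueError(f"unknown value_type {offender!r} in {path}")
    df["value_type"] = normalized_types

    for col in _METADATA_COLUMNS:
        blank = df[col].str.strip() == ""
        df.loc[blank, col] = "unknown"
    return df


def write_atlas(entries: pd.DataFrame, path: str | Path) -> None:
    """Write the atlas TSV with stable column order and uM concentrations."""
    if entries.empty:
        raise ValueError("refusing to write an empty atlas")
    cols = [c for c in ATLAS_COLUMNS if c in entries.columns]
    cols += [c for c in entries.columns if c not in cols]
    entries[cols].to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_atlas(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"canonical_gene": str})
    if "concentration_uM" not in df.columns:
        raise ValueError("missing column concentration_uM")
    if "normalized" in df.columns:
        df["normalized"] = df["normalized"].astype(bool)
    return df


def read_housekeeping_list(path: str | Path) -> set[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        name = line.split("#", 1)[0].strip()
        if name:
            out.add(name.upper())
    return out


@dataclass
class PipelineConfig:
    """All pipeline constants and paths, overridable from a YAML file.

    Every bulk-cell and tissue constant is an assumption of the method,
    exposed here so users can substitute cell-type or tissue specific
    numbers.
    """

    estimation: EstimationParams = field(default_factory=EstimationParams)
    digest: DigestSpec = field(default_factory=DigestSpec.trypsin)
    metabolite_constants: ConversionConstants = field(default_factory=ConversionConstants)
    tissue_model: TissueCompositionModel = field(default_factory=TissueCompositionModel)
    reference_filters: ReferenceFilters = field(default_factory=ReferenceFilters)
    alpha: float = 0.05
    seed: int = 0
    studies_dir: str | None = None
    fasta: str | None = None
    synonyms: str | None = None
    housekeeping: str | None = None
    out_dir: str = "."

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "estimation" in raw:
            kwargs["estimation"] = EstimationParams(**raw["estimation"])
        if "digest" in raw:
            d = dict(raw["digest"])
            if "cleavage_residues" in d:
                d["cleavage_residues"] = frozenset(d["cleavage_residues"])
            kwargs["digest"] = DigestSpec(**d)
        if "metabolite_constants" in raw:
            kwargs["metabolite_constants"] = ConversionConstants(**raw["metabolite_constants"])
        if "volume_fractions" in raw:
            kwargs["tissue_model"] = TissueCompositionModel(fractions=dict(raw["volume_fractions"]))
        if "reference_filters" in raw:
            rf = dict(raw["reference_filters"])
            for key in ("species", "age_classes", "organelle_only_studies"):
                if key in rf:
                    rf[key] = tuple(rf[key])
            kwargs["reference_filters"] = ReferenceFilters(**rf)
        for key in ("alpha", "seed", "studies_dir", "fasta", "synonyms", "housekeeping", "out_dir"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)
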