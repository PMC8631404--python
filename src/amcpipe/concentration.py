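"""Molar concentration estimation and housekeeping normalization.

The total-protein-mass ("proteomic ruler") approach converts relative MS
signal shares into absolute per-cell quantities using two bulk constants:
total cellular protein concentration (200 g/L) and protein mass per cell
(200 pg).  For one study (one cellular proteome):

    mwWeightNormSumIntens = sum_i (signal_i / detectability_i) * MW_i
    copyNumber_i = (signal_i / detectability_i) * protPerCell * N_A
                   / mwWeightNormSumIntens
    totalVolume  = sum_i (copyNumber_i * MW_i / N_A) / totalCellProtConc
    concentration_i = copyNumber_i / (totalVolume * N_A)

Two algebraic identities follow and serve as self-checks: totalVolume is
always protPerCell/totalCellProtConc (1.0e-12 L with the defaults), and the
mass balance sum_i concentration_i * MW_i recovers 200 g/L exactly.

Studies are then made mutually comparable by a multiplicative per-study
correction that equalizes the median concentration of housekeeping
proteins to a global reference median computed from healthy young-to-middle
aged mouse data (organelle-only sources are normalized with, but never
contribute to, the reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EstimationParams",
    "ReferenceFilters",
    "QuantInput",
    "QuantResult",
    "ATLAS_COLUMNS",
    "estimate_study",
    "convert_reported_units",
    "compute_reference_median",
    "normalize_to_reference",
]

#: Canonical column order of the atlas table (concentrations in uM).
ATLAS_COLUMNS = [
    "canonical_gene",
    "concentration_uM",
    "normalized",
    "data_type",
    "study_id",
    "species",
    "brain_region",
    "cell_type",
    "location",
    "condition",
    "age",
]


@dataclass(frozen=True)
class EstimationParams:
    """Bulk-cell constants of the total-protein-mass approach."""

    total_cell_prot_conc: float = 200.0  # g/L
    prot_per_cell_pg: float = 200.0  # pg
    avogadro: float = 6.02214076e23  # 1/mol

    def __post_init__(self) -> None:
        if min(self.total_cell_prot_conc, self.prot_per_cell_pg, self.avogadro) <= 0:
            raise ValueError("estimation constants must be strictly positive")

    @property
    def prot_per_cell_g(self) -> float:
        return self.prot_per_cell_pg * 1e-12


@dataclass
class QuantInput:
    """One protein's raw quantification within one study."""

    canonical_gene: str
    signal: float  # a.u.; LFQ/iBAQ/TMT/SILAC value
    detectability: float  # theoretical peptide count, or 1 for iBAQ
    mol_weight: float  # g/mol
    data_type: str = "LFQ"
    metadata: dict = field(default_factory=dict)


@dataclass
class QuantResult:
    """Per-study estimation output (Adjusted Molecular Concentrations)."""

    genes: list[str]
    copy_numbers: np.ndarray  # molecules/cell
    concentrations_uM: np.ndarray
    mw_weight_norm_sum_intens: float  # a.u. * g/mol
    total_volume_L: float
    n_dropped: int = 0  # zero/missing-signal entries removed before Eq. 1


def estimate_study(inputs: Sequence[QuantInput], params: EstimationParams | None = None) -> QuantResult:
    """Estimate copy numbers and molar concentrations for one study.

    Entries with zero or missing signal carry no quantification and are
    dropped before the sums; a study with no positive signal is degenerate.
    """
    params = params or EstimationParams()
    kept = [q for q in inputs if q.signal and np.isfinite(q.signal) and q.signal > 0]
    n_dropped = len(inputs) - len(kept)
    if not kept:
        raise ValueError("degenerate study: all signals zero or missing")
    for q in kept:
        if q.mol_weight <= 0:
            raise ValueError(f"non-positive molecular weight for {q.canonical_gene}")
        if q.detectability <= 0:
            raise ValueError(
                f"non-positive detectability for {q.canonical_gene}; exclude upstream"
            )

    signal = np.array([q.signal for q in kept], dtype=float)
    det = np.array([q.detectability for q in kept], dtype=float)
    mw = np.array([q.mol_weight for q in kept], dtype=float)

    norm_signal = signal / det
    mw_sum = float(np.sum(norm_signal * mw))
    copy_numbers = norm_signal * params.prot_per_cell_g * params.avogadro / mw_sum
    total_volume = float(np.sum(copy_numbers * mw / params.avogadro)) / params.total_cell_prot_conc
    conc_molar = copy_numbers / (total_volume * params.avogadro)
    return QuantResult(
        genes=[q.canonical_gene for q in kept],
        copy_numbers=copy_numbers,
        concentrations_uM=conc_molar * 1e6,
        mw_weight_norm_sum_intens=mw_sum,
        total_volume_L=total_volume,
        n_dropped=n_dropped,
    )


_MOLAR_TO_UM = {"M": 1e6, "MM": 1e3, "UM": 1.0, "μM".upper(): 1.0, "NM": 1e-3}


def convert_reported_units(value: float, unit: str, params: EstimationParams | None = None) -> float:
    """Convert an already-absolute reported value to uM.

    Molar-family units rescale directly; mol per g protein crosses to molar
    via the total cellular protein concentration (200 g/L).
    """
    params = params or EstimationParams()
    key = unit.strip().replace("µ", "μ").upper()
    if key in _MOLAR_TO_UM:
        return value * _MOLAR_TO_UM[key]
    if key in {"MOL_PER_G_PROTEIN", "MOL/G PROTEIN", "MOL/G_PROTEIN"}:
        return value * params.total_cell_prot_conc * 1e6
    raise ValueError(f"unknown unit {unit!r}")


@dataclass(frozen=True)
class ReferenceFilters:
    """Selection of entries eligible for the global reference median."""

    species: tuple[str, ...] = ("mouse", "mouse cell line")
    condition: str = "healthy"
    age_classes: tuple[str, ...] = ("young", "middle")
    organelle_only_studies: tuple[str, ...] = ()


def compute_reference_median(
    atlas: pd.DataFrame,
    housekeeping: Iterable[str],
    filters: ReferenceFilters | None = None,
) -> float:
    """Median uM concentration of housekeeping proteins in reference data.

    Reference data: healthy young-to-middle-aged mouse (including mouse
    cell lines), excluding organelle-only studies, restricted to the
    housekeeping gene set.
    """
    filters = filters or ReferenceFilters()
    hk = {g.strip().upper() for g in housekeeping}
    species = {s.lower() for s in filters.species}
    ages = {a.lower() for a in filters.age_classes}
    mask = (
        atlas["canonical_gene"].str.upper().isin(hk)
        & atlas["species"].str.lower().isin(species)
        & (atlas["condition"].str.lower() == filters.condition.lower())
        & atlas["age"].str.lower().isin(ages)
        & ~atlas["study_id"].isin(filters.organelle_only_studies)
        & (atlas["concentration_uM"] > 0)
    )
    pool = atlas.loc[mask, "concentration_uM"]
    if pool.empty:
        raise ValueError("no reference entries after filtering")
    return float(pool.median())


def normalize_to_reference(
    atlas: pd.DataFrame,
    housekeeping: Iterable[str],
    reference_median: float,
) -> pd.DataFrame:
    """Scale every study so its housekeeping median equals the reference.

    The correction is per-study, multiplicative, on the linear uM scale;
    applying it twice is a no-op.  Studies lacking any positive-concentration
    housekeeping gene raise with the study id.
    """
    if reference_median <= 0:
        raise ValueError("reference median must be positive")
    hk = {g.strip().upper() for g in housekeeping}
    out = atlas.copy()
    for study, idx in out.groupby("study_id").groups.items():
        sub = out.loc[idx]
        pool = sub.loc[
            sub["canonical_gene"].str.upper().isin(hk) & (sub["concentration_uM"] > 0),
            "concentration_uM",
        ]
        if pool.empty:
            raise ValueError(f"no housekeeping genes with positive concentration in study {study}")
        study_median = float(pool.median())
        if study_median <= 0:
            raise ValueError(f"zero housekeeping median in study {study}")
        out.loc[idx, "concentration_uM"] = (
            out.loc[idx, "concentration_uM"] * (reference_median / study_median)
        )
    out["normalized"] = True
    return out
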