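"""Metabolite unit standardization, identity alignment and tissue mixing.

Literature metabolite measurements arrive in heterogeneous units (molar,
ng per g wet tissue, nmol per mg dry weight, ...) and at different scales
(tissue, single cell types, extracellular space).  Conversions to uM use
two bulk constants: brain density 1.04 g/mL and brain water content 80%
(so 1 mg dry matter corresponds to 5 mg wet tissue).

Compound identities are aligned to PubChem CIDs through an offline name
table plus a manual override map.  Tissue-level concentrations are
predicted from compartment concentrations by volume-fraction mixing:
extracellular 0.19, vasculature 0.03, neuronal somas 0.10, neurites 0.60,
glia 0.08.  Neuronal concentration supplies both soma and neurites; the
glia term uses the astrocytic concentration, imputed from the neuronal one
when missing.  Records lacking a blood or extracellular value are excluded
rather than imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "MetaboliteRecord",
    "ConversionConstants",
    "TissueCompositionModel",
    "to_molar",
    "from_molar",
    "align_cid",
    "load_cid_table",
    "mix_tissue",
    "compare_predicted_to_measured",
]

COMPARTMENTS = {"tissue", "neuron", "astrocyte", "blood", "extracellular"}


@dataclass(frozen=True)
class ConversionConstants:
    brain_density: float = 1.04  # g/mL
    water_fraction: float = 0.80  # dimensionless

    def __post_init__(self) -> None:
        if self.brain_density <= 0:
            raise ValueError("density must be positive")
        if not 0 < self.water_fraction < 1:
            raise ValueError("water fraction must be in (0,1)")

    @property
    def dry_per_wet(self) -> float:
        """mg dry matter per mg wet tissue (0.20 at 80% water)."""
        return 1.0 - self.water_fraction


@dataclass
class MetaboliteRecord:
    """One literature metabolite measurement with provenance."""

    name: str
    value: float
    unit: str
    compartment: str = "tissue"
    cid: int | None = None
    mol_weight: float | None = None  # g/mol, needed for mass-based units
    species: str = "unknown"
    method: str = "other"  # MRS, MS, other
    source: str = "unknown"

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"negative value for {self.name}")
        base = self.compartment.split(":", 1)[0]
        if base not in COMPARTMENTS and base != "organelle":
            raise ValueError(f"unknown compartment {self.compartment!r}")


_MOLAR_TO_UM = {"M": 1e6, "MM": 1e3, "UM": 1.0, "NM": 1e-3}


def _unit_key(unit: str) -> str:
    return unit.strip().replace("µ", "u").replace("μ", "u").upper().replace(" ", "_")


def to_molar(record: MetaboliteRecord, constants: ConversionConstants | None = None) -> float:
    """Convert one record's value to uM.

    ng/g wet:     value*1e-9 g/g * density g/mL * 1000 mL/L / MW -> mol/L
    nmol/mg dry:  value * dry_per_wet (nmol/mg wet = umol/g wet)
                  * density * 1000 -> nmol/L... handled in umol/L directly
    nmol/g wet, umol/g wet: density bridge only (no MW needed)
    molar family: metric rescale
    """
    constants = constants or ConversionConstants()
    key = _unit_key(record.unit)
    v = record.value
    if key in _MOLAR_TO_UM:
        return v * _MOLAR_TO_UM[key]
    if key in {"NG_PER_G_WET", "NG/G_WET", "NG/G_WET_TISSUE"}:
        if record.mol_weight is None or record.mol_weight <= 0:
            raise ValueError(f"mol_weight required for unit {record.unit!r} ({record.name})")
        mol_per_L = v * 1e-9 * constants.brain_density * 1000.0 / record.mol_weight
        return mol_per_L * 1e6
    if key in {"NMOL_PER_MG_DRY", "NMOL/MG_DRY", "NMOL/MG_DRY_WEIGHT"}:
        # nmol/mg dry -> nmol/mg wet -> umol/g wet -> uM via density
        umol_per_g_wet = v * constants.dry_per_wet
        return umol_per_g_wet * constants.brain_density * 1000.0
    if key in {"NMOL_PER_G_WET", "NMOL/G_WET"}:
        return v * 1e-3 * constants.brain_density * 1000.0
    if key in {"UMOL_PER_G_WET", "UMOL/G_WET"}:
        return v * constants.brain_density * 1000.0
    raise ValueError(f"unknown unit {record.unit!r}")


def from_molar(value_uM: float, unit: str, mol_weight: float | None = None,
               constants: ConversionConstants | None = None) -> float:
    """Inverse of :func:`to_molar` (used for round-trip checks and emission)."""
    constants = constants or ConversionConstants()
    key = _unit_key(unit)
    if key in _MOLAR_TO_UM:
        return value_uM / _MOLAR_TO_UM[key]
    if key in {"NG_PER_G_WET", "NG/G_WET", "NG/G_WET_TISSUE"}:
        if mol_weight is None or mol_weight <= 0:
            raise ValueError("mol_weight required")
        return value_uM * 1e-6 * mol_weight / (constants.brain_density * 1000.0) / 1e-9
    if key in {"NMOL_PER_MG_DRY", "NMOL/MG_DRY", "NMOL/MG_DRY_WEIGHT"}:
        return value_uM / (constants.brain_density * 1000.0) / constants.dry_per_wet
    if key in {"NMOL_PER_G_WET", "NMOL/G_WET"}:
        return value_uM / (1e-3 * constants.brain_density * 1000.0)
    if key in {"UMOL_PER_G_WET", "UMOL/G_WET"}:
        return value_uM / (constants.brain_density * 1000.0)
    raise ValueError(f"unknown unit {unit!r}")


def load_cid_table(path) -> dict[str, int]:
    """Load a name -> PubChem CID table (TSV: name, cid).

    Names are lower-cased; a name mapped to two different CIDs is a table
    defect and raises at load.
    """
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "cid": int})
    for col in ("name", "cid"):
        if col not in df.columns:
            raise ValueError(f"CID table missing column {col}")
    table: dict[str, int] = {}
    for _, row in df.iterrows():
        key = row["name"].strip().lower()
        cid = int(row["cid"])
        if key in table and table[key] != cid:
            raise ValueError(f"conflicting CID for name {key!r}: {table[key]} vs {cid}")
        table[key] = cid
    return table


def align_cid(
    records: list[MetaboliteRecord],
    cid_table: dict[str, int],
    manual_map: dict[str, int] | None = None,
) -> tuple[list[MetaboliteRecord], dict[str, int]]:
    """Assign PubChem CIDs by name; manual curation overrides the table.

    Records already carrying a CID are left unchanged; unresolvable names
    are retained and counted in the report.
    """
    manual = {k.strip().lower(): v for k, v in (manual_map or {}).items()}
    report = {"resolved": 0, "unresolved": 0}
    for rec in records:
        if rec.cid is not None:
            report["resolved"] += 1
            continue
        key = rec.name.strip().lower()
        if key in manual:
            rec.cid = manual[key]
            report["resolved"] += 1
        elif key in cid_table:
            rec.cid = cid_table[key]
            report["resolved"] += 1
        else:
            report["unresolved"] += 1
            logger.warning("unresolved metabolite name %r", rec.name)
    return records, report


@dataclass(frozen=True)
class TissueCompositionModel:
    """Brain tissue volume fractions for compartment mixing."""

    fractions: dict = field(
        default_factory=lambda: {
            "extracellular": 0.19,
            "vasculature": 0.03,
            "neuron_soma": 0.10,
            "neurites": 0.60,
            "glia": 0.08,
        }
    )

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"volume fractions sum to {total}, expected 1.0")
        if any(not 0 <= f <= 1 for f in self.fractions.values()):
            raise ValueError("volume fractions must lie in [0,1]")


def mix_tissue(
    per_compartment: dict[int, dict[str, float]],
    model: TissueCompositionModel | None = None,
) -> tuple[dict[int, float], list[int]]:
    """Predict tissue uM from compartment uM by volume-fraction mixing.

    ``per_compartment`` maps CID -> {neuron, astrocyte, blood,
    extracellular} -> uM.  The neuronal concentration fills both the soma
    and neurite fractions; the glia fraction uses the astrocytic
    concentration (imputed from neuron when missing); vasculature uses
    blood.  CIDs still missing a compartment after imputation are excluded
    and returned in the second element.
    """
    model = model or TissueCompositionModel()
    f = model.fractions
    predicted: dict[int, float] = {}
    excluded: list[int] = []
    for cid, comp in per_compartment.items():
        neuron = comp.get("neuron")
        astro = comp.get("astrocyte", neuron)  # imputation rule
        blood = comp.get("blood")
        extra = comp.get("extracellular")
        if any(x is None for x in (neuron, astro, blood, extra)):
            excluded.append(cid)
            logger.warning("CID %s missing a compartment after imputation; excluded", cid)
            continue
        predicted[cid] = (
            f["extracellular"] * extra
            + f["vasculature"] * blood
            + (f["neuron_soma"] + f["neurites"]) * neuron
            + f["glia"] * astro
        )
    return predicted, excluded


def compare_predicted_to_measured(
    predicted: dict[int, float], measured: dict[int, float]
) -> dict[str, float]:
    """Rank and linear correlation of predicted vs measured tissue uM.

    Returns ``{"n_common", "spearman_rho", "pearson_r"}`` over the common
    CIDs; fewer than 3 common compounds is insufficient overlap.
    """
    common = sorted(set(predicted) & set(measured))
    if len(common) < 3:
        raise ValueError("insufficient overlap: fewer than 3 common compounds")
    p = [predicted[c] for c in common]
    m = [measured[c] for c in common]
    rho = float(sps.spearmanr(p, m).statistic)
    r = float(sps.pearsonr(p, m).statistic)
    return {"n_common": len(common), "spearman_rho": rho, "pearson_r": r}
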