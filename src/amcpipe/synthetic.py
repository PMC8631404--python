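"""Synthetic multi-study proteomics/metabolomics fixtures with ground truth.

Stands in for the heterogeneous literature studies the pipeline is built
to integrate: it emits per-study quantification tables whose signals are
true per-cell copy numbers distorted by exactly the nuisances the pipeline
must undo — per-protein detectability (theoretical peptide count for
LFQ/TMT/SILAC, none for iBAQ), a per-study multiplicative batch scale
factor, lognormal measurement noise, gene-label corruption through a
registered (hence invertible) synonym registry, and dropout.

Protein abundances and noise are lognormal — the standard model for MS
proteomics — with true copy numbers spanning roughly four orders of
magnitude.  Sequences follow a lognormal length distribution (median ~400
residues) with ~11% K/R content, so nearly every protein digests into at
least one detectable tryptic peptide.  A designated housekeeping subset
(~5% of genes) is shared unchanged across studies and anchors the
normalization.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .digest import DigestSpec, ProteinSequence, count_theoretical_peptides, molecular_weight
from .metabolite import ConversionConstants, from_molar

__all__ = ["Proteome", "SyntheticStudy", "generate_proteome", "simulate_study",
           "simulate_metabolome"]

# Rough mammalian amino-acid frequencies, with K+R set to ~11%.
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_AA_FREQ = np.array([
    0.074, 0.020, 0.048, 0.068, 0.036, 0.066, 0.026, 0.042, 0.058, 0.098,
    0.022, 0.038, 0.056, 0.046, 0.052, 0.075, 0.053, 0.062, 0.012, 0.048,
])
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()


@dataclass
class Proteome:
    """Ground-truth proteome shared by all simulated studies."""

    genes: list[str]
    sequences: dict[str, ProteinSequence]
    true_copy_numbers: dict[str, float]  # molecules/cell
    mol_weights: dict[str, float]  # g/mol
    accessions: dict[str, str]
    synonyms: dict[str, str]  # gene -> registered alternative label
    housekeeping: set[str]
    seed: int

    def synonym_table_rows(self) -> list[tuple[str, list[str], str]]:
        """Rows (accession, [gene, synonym], species) for the offline table."""
        return [
            (self.accessions[g], [g, self.synonyms[g]], "mouse") for g in self.genes
        ]

    def true_concentrations_uM(self, params=None) -> dict[str, float]:
        """Molar concentrations implied by the true copy numbers.

        Uses the same bulk-cell volume as the estimation pipeline
        (protPerCell/totalCellProtConc = 1e-12 L by default).
        """
        from .concentration import EstimationParams

        params = params or EstimationParams()
        volume = params.prot_per_cell_g / params.total_cell_prot_conc
        na = params.avogadro
        return {g: c / (volume * na) * 1e6 for g, c in self.true_copy_numbers.items()}


@dataclass
class SyntheticStudy:
    """One generated study table plus its ground truth."""

    study_id: str
    data_type: str
    table: pd.DataFrame
    batch_factor: float
    noise_cv: float
    corrupted_labels: dict[str, str]  # emitted label -> true gene
    dropped_genes: set[str]
    housekeeping: set[str]
    seed: int


def generate_proteome(
    n_genes: int,
    seed: int,
    housekeeping_frac: float = 0.05,
    median_length: int = 400,
    length_sigma: float = 0.45,
    abundance_sigma_ln: float = 2.3,
) -> Proteome:
    """Generate gene symbols, sequences, weights and true copy numbers.

    ``abundance_sigma_ln`` = 2.3 puts ~95% of copy numbers within four
    orders of magnitude, matching the dynamic range of deep MS proteomes.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    rng = np.random.default_rng(seed)
    genes = [f"SYG{i:05d}" for i in range(n_genes)]
    synonyms = {g: f"{1100000 + i:07d}RIK" for i, g in enumerate(genes)}
    accessions = {g: f"P{10000 + i:05d}" for i, g in enumerate(genes)}

    lengths = np.maximum(
        50, np.round(rng.lognormal(np.log(median_length), length_sigma, n_genes))
    ).astype(int)
    sequences: dict[str, ProteinSequence] = {}
    mol_weights: dict[str, float] = {}
    for g, L in zip(genes, lengths):
        residues = "".join(rng.choice(_AA, size=L, p=_AA_FREQ))
        seq = ProteinSequence(identifier=g, residues=residues)
        sequences[g] = seq
        mol_weights[g] = molecular_weight(seq)

    # median ~1e4 copies/cell, ~4 orders of magnitude overall
    copies = rng.lognormal(np.log(1e4), abundance_sigma_ln, n_genes)
    true_copy_numbers = dict(zip(genes, copies))

    n_hk = max(2, int(round(housekeeping_frac * n_genes)))
    # housekeeping anchors are drawn from mid-to-high abundance for stable medians
    order = np.argsort(copies)
    candidates = [genes[i] for i in order[n_genes // 2 :]]
    housekeeping = set(rng.choice(candidates, size=min(n_hk, len(candidates)), replace=False))

    return Proteome(
        genes=genes,
        sequences=sequences,
        true_copy_numbers=true_copy_numbers,
        mol_weights=mol_weights,
        accessions=accessions,
        synonyms=synonyms,
        housekeeping=housekeeping,
        seed=seed,
    )


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(-sigma2 / 2, np.sqrt(sigma2), size)


def simulate_study(
    proteome: Proteome,
    data_type: str = "LFQ",
    batch_factor: float = 1.0,
    noise_cv: float = 0.2,
    synonym_corruption_rate: float = 0.0,
    dropout_rate: float = 0.0,
    seed: int = 0,
    study_id: str | None = None,
    species: str = "mouse",
    brain_region: str = "cortex",
    cell_type: str = "neuron",
    location: str = "cell",
    condition: str = "healthy",
    age: str = "young",
    digest_spec: DigestSpec | None = None,
) -> SyntheticStudy:
    """Emit one study table: signal = copies * detectability * batch * noise.

    Detectability is the theoretical tryptic peptide count for
    LFQ/TMT/SILAC and 1 for iBAQ (zero-peptide proteins are skipped for
    peptide-scaled types, as a real pipeline would never see them).
    Dropout is guarded so at least two housekeeping genes always survive.
    """
    for name, rate in (("synonym_corruption_rate", synonym_corruption_rate),
                       ("dropout_rate", dropout_rate)):
        if not 0 <= rate <= 1:
            raise ValueError(f"{name} must lie in [0,1]")
    if batch_factor <= 0:
        raise ValueError("batch_factor must be positive")
    dt = data_type.strip().upper()
    if dt not in {"LFQ", "IBAQ", "TMT", "SILAC", "MOLAR"}:
        raise ValueError(f"unknown data_type {data_type!r}")
    dt = "iBAQ" if dt == "IBAQ" else dt
    rng = np.random.default_rng(seed)
    study_id = study_id or f"study_{dt}_{seed}"
    spec = digest_spec or DigestSpec.trypsin()

    rows = []
    corrupted: dict[str, str] = {}
    dropped: set[str] = set()
    # dropout guard: keep >=2 housekeeping genes
    hk = sorted(proteome.housekeeping)
    protected = set(rng.choice(hk, size=min(2, len(hk)), replace=False))
    for gene in proteome.genes:
        if gene not in protected and rng.random() < dropout_rate:
            dropped.add(gene)
            continue
        copies = proteome.true_copy_numbers[gene]
        if dt == "MOLAR":
            det = 1.0
        elif dt == "iBAQ":
            det = 1.0
        else:
            det = count_theoretical_peptides(proteome.sequences[gene], spec)
            if det == 0:
                dropped.add(gene)
                continue
        noise = _lognormal_noise(rng, noise_cv, 1)[0]
        if dt == "MOLAR":
            # report a true molar concentration (uM) perturbed by noise only
            volume = 1e-12  # L, bulk-cell volume of the default constants
            value = copies / (volume * 6.02214076e23) * 1e6 * noise
            value_type = "molar"
        else:
            value = copies * det * batch_factor * noise
            value_type = dt
        label = gene
        if rng.random() < synonym_corruption_rate:
            label = proteome.synonyms[gene]
            corrupted[label] = gene
        rows.append(
            (label, proteome.accessions[gene], value, value_type, study_id,
             species, brain_region, cell_type, location, condition, age)
        )
    table = pd.DataFrame(
        rows,
        columns=["gene", "accession", "value", "value_type", "study_id", "species",
                 "brain_region", "cell_type", "location", "condition", "age"],
    )
    return SyntheticStudy(
        study_id=study_id,
        data_type=dt,
        table=table,
        batch_factor=batch_factor,
        noise_cv=noise_cv,
        corrupted_labels=corrupted,
        dropped_genes=dropped,
        housekeeping=set(proteome.housekeeping),
        seed=seed,
    )


_METAB_UNITS = ("uM", "ng_per_g_wet", "nmol_per_mg_dry")


def simulate_metabolome(
    n_compounds: int,
    compartments: tuple[str, ...] = ("tissue", "neuron", "astrocyte", "blood", "extracellular"),
    seed: int = 0,
    noise_cv: float = 0.0,
    constants: ConversionConstants | None = None,
) -> dict:
    """Generate metabolite tables in mixed units with known true uM values.

    Returns a dict with ``records`` (DataFrame in the metabolite table
    layout), ``truth`` (cid -> compartment -> uM), ``cid_table`` (name
    variant -> CID) and ``mol_weights``.  Emitted values are the truth
    expressed in a randomly chosen unit via the module's constants, so
    converting them back to uM recovers the truth exactly at zero noise.
    """
    if n_compounds < 5:
        raise ValueError("n_compounds must be >= 5")
    from .metabolite import COMPARTMENTS

    for c in compartments:
        if c.split(":", 1)[0] not in COMPARTMENTS and not c.startswith("organelle"):
            raise ValueError(f"unknown compartment {c!r}")
    constants = constants or ConversionConstants()
    rng = np.random.default_rng(seed)
    names = [f"met{i:04d}" for i in range(n_compounds)]
    cids = {name: 100000 + i for i, name in enumerate(names)}
    mol_weights = {name: float(rng.uniform(75, 500)) for name in names}
    # name variants (case and suffix forms) all mapping to the same CID
    cid_table: dict[str, int] = {}
    for name, cid in cids.items():
        cid_table[name] = cid
        cid_table[f"{name}-acid"] = cid
        cid_table[name.upper().lower()] = cid

    truth: dict[int, dict[str, float]] = {}
    rows = []
    for name in names:
        cid = cids[name]
        truth[cid] = {}
        for comp in compartments:
            true_uM = float(rng.lognormal(np.log(50.0), 1.5))
            truth[cid][comp] = true_uM
            unit = _METAB_UNITS[rng.integers(len(_METAB_UNITS))]
            value = from_molar(true_uM, unit, mol_weights[name], constants)
            if noise_cv > 0:
                value *= _lognormal_noise(rng, noise_cv, 1)[0]
            emitted_name = name if rng.random() < 0.7 else f"{name}-acid"
            rows.append(
                (emitted_name, "", value, unit, mol_weights[name], comp, "mouse",
                 "MS" if unit != "uM" else "MRS", f"synthetic_{seed}")
            )
    records = pd.DataFrame(
        rows,
        columns=["name", "cid", "value", "unit", "mol_weight", "compartment",
                 "species", "method", "source"],
    )
    return {"records": records, "truth": truth, "cid_table": cid_table,
            "mol_weights": mol_weights}
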