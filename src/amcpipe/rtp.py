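"""RNA-to-protein (RTP) conversion ratios.

Paired multi-omics references (same study measuring both transcriptome and
proteome) allow a per-gene conversion ratio protein_uM / expression to be
fitted and applied to expression-only data, filling cell types and brain
regions that lack direct protein quantification.  This is a deliberately
direct estimator — one ratio per gene, no smoothing, no cell-type specific
correction — so cross-cell-type degradation is expected and is reported,
not corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["RtpModel", "fit_rtp", "predict_protein"]

EXPRESSION_UNITS = {"RPKM", "TPM"}


@dataclass
class RtpModel:
    """Per-gene protein/expression ratios in uM per expression unit."""

    ratios: dict[str, float]
    unit: str = "RPKM"
    reference: dict = field(default_factory=dict)
    excluded_zero_expression: list[str] = field(default_factory=list)


def _mean(v) -> float:
    if isinstance(v, (int, float, np.floating)):
        return float(v)
    return float(np.mean(np.asarray(v, dtype=float)))


def fit_rtp(
    ref_expression: Mapping[str, float | Sequence[float]],
    ref_protein: Mapping[str, float | Sequence[float]],
    unit: str = "RPKM",
    reference: dict | None = None,
) -> RtpModel:
    """Fit ratio_g = protein_g / expression_g over the common gene set.

    Replicates are averaged per gene before the ratio.  Genes with zero
    expression are excluded and recorded on the model.
    """
    if unit not in EXPRESSION_UNITS:
        raise ValueError(f"unknown expression unit {unit!r}")
    common = sorted(set(ref_expression) & set(ref_protein))
    if not common:
        raise ValueError("empty gene intersection between expression and protein references")
    ratios: dict[str, float] = {}
    excluded: list[str] = []
    for gene in common:
        expr = _mean(ref_expression[gene])
        prot = _mean(ref_protein[gene])
        if expr <= 0:
            excluded.append(gene)
            continue
        ratios[gene] = prot / expr
    if not ratios:
        raise ValueError("no genes with positive expression")
    if excluded:
        logger.info("excluded %d genes with zero expression", len(excluded))
    return RtpModel(ratios=ratios, unit=unit, reference=reference or {},
                    excluded_zero_expression=excluded)


def predict_protein(
    expression: Mapping[str, float | Sequence[float]],
    model: RtpModel,
    unit: str | None = None,
) -> tuple[dict[str, float], int]:
    """Predict protein uM as ratio_g * expression_g, gene-wise linear.

    Genes without a fitted ratio are omitted; their count is returned.
    The expression unit must match the model's.
    """
    if unit is not None and unit != model.unit:
        raise ValueError(f"expression unit {unit!r} does not match model unit {model.unit!r}")
    predicted: dict[str, float] = {}
    missing = 0
    for gene, value in expression.items():
        ratio = model.ratios.get(gene)
        if ratio is None:
            missing += 1
            continue
        predicted[gene] = ratio * _mean(value)
    return predicted, missing
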