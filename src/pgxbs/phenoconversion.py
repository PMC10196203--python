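"""Phenoconversion: adjusting metabolizer phenotypes for drug–drug
interactions.

A genotype-predicted metabolizer phenotype describes the enzyme the patient
was born with, not the enzyme they are running today: co-medications that
inhibit or induce the enzyme can convert, say, a genotypic normal
metabolizer into a functional poor metabolizer. For activity-score genes
the adjustment multiplies the diplotype activity score by one factor per
matching perpetrator drug (strong inhibitor ×0, moderate inhibitor ×0.5,
moderate inducer ×1.5, strong inducer ×2 by default — the factors are data
in the knowledge base) and re-bins the result. For categorical metabolizer
genes, which have no activity score, the adjustment shifts the label along
the PM < IM < NM < RM < UM ordering: a strong inhibitor forces PM, a
moderate inhibitor steps down one label, moderate/strong inducers step up
one/two labels, capped at the ends.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel

from .knowledge_base import (
    KnowledgeBase,
    METABOLIZER_ORDER,
    Phenotype,
    PhenotypeCall,
    PhenotypeSystem,
    bin_activity_score,
)

_INHIBITORS = ("strong_inhibitor", "moderate_inhibitor")
_ORDINAL_SHIFT = {
    "moderate_inhibitor": -1,
    "moderate_inducer": +1,
    "strong_inducer": +2,
}


class PhenoconvertedCall(BaseModel):
    """A phenotype call adjusted for interacting co-medications."""

    base: PhenotypeCall
    perpetrators: list[tuple[str, str]]  # (drug, strength) applied
    adjusted_activity: Optional[float] = None
    adjusted_label: Phenotype
    phenoconverted: bool  # true iff adjusted label differs from the base label

    def as_call(self) -> PhenotypeCall:
        """The adjusted call in the shape the scorer consumes."""
        return self.base.model_copy(
            update={
                "phenotype": self.adjusted_label,
                "activity_score": self.adjusted_activity,
                "phenoconverted": self.phenoconverted,
            }
        )


def apply_phenoconversion(
    call: PhenotypeCall, comedications: list[str], kb: KnowledgeBase
) -> PhenoconvertedCall:
    """Adjust a metabolizer phenotype for inhibitors/inducers among
    ``comedications``.

    With no matching perpetrator the call is returned unchanged. Inhibitors
    never raise and inducers never lower the adjusted activity relative to
    the base. Carrier-system genes cannot be phenoconverted and raise
    ``ValueError``.
    """
    gdef = kb.genes.get(call.gene_symbol)
    if gdef is None or gdef.phenotype_system is not PhenotypeSystem.METABOLIZER:
        raise ValueError(
            f"phenoconversion applies only to metabolizer-system genes, "
            f"not {call.gene_symbol}"
        )

    matched = kb.perpetrators_for(call.gene_symbol, comedications)
    perpetrators = [(m.perpetrator_drug, m.strength) for m in matched]

    if not matched or call.indeterminate:
        return PhenoconvertedCall(
            base=call,
            perpetrators=perpetrators if not call.indeterminate else [],
            adjusted_activity=call.activity_score,
            adjusted_label=call.phenotype,
            phenoconverted=False,
        )

    if call.activity_score is not None:
        factor = 1.0
        for m in matched:
            factor *= kb.phenoconversion_multipliers[m.strength]
        adjusted = call.activity_score * factor
        label = bin_activity_score(kb, call.gene_symbol, adjusted)
        return PhenoconvertedCall(
            base=call,
            perpetrators=perpetrators,
            adjusted_activity=adjusted,
            adjusted_label=label,
            phenoconverted=label is not call.phenotype,
        )

    # categorical metabolizer gene: ordinal label shift
    if any(m.strength == "strong_inhibitor" for m in matched):
        label = Phenotype.PM
    else:
        idx = METABOLIZER_ORDER.index(call.phenotype)
        idx += sum(_ORDINAL_SHIFT[m.strength] for m in matched)
        idx = max(0, min(idx, len(METABOLIZER_ORDER) - 1))
        label = METABOLIZER_ORDER[idx]
    return PhenoconvertedCall(
        base=call,
        perpetrators=perpetrators,
        adjusted_activity=None,
        adjusted_label=label,
        phenoconverted=label is not call.phenotype,
    )
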