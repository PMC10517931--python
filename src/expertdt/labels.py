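"""Label vocabulary shared across the pipeline.

Four renal-cell-carcinoma subtypes (the final classes), three not-tumor
tissue categories that collapse into a single NT super-class, and the
sentinel labels used by tile-label maps.
"""

from __future__ import annotations

CCRCC = "ccRCC"
PAPRCC = "papRCC"
CHRRCC = "chrRCC"
ONCO = "ONCO"

#: The four subtype classes, in decreasing order of clinical prevalence.
#: This order also breaks patient-vote ties.
SUBTYPES: tuple[str, ...] = (CCRCC, PAPRCC, CHRRCC, ONCO)

FIBER = "fiber"
NECROSIS = "necrosis"
NORMAL_PARENCHYMA = "normal_parenchyma"

#: Tissue categories that form the not-cancer super-class.
NOT_TUMOR_TISSUES: tuple[str, ...] = (FIBER, NECROSIS, NORMAL_PARENCHYMA)

#: Every label an ROI annotation may carry.
ROI_LABELS: tuple[str, ...] = SUBTYPES + NOT_TUMOR_TISSUES

TUMOR = "T"
NOT_TUMOR = "NT"

#: Sentinels: cells that never enter a classifier and never vote.
BACKGROUND = "BACKGROUND"
OUT_OF_STAGE = "OUT_OF_STAGE"
SENTINELS: frozenset[str] = frozenset({BACKGROUND, OUT_OF_STAGE})

#: Patient-level outcome when no tile is predicted as tumor.
NO_TUMOR = "NO_TUMOR"


def collapse_to_super(label: str) -> str:
    """Map a terminal ROI label to its training super-class.

    Subtypes map to themselves; fiber/necrosis/normal parenchyma map to NT.
    """
    if label in SUBTYPES:
        return label
    if label in NOT_TUMOR_TISSUES:
        return NOT_TUMOR
    raise ValueError(f"unknown tissue label: {label!r}")
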