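"""Hierarchical majority voting: cells -> image label -> well decision.

An image pre-screened negative (no candidate region) is negative outright.
Otherwise its label is the strict majority of its cell labels; a tied cell
vote resolves to positive — the conservative direction for a screening
assay, and recoverable at the well vote. An image whose every candidate was
discarded as an extracellular artifact is negative: nothing intracellular
fluoresced.

A well takes the strict majority of its image labels and SUSPENDS the
decision when the counts tie, deferring to the physician rather than
guessing. Suspension happens iff ``n_pos_images == n_neg_images``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import NEGATIVE, POSITIVE, SUSPENDED
from .screening import PRESUMED_NEGATIVE


@dataclass
class WellDecision:
    well_id: str
    decision: str  # positive | negative | suspended
    image_labels: list[str]
    n_pos_images: int
    n_neg_images: int


def classify_image(cell_labels: list[str], prescreen: str) -> str:
    """Majority vote over cell labels, honoring the pre-screen."""
    if prescreen == PRESUMED_NEGATIVE:
        return NEGATIVE
    if not cell_labels:
        return NEGATIVE  # every candidate was an extracellular artifact
    n_pos = sum(1 for lab in cell_labels if lab == POSITIVE)
    n_neg = len(cell_labels) - n_pos
    return POSITIVE if n_pos >= n_neg else NEGATIVE


def classify_well(well_id: str, image_labels: list[str]) -> WellDecision:
    """Majority vote over image labels; a tied vote suspends the decision."""
    if not image_labels:
        raise ValueError(f"well {well_id!r} has no image labels")
    n_pos = sum(1 for lab in image_labels if lab == POSITIVE)
    n_neg = len(image_labels) - n_pos
    if n_pos > n_neg:
        decision = POSITIVE
    elif n_neg > n_pos:
        decision = NEGATIVE
    else:
        decision = SUSPENDED
    return WellDecision(
        well_id=well_id,
        decision=decision,
        image_labels=list(image_labels),
        n_pos_images=n_pos,
        n_neg_images=n_neg,
    )


# The full pipeline (screening -> cells -> features -> predict -> voting)
# lives in pipeline.py; re-exported here as part of the aggregation surface.
from .pipeline import run_pipeline  # noqa: E402, F401
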