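"""Probability that a scheduled visit detects a latent recurrence.

Examinations performed at the same visit are combined assuming conditional
independence of false negatives, the standard assumption in surveillance
decision models:

    P(detect) = 1 - prod_i (1 - sens_i)

over the examinations with an applicable distant-recurrence sensitivity.
Colonoscopy has no such sensitivity and contributes nothing to detection.
Specificity is treated as 1 (no false-positive work-ups are modeled).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .errors import ValidationError


@dataclass(frozen=True)
class SensitivitySet:
    """Per-examination sensitivity for distant (liver/lung) recurrence."""

    clinical_evaluation: float = 0.23
    laboratory: float = 0.58
    cect: float = 0.92

    def __post_init__(self) -> None:
        for name in ("clinical_evaluation", "laboratory", "cect"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"sensitivity {name}={v} outside [0, 1]")

    def get(self, exam_name: str) -> float | None:
        """Sensitivity for an examination name, or None if not applicable."""
        return getattr(self, exam_name, None)


def visit_detection_prob(tests: Iterable[str], sens: SensitivitySet) -> float:
    """Detection probability for one visit given the examinations performed.

    ``tests`` holds examination names; names without an applicable
    sensitivity (colonoscopy) contribute nothing.  Empty set -> 0.
    """
    miss = 1.0
    for name in tests:
        s = sens.get(name)
        if s is not None:
            miss *= 1.0 - s
    return 1.0 - miss
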