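"""Study design: two opposing comparison arms around a deacetylase.

The experiment contrasts a knockdown arm (enzyme-depleted vs. its paired
control) and an overexpression arm (enzyme-overexpressing vs. its paired
control), one run per condition.  Each arm is an (experimental, control)
pair of sample identifiers; all downstream fold changes are
experimental/control on the linear intensity scale.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

KNOCKDOWN = "knockdown"
OVEREXPRESSION = "overexpression"
ARMS = (KNOCKDOWN, OVEREXPRESSION)

#: A comparison expressed as log2-space coefficients per sample id.  The
#: standard arms are simple pairs {experimental: +1, control: -1}; the
#: scrambled validation schemes use composite contrasts over all four samples.
Contrast = dict[str, float]


@dataclass(frozen=True)
class StudyDesign:
    """The 4-sample, 2-arm design: each arm is (experimental, control)."""

    knockdown: tuple[str, str]
    overexpression: tuple[str, str]

    def __post_init__(self) -> None:
        ids = (*self.knockdown, *self.overexpression)
        if len(set(ids)) != 4:
            raise ValidationError(f"the 4 sample ids must be distinct, got {ids}")

    @property
    def arms(self) -> dict[str, tuple[str, str]]:
        return {KNOCKDOWN: self.knockdown, OVEREXPRESSION: self.overexpression}

    @property
    def sample_ids(self) -> tuple[str, str, str, str]:
        """All sample ids, ordered (kd experimental, kd control, oe experimental, oe control)."""
        return (*self.knockdown, *self.overexpression)

    def contrasts(self) -> dict[str, Contrast]:
        """Log2-space contrast per arm: experimental minus control."""
        return {
            arm: {exp: +1.0, ctl: -1.0} for arm, (exp, ctl) in self.arms.items()
        }


#: Sample numbering follows the study convention: 1 = control shRNA,
#: 3 = deacetylase shRNA, 5 = vector + acetyltransferases,
#: 7 = deacetylase overexpression + acetyltransferases.
DEFAULT_DESIGN = StudyDesign(knockdown=("s3", "s1"), overexpression=("s7", "s5"))
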