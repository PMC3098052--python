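"""The alpha uniqueness score.

alpha = I1 - I2, where I1 is the highest average percent identity I among
the alignments supporting the classification and I2 the highest I among
the alignments indicating a different classification.  With no conflicting
alignments there is no I2 term and alpha equals I1.  For a missing gene
the conflicts are alignments to annotated genes or entity-overlapping
ORFs; for an absent annotation only alignments to entity-overlapping ORFs
conflict (gene-hit identities never enter I2 for absents, even when
larger).  alpha is reported unclamped and may in principle be negative.
"""

from __future__ import annotations

from collections.abc import Sequence

from .model import LABEL_ABSENT, LABEL_MISSING, AlignmentHit


def alpha_score(
    label: str,
    supporting: Sequence[AlignmentHit],
    conflicting: Sequence[AlignmentHit],
) -> float:
    """alpha = max I over supporting hits minus max I over conflicting hits."""
    if label not in (LABEL_MISSING, LABEL_ABSENT):
        raise ValueError(f"alpha is defined only for missing/absent labels, got {label!r}")
    if not supporting:
        raise ValueError(f"label {label!r} requires at least one supporting hit")
    i1 = max(h.I for h in supporting)
    if not conflicting:
        return i1
    i2 = max(h.I for h in conflicting)
    return i1 - i2


def group_alpha(member_alphas: Sequence[float]) -> float:
    """Arithmetic mean of the member alpha scores of a missing-gene group."""
    if not member_alphas:
        raise ValueError("empty group")
    return sum(member_alphas) / len(member_alphas)
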