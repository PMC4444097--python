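"""Tags-per-million normalization, zero-count floor, and fold change.

A tag's expression in a library is its clean-tag count scaled to tags
per million (TPM): ``count / library_total * 1e6``.  A tag absent from
one library (count 0) gets a small floor TPM (default 0.01) so the log2
fold change stays defined; the floor is applied on the TPM scale, not as
a pseudocount on the raw counts.  Fold change is the absolute log2 ratio
of the two *unrounded* TPM values — rounding before the ratio visibly
distorts large fold changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .tag_io import CountPair, LibraryPair

__all__ = [
    "ExpressionPair",
    "FoldChange",
    "DEFAULT_FLOOR",
    "tpm",
    "expression_pair",
    "apply_floor",
    "fold_change",
]

DEFAULT_FLOOR = 0.01  # TPM substituted for a zero count


@dataclass(frozen=True)
class ExpressionPair:
    tpm_a: float
    tpm_b: float
    floored_a: bool = False
    floored_b: bool = False


@dataclass(frozen=True)
class FoldChange:
    """Absolute log2 TPM ratio and which library is higher."""

    abs_log2: float
    direction: str  # "up_in_a" | "up_in_b" | "tie"


def tpm(count: int, total: int) -> float:
    """Tags-per-million: ``count / total * 1e6``, unrounded.

    ``total`` is the whole-library clean-read count, not the table sum.
    """
    if total < 1:
        raise ValueError(f"library total must be >= 1, got {total}")
    if count < 0:
        raise ValueError(f"count must be >= 0, got {count}")
    return count / total * 1e6


def expression_pair(counts: CountPair, libs: LibraryPair) -> ExpressionPair:
    """Pre-floor TPM of one tag in both libraries."""
    return ExpressionPair(tpm(counts.x, libs.n1), tpm(counts.y, libs.n2))


def apply_floor(
    expression: ExpressionPair,
    counts: CountPair,
    floor: float = DEFAULT_FLOOR,
) -> ExpressionPair:
    """Replace the TPM of any zero-count side with ``floor``.

    Sides with a nonzero count are untouched, even if their TPM is below
    the floor.
    """
    if floor <= 0:
        raise ValueError(f"floor must be positive, got {floor}")
    result = expression
    if counts.x == 0:
        result = replace(result, tpm_a=floor, floored_a=True)
    if counts.y == 0:
        result = replace(result, tpm_b=floor, floored_b=True)
    return result


def fold_change(expression: ExpressionPair) -> FoldChange:
    """``|log2(tpm_b / tpm_a)|`` with the direction of the higher library."""
    if expression.tpm_a <= 0 or expression.tpm_b <= 0:
        raise ValueError(
            "fold change needs strictly positive TPMs; apply the zero floor first"
        )
    if expression.tpm_a == expression.tpm_b:
        return FoldChange(0.0, "tie")
    ratio = math.log2(expression.tpm_b / expression.tpm_a)
    return FoldChange(abs(ratio), "up_in_b" if ratio > 0 else "up_in_a")
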