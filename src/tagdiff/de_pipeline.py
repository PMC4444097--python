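"""The end-to-end differential-expression pipeline for one library pair.

Order of operations: TPM normalization, zero-count floor, fold change,
Audic–Claverie exact test per tag, BY FDR across tags, then calls.  A
tag is called differentially expressed when ``p < alpha`` (strict) and
``|log2 fold change| >= min_abs_log2fc`` (non-strict); the BY q-value is
reported as an additional column and rejection flag rather than folded
into the DE rule, since the p/fold rule and the FDR cap are stated as
separate filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import exact_test, expression, multiple_testing
from .exact_test import ACResult, TailInterval
from .expression import ExpressionPair, FoldChange
from .tag_io import CountPair, LibraryPair

__all__ = ["Thresholds", "TestResult", "DESummary", "run_de", "classify_unique", "summarize"]


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds for the DE pipeline."""

    alpha: float = 0.05               # p-value cutoff (strict)
    min_abs_log2fc: float = 1.0       # |log2 fold change| cutoff (>=, i.e. 2-fold)
    fdr_cap: float = 0.001            # BY q-value cap for the FDR flag
    floor: float = 0.01               # TPM substituted for zero counts

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        for name in ("min_abs_log2fc", "fdr_cap", "floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class TestResult:
    tag_id: str
    counts: CountPair
    expression: ExpressionPair
    fold: FoldChange
    p_value: float
    q_value: float
    de_call: bool
    unique_call: str                      # only_in_a | only_in_b | both | neither
    fdr_pass: bool = False                # q <= fdr_cap
    ci95: TailInterval | None = None
    ci99: TailInterval | None = None
    ac: ACResult | None = field(default=None, repr=False)


@dataclass(frozen=True)
class DESummary:
    n_total: int
    n_de: int
    de_up_in_a: int
    de_up_in_b: int
    unique_a: int
    unique_b: int


def classify_unique(counts: CountPair) -> str:
    """Library-uniqueness of a tag from its zero pattern."""
    if counts.x > 0 and counts.y == 0:
        return "only_in_a"
    if counts.x == 0 and counts.y > 0:
        return "only_in_b"
    if counts.x > 0 and counts.y > 0:
        return "both"
    return "neither"


def run_de(
    table: list[CountPair],
    libs: LibraryPair,
    thresholds: Thresholds = Thresholds(),
    compute_ci: bool = True,
) -> list[TestResult]:
    """Run the full pipeline; one :class:`TestResult` per input tag.

    Deterministic and purely a function of its inputs.  ``compute_ci``
    skips the per-tag 95%/99% count intervals, which large calibration
    runs do not need.
    """
    partial = []
    for counts in table:
        expr = expression.expression_pair(counts, libs)
        expr = expression.apply_floor(expr, counts, thresholds.floor)
        fold = expression.fold_change(expr)
        ac = exact_test.two_sided_p(counts, libs)
        partial.append((counts, expr, fold, ac))

    if partial:
        fdr = multiple_testing.benjamini_yekutieli(
            [ac.p_value for *_rest, ac in partial], threshold=thresholds.fdr_cap
        )
        q_values = fdr.q_values
        fdr_passes = fdr.rejected
    else:
        q_values, fdr_passes = [], []

    results: list[TestResult] = []
    for (counts, expr, fold, ac), q, fdr_pass in zip(partial, q_values, fdr_passes):
        de = ac.p_value < thresholds.alpha and fold.abs_log2 >= thresholds.min_abs_log2fc
        ci95 = ci99 = None
        if compute_ci:
            ci95 = exact_test.confidence_interval(counts.x, libs, 0.05)
            ci99 = exact_test.confidence_interval(counts.x, libs, 0.01)
        results.append(
            TestResult(
                tag_id=counts.tag_id,
                counts=counts,
                expression=expr,
                fold=fold,
                p_value=ac.p_value,
                q_value=float(q),
                de_call=de,
                unique_call=classify_unique(counts),
                fdr_pass=bool(fdr_pass),
                ci95=ci95,
                ci99=ci99,
                ac=ac,
            )
        )
    return results


def summarize(results: list[TestResult]) -> DESummary:
    """Tallies of DE calls by direction and library-unique tags."""
    n_de = sum(r.de_call for r in results)
    return DESummary(
        n_total=len(results),
        n_de=n_de,
        de_up_in_a=sum(r.de_call and r.fold.direction == "up_in_a" for r in results),
        de_up_in_b=sum(r.de_call and r.fold.direction == "up_in_b" for r in results),
        unique_a=sum(r.unique_call == "only_in_a" for r in results),
        unique_b=sum(r.unique_call == "only_in_b" for r in results),
    )
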