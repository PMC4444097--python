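"""Consensus miRNA-target intersection and annotation-class summaries.

A gene counts as a *consensus* target of a miRNA when every prediction
source lists it (a miRNA missing from a source contributes an empty set,
so its consensus is empty); a *coordinated* gene is a consensus target
that is also differentially expressed at the mRNA level.  A
``min_sources`` relaxation admits genes predicted by at least k of the
sources instead of all of them.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .tag_io import AnnotatedTagRecord, PredictionSets, normalize_id

__all__ = [
    "CoordinatedTargets",
    "ClassSummaryRow",
    "consensus_targets",
    "coordinated_table",
    "summarize_classes",
    "antisense_abundance",
]


@dataclass(frozen=True)
class CoordinatedTargets:
    mirna_id: str
    consensus_genes: tuple[str, ...]
    coordinated_genes: tuple[str, ...]

    @property
    def n_coordinated(self) -> int:
        return len(self.coordinated_genes)


@dataclass(frozen=True)
class ClassSummaryRow:
    locus_class: str
    unique_srna: int      # distinct tags in the class
    total_reads: int      # summed counts


def consensus_targets(
    predictions: PredictionSets,
    mirna_id: str,
    min_sources: int | None = None,
) -> set[str]:
    """Genes predicted by at least ``min_sources`` sources (default: all).

    A miRNA absent from a source is read as "no predicted targets"
    there, so under the default strict rule its consensus is empty.
    """
    k = len(predictions.source_names) if min_sources is None else min_sources
    if k < 1:
        raise ValueError(f"min_sources must be >= 1, got {min_sources}")
    mirna = normalize_id(mirna_id)
    votes: dict[str, int] = defaultdict(int)
    for source in predictions.source_names:
        for gene in predictions.predictions.get(source, {}).get(mirna, set()):
            votes[gene] += 1
    return {gene for gene, n in votes.items() if n >= k}


def coordinated_table(
    predictions: PredictionSets,
    de_genes: set[str],
    mirna_ids=None,
    min_sources: int | None = None,
) -> list[CoordinatedTargets]:
    """One row per miRNA with at least one coordinated gene.

    Rows sort by miRNA id and gene lists lexicographically, so output is
    invariant to input row order and duplicate prediction pairs.
    """
    de_normalized = {normalize_id(g) for g in de_genes}
    if mirna_ids is None:
        mirna_ids = predictions.mirnas()
    rows: list[CoordinatedTargets] = []
    for mirna in sorted({normalize_id(m) for m in mirna_ids}):
        consensus = consensus_targets(predictions, mirna, min_sources=min_sources)
        coordinated = consensus & de_normalized
        if coordinated:
            rows.append(
                CoordinatedTargets(
                    mirna_id=mirna,
                    consensus_genes=tuple(sorted(consensus)),
                    coordinated_genes=tuple(sorted(coordinated)),
                )
            )
    return rows


def summarize_classes(
    records: list[AnnotatedTagRecord],
    vocabulary=None,
) -> tuple[list[ClassSummaryRow], ClassSummaryRow]:
    """Per-locus-class distinct-tag and read tallies plus grand totals."""
    allowed = set(vocabulary) if vocabulary is not None else None
    tags: dict[str, set[str]] = defaultdict(set)
    reads: dict[str, int] = defaultdict(int)
    for record in records:
        if allowed is not None and record.locus_class not in allowed:
            raise ValueError(f"unknown locus class {record.locus_class!r}")
        tags[record.locus_class].add(record.tag_id)
        reads[record.locus_class] += record.count
    rows = [
        ClassSummaryRow(cls, len(tags[cls]), reads[cls]) for cls in sorted(tags)
    ]
    totals = ClassSummaryRow(
        "total",
        sum(row.unique_srna for row in rows),
        sum(row.total_reads for row in rows),
    )
    return rows, totals


def antisense_abundance(
    records: list[AnnotatedTagRecord],
) -> tuple[dict[str, tuple[int, int]], float]:
    """Per-gene (sense, antisense) read counts and the fraction of genes
    whose antisense reads are fewer than their sense reads.

    Only genes observed in *both* orientations enter the fraction's
    denominator — the comparison needs a corresponding sense count.
    Returns fraction 0.0 when no gene qualifies.
    """
    sense: dict[str, int] = defaultdict(int)
    antisense: dict[str, int] = defaultdict(int)
    for record in records:
        if record.gene_id is None or record.orientation is None:
            continue
        gene = normalize_id(record.gene_id)
        if record.orientation == "sense":
            sense[gene] += record.count
        else:
            antisense[gene] += record.count
    per_gene = {
        gene: (sense.get(gene, 0), antisense.get(gene, 0))
        for gene in set(sense) | set(antisense)
    }
    comparable = [g for g in per_gene if sense.get(g, 0) > 0 and antisense.get(g, 0) > 0]
    if not comparable:
        return per_gene, 0.0
    fraction = sum(antisense[g] < sense[g] for g in comparable) / len(comparable)
    return per_gene, fraction
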