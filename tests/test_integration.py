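"""Consensus target set algebra and annotation-class summaries."""

import numpy as np
import pytest

from tagdiff.integration import (
    antisense_abundance,
    consensus_targets,
    coordinated_table,
    summarize_classes,
)
from tagdiff.tag_io import AnnotatedTagRecord, PredictionSets


def make_predictions(per_source: dict[str, dict[str, set[str]]]) -> PredictionSets:
    return PredictionSets(source_names=list(per_source), predictions=per_source)


class TestConsensus:
    def test_intersection_across_all_sources(self):
        predictions = make_predictions(
            {
                "A": {"MIR-X": {"G1", "G2"}},
                "B": {"MIR-X": {"G2", "G3"}},
                "C": {"MIR-X": {"G2"}},
                "D": {"MIR-X": {"G2", "G4"}},
            }
        )
        assert consensus_targets(predictions, "mir-x") == {"G2"}

    def test_missing_source_absorbs_to_empty(self):
        predictions = make_predictions(
            {"A": {"MIR-X": {"G1"}}, "B": {}}
        )
        assert consensus_targets(predictions, "mir-x") == set()

    def test_min_sources_relaxation(self):
        predictions = make_predictions(
            {
                "A": {"MIR-X": {"G1", "G2"}},
                "B": {"MIR-X": {"G2"}},
                "C": {"MIR-X": {"G1"}},
            }
        )
        assert consensus_targets(predictions, "mir-x", min_sources=2) == {"G1", "G2"}

    def test_adding_a_source_never_grows_consensus(self):
        rng = np.random.default_rng(7)
        universe = [f"G{i}" for i in range(200)]
        sources: dict[str, dict[str, set[str]]] = {}
        previous: set[str] | None = None
        for k in range(4):
            genes = set(rng.choice(universe, size=50, replace=False))
            sources[f"S{k}"] = {"MIR-1": genes}
            current = consensus_targets(make_predictions(dict(sources)), "mir-1")
            if previous is not None:
                assert current <= previous
            previous = current

    def test_matches_brute_force_membership_filter(self):
        rng = np.random.default_rng(11)
        universe = [f"G{i}" for i in range(200)]
        per_source = {
            f"S{k}": {"MIR-1": set(rng.choice(universe, size=50, replace=False))}
            for k in range(4)
        }
        predictions = make_predictions(per_source)
        expected = {
            gene
            for gene in universe
            if all(gene in per_source[s]["MIR-1"] for s in per_source)
        }
        assert consensus_targets(predictions, "mir-1") == expected


class TestCoordinatedTable:
    def test_single_coordinated_gene(self):
        predictions = make_predictions(
            {
                "A": {"MIR-X": {"CARS", "CFL2"}},
                "B": {"MIR-X": {"CARS", "CFL2"}},
            }
        )
        rows = coordinated_table(predictions, de_genes={"cars"})
        assert len(rows) == 1
        assert rows[0].mirna_id == "MIR-X"
        assert rows[0].coordinated_genes == ("CARS",)
        assert rows[0].n_coordinated == 1

    def test_empty_de_genes_empty_output(self):
        predictions = make_predictions({"A": {"MIR-X": {"G1"}}})
        assert coordinated_table(predictions, de_genes=set()) == []

    def test_total_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(13)
        universe = [f"G{i}" for i in range(150)]
        mirnas = [f"MIR-{i}" for i in range(12)]
        per_source = {
            s: {
                m: set(rng.choice(universe, size=40, replace=False))
                for m in mirnas
            }
            for s in ("S1", "S2", "S3", "S4")
        }
        predictions = make_predictions(per_source)
        de_genes = set(rng.choice(universe, size=60, replace=False))
        rows = coordinated_table(predictions, de_genes, mirna_ids=mirnas)

        expected = 0
        for m in mirnas:
            for gene in universe:
                if gene in de_genes and all(
                    gene in per_source[s][m] for s in per_source
                ):
                    expected += 1
        assert sum(r.n_coordinated for r in rows) == expected

    def test_invariant_to_row_order_and_duplicates(self):
        base = {
            "A": {"MIR-2": {"G1"}, "MIR-1": {"G1", "G2"}},
            "B": {"MIR-1": {"G2", "G1"}, "MIR-2": {"G1"}},
        }
        shuffled = {
            "A": {"MIR-1": {"G2", "G1"}, "MIR-2": {"G1"}},
            "B": {"MIR-2": {"G1"}, "MIR-1": {"G1", "G2"}},
        }
        de = {"G1", "G2"}
        assert coordinated_table(make_predictions(base), de) == coordinated_table(
            make_predictions(shuffled), de
        )


class TestClassSummary:
    def test_direct_tally(self):
        records = [
            AnnotatedTagRecord("t1", "microRNA", 10),
            AnnotatedTagRecord("t2", "rRNA", 5),
            AnnotatedTagRecord("t3", "microRNA", 1),
        ]
        rows, totals = summarize_classes(records)
        by_class = {row.locus_class: row for row in rows}
        assert (by_class["microRNA"].unique_srna, by_class["microRNA"].total_reads) == (2, 11)
        assert (by_class["rRNA"].unique_srna, by_class["rRNA"].total_reads) == (1, 5)
        assert (totals.unique_srna, totals.total_reads) == (3, 16)

    def test_empty_input(self):
        rows, totals = summarize_classes([])
        assert rows == [] and totals.total_reads == 0

    def test_conservation_on_random_records(self):
        rng = np.random.default_rng(5)
        classes = ["microRNA", "rRNA", "tRNA", "exonsense", "unannotated"]
        records = [
            AnnotatedTagRecord(f"t{i}", classes[rng.integers(len(classes))],
                               int(rng.integers(0, 100)))
            for i in range(1000)
        ]
        rows, totals = summarize_classes(records)
        assert totals.total_reads == sum(r.count for r in records)
        assert totals.unique_srna == len({r.tag_id for r in records})

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="mystery"):
            summarize_classes(
                [AnnotatedTagRecord("t1", "mystery", 1)], vocabulary=["microRNA"]
            )


class TestAntisense:
    def test_simple_gene_comparison(self):
        records = [
            AnnotatedTagRecord("t1", "exonsense", 100, "sense", "G"),
            AnnotatedTagRecord("t2", "exonantisense", 3, "antisense", "G"),
        ]
        per_gene, fraction = antisense_abundance(records)
        assert per_gene["G"] == (100, 3)
        assert fraction == 1.0

    def test_single_orientation_genes_excluded(self):
        records = [
            AnnotatedTagRecord("t1", "exonsense", 100, "sense", "G1"),
            AnnotatedTagRecord("t2", "exonsense", 5, "sense", "G2"),
            AnnotatedTagRecord("t3", "exonantisense", 1, "antisense", "G2"),
        ]
        per_gene, fraction = antisense_abundance(records)
        assert fraction == 1.0  # only G2 qualifies
        assert per_gene["G1"] == (100, 0)

    def test_no_antisense_records_fraction_zero(self):
        records = [AnnotatedTagRecord("t1", "exonsense", 10, "sense", "G")]
        _, fraction = antisense_abundance(records)
        assert fraction == 0.0

    def test_skewed_generator_yields_high_fraction(self):
        # antisense expression at 5% of sense over 200 genes
        rng = np.random.default_rng(17)
        records = []
        for i in range(200):
            sense_reads = int(rng.poisson(200))
            anti_reads = int(rng.poisson(10))
            records.append(
                AnnotatedTagRecord(f"s{i}", "exonsense", sense_reads, "sense", f"G{i}")
            )
            records.append(
                AnnotatedTagRecord(f"a{i}", "exonantisense", anti_reads, "antisense", f"G{i}")
            )
        _, fraction = antisense_abundance(records)
        assert fraction > 0.9
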