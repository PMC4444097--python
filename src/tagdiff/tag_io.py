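"""Reading and writing tag-count tables, prediction lists and reports.

All on-disk formats are plain UTF-8 TSV.  Lines starting with ``#`` are
comments; ``#key=value`` comment lines in a count table carry library
metadata (``name_a``, ``name_b``, ``total_a``, ``total_b``).  Library
totals are whole-library clean-read counts supplied by the caller — they
are deliberately *not* inferred from column sums, because the table
usually holds only a subset of the library (the TPM denominator must be
the full library size).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "CountPair",
    "LibraryPair",
    "AnnotatedTagRecord",
    "PredictionSets",
    "TagTableError",
    "read_count_table",
    "read_prediction_lists",
    "read_annotated_tags",
    "write_result_table",
    "read_result_table",
    "load_config",
]


class TagTableError(ValueError):
    """Raised when an input table violates the format contract."""


@dataclass(frozen=True)
class CountPair:
    """Clean-tag counts of one tag in the two libraries (x in A, y in B)."""

    tag_id: str
    x: int
    y: int

    def __post_init__(self) -> None:
        if not self.tag_id:
            raise TagTableError("tag_id must be a non-empty string")
        for name, value in (("x", self.x), ("y", self.y)):
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise TagTableError(
                    f"count {name} for tag {self.tag_id!r} must be an integer, "
                    f"got {value!r}"
                )
            if value < 0:
                raise TagTableError(
                    f"count {name} for tag {self.tag_id!r} is negative ({value})"
                )


@dataclass(frozen=True)
class LibraryPair:
    """Names and whole-library clean-read totals of the two libraries."""

    name_a: str
    name_b: str
    n1: int
    n2: int

    def __post_init__(self) -> None:
        for name, value in (("n1", self.n1), ("n2", self.n2)):
            if not isinstance(value, int) or isinstance(value, bool) or value < 1:
                raise TagTableError(
                    f"library total {name} must be a positive integer, got {value!r}"
                )


@dataclass(frozen=True)
class AnnotatedTagRecord:
    """A tag with its locus-class annotation (annotation done upstream)."""

    tag_id: str
    locus_class: str
    count: int
    orientation: str | None = None  # "sense" | "antisense"
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.count < 0:
            raise TagTableError(f"count for tag {self.tag_id!r} is negative")
        if self.orientation not in (None, "sense", "antisense"):
            raise TagTableError(
                f"orientation for tag {self.tag_id!r} must be sense/antisense, "
                f"got {self.orientation!r}"
            )


@dataclass
class PredictionSets:
    """Per-source miRNA -> target-gene-set maps.

    Identifiers are normalized (trimmed, upper-cased) so sources using
    different case conventions intersect correctly.
    """

    source_names: list[str]
    predictions: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    def mirnas(self) -> list[str]:
        seen: dict[str, None] = {}
        for source in self.source_names:
            for mirna in self.predictions.get(source, {}):
                seen.setdefault(mirna, None)
        return list(seen)


def normalize_id(identifier: str) -> str:
    """Trim and upper-case an identifier for case-insensitive comparison."""
    return identifier.strip().upper()


def _read_meta_and_body(path: str | Path) -> tuple[dict[str, str], pd.DataFrame]:
    """Split ``#key=value`` comment headers from the TSV body."""
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if "=" in stripped and " " not in stripped.split("=", 1)[0]:
                    key, value = stripped.split("=", 1)
                    meta[key.strip()] = value.strip()
                continue
            if line.strip():
                body_lines.append(line)
    if not body_lines:
        raise TagTableError(f"{path}: no header row found")
    frame = pd.read_csv(io.StringIO("".join(body_lines)), sep="\t", dtype=str)
    return meta, frame


def read_count_table(
    path: str | Path,
    config: Mapping[str, object] | None = None,
) -> tuple[list[CountPair], LibraryPair]:
    """Read a tag-count TSV (tag_id, count_a, count_b) plus library metadata.

    Library totals come from ``#total_a=``/``#total_b=`` header comments or
    from ``config`` (keys ``total_a``, ``total_b``, optional ``name_a``,
    ``name_b``); an explicit config value overrides the header.
    """
    meta, frame = _read_meta_and_body(path)
    if config:
        meta.update({k: str(v) for k, v in config.items()})

    required = ("tag_id", "count_a", "count_b")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise TagTableError(f"{path}: missing column(s) {', '.join(missing)}")

    totals: dict[str, int] = {}
    for key in ("total_a", "total_b"):
        if key not in meta:
            raise TagTableError(
                f"{path}: library total {key!r} not supplied "
                "(use a '#total_a=...' header comment or the config)"
            )
        try:
            totals[key] = int(str(meta[key]).replace(",", ""))
        except ValueError as exc:
            raise TagTableError(f"{path}: unparseable {key}={meta[key]!r}") from exc

    libs = LibraryPair(
        name_a=meta.get("name_a", "A"),
        name_b=meta.get("name_b", "B"),
        n1=totals["total_a"],
        n2=totals["total_b"],
    )

    pairs: list[CountPair] = []
    seen: set[str] = set()
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        tag_id = str(getattr(row, "tag_id")).strip()
        if tag_id in seen:
            raise TagTableError(f"{path}, row {row_number}: duplicate tag_id {tag_id!r}")
        seen.add(tag_id)
        counts = {}
        for column in ("count_a", "count_b"):
            raw = getattr(row, column)
            try:
                counts[column] = int(raw)
            except (TypeError, ValueError) as exc:
                raise TagTableError(
                    f"{path}, row {row_number}: {column}={raw!r} is not an integer"
                ) from exc
        try:
            pairs.append(CountPair(tag_id, counts["count_a"], counts["count_b"]))
        except TagTableError as exc:
            raise TagTableError(f"{path}, row {row_number}: {exc}") from exc
    return pairs, libs


def read_prediction_lists(
    paths: Sequence[str | Path],
    source_names: Sequence[str] | None = None,
) -> PredictionSets:
    """Read one (mirna_id, gene_id) TSV per prediction source.

    Sources keep the order given; duplicate pairs collapse by set
    semantics.  An empty source file yields an empty map for that source.
    """
    if source_names is None:
        source_names = [Path(p).stem for p in paths]
    if len(source_names) != len(paths):
        raise TagTableError("source_names and paths must have equal length")
    result = PredictionSets(source_names=list(source_names))
    for source, path in zip(source_names, paths):
        per_mirna: dict[str, set[str]] = {}
        frame = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["mirna_id", "gene_id"], dtype=str, skip_blank_lines=True,
        )
        frame = frame.dropna()
        for mirna, gene in zip(frame["mirna_id"], frame["gene_id"]):
            per_mirna.setdefault(normalize_id(mirna), set()).add(normalize_id(gene))
        result.predictions[source] = per_mirna
    return result


def read_annotated_tags(
    path: str | Path,
    vocabulary: Iterable[str] | None = None,
) -> list[AnnotatedTagRecord]:
    """Read a pre-annotated tag TSV (tag_id, locus_class, count[, orientation, gene_id])."""
    _, frame = _read_meta_and_body(path)
    required = ("tag_id", "locus_class", "count")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise TagTableError(f"{path}: missing column(s) {', '.join(missing)}")
    allowed = set(vocabulary) if vocabulary is not None else None
    records: list[AnnotatedTagRecord] = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        locus_class = str(getattr(row, "locus_class"))
        if allowed is not None and locus_class not in allowed:
            raise TagTableError(
                f"{path}, row {row_number}: unknown locus class {locus_class!r}"
            )
        orientation = getattr(row, "orientation", None)
        if orientation is not None and pd.isna(orientation):
            orientation = None
        gene_id = getattr(row, "gene_id", None)
        if gene_id is not None and pd.isna(gene_id):
            gene_id = None
        records.append(
            AnnotatedTagRecord(
                tag_id=str(getattr(row, "tag_id")),
                locus_class=locus_class,
                count=int(getattr(row, "count")),
                orientation=orientation,
                gene_id=gene_id,
            )
        )
    return records


_RESULT_COLUMNS = [
    "tag_id", "count_a", "count_b", "tpm_a", "tpm_b", "log2fc", "direction",
    "p_value", "q_value", "ci95_low", "ci95_high", "ci99_low", "ci99_high",
    "de_call", "unique_call",
]


def write_result_table(results, path: str | Path, sort_by_p: bool = False) -> None:
    """Write test results as TSV; values are stored unrounded.

    ``results`` is a sequence of :class:`tagdiff.de_pipeline.TestResult`.
    """
    rows = []
    for r in results:
        ci95 = r.ci95
        ci99 = r.ci99
        rows.append({
            "tag_id": r.tag_id,
            "count_a": r.counts.x,
            "count_b": r.counts.y,
            "tpm_a": r.expression.tpm_a,
            "tpm_b": r.expression.tpm_b,
            "log2fc": r.fold.abs_log2,
            "direction": r.fold.direction,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "ci95_low": "" if ci95 is None or ci95.y_min is None else ci95.y_min,
            "ci95_high": "" if ci95 is None or ci95.y_max is None else ci95.y_max,
            "ci99_low": "" if ci99 is None or ci99.y_min is None else ci99.y_min,
            "ci99_high": "" if ci99 is None or ci99.y_max is None else ci99.y_max,
            "de_call": r.de_call,
            "unique_call": r.unique_call,
        })
    frame = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    if sort_by_p and len(frame):
        frame = frame.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    frame.to_csv(path, sep="\t", index=False)


def read_result_table(path: str | Path) -> pd.DataFrame:
    """Read a result TSV back; floats round-trip at full precision."""
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def load_config(path: str | Path) -> dict:
    """Load a YAML config (totals, thresholds, simulation settings)."""
    with open(path, encoding="utf-8") as handle:
        loaded = yaml.safe_load(handle)
    return loaded or {}
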