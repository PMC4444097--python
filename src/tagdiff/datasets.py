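"""Packaged reference data: the published liver miRNA count table."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .tag_io import CountPair, LibraryPair, read_count_table

__all__ = ["load_rss_liver_mirna", "rss_liver_mirna_reference"]

_DATA = "rss_liver_mirna_counts.tsv"


def _data_path():
    return resources.files("tagdiff.data").joinpath(_DATA)


def load_rss_liver_mirna() -> tuple[list[CountPair], LibraryPair]:
    """The 22 differentially expressed liver miRNAs: per-library clean-tag
    counts (library A = RSS, library B = normal) and the two libraries'
    clean-read totals."""
    with resources.as_file(_data_path()) as path:
        return read_count_table(path)


def rss_liver_mirna_reference() -> pd.DataFrame:
    """The same table with its published fold-change, direction and
    p-value columns, for regression checks."""
    with resources.as_file(_data_path()) as path:
        return pd.read_csv(path, sep="\t", comment="#", dtype={"tag_id": str})
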