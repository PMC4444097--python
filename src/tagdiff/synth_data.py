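"""Synthetic two-library tag-count data with known truth.

The generator reproduces the statistical structure the exact test
assumes: each tag has a relative abundance (drawn log-normal, then
normalized), each library's count is an independent Poisson draw around
``library_total * abundance``, and a chosen fraction of tags carries a
true log2 effect in library B.  Because effects are applied
multiplicatively and library B is renormalized, non-effect tags share a
small common composition shift (-log2 of the renormalization constant);
the recorded truth stores the composition-corrected effect — exactly 0
for null tags — alongside the exact post-normalization abundances.

Randomness uses counter-based Philox streams keyed by (seed, draw
kind), so each vector of draws is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .de_pipeline import TestResult, Thresholds
from .tag_io import CountPair, LibraryPair

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "CalibrationSummary",
    "generate_pair",
    "calibrate",
]

# Draw kinds -> Philox sub-stream index
_STREAMS = {"abundance": 0, "de_mask": 1, "sign": 2, "counts_a": 3, "counts_b": 4}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one simulated library pair.

    Defaults mirror a deep small-RNA experiment: library totals equal to
    the two liver libraries' clean-read counts, roughly a tenth of tags
    differentially expressed, and log-normal abundances whose spread
    (sd of log) of 1.5 gives the usual few dominant tags over a long
    low-count tail.  ``min_expected_count`` optionally floors the
    expected count in the smaller library (abundances are lifted to the
    floor and renormalized), for calibration runs that need every tag
    comfortably in the Poisson regime.
    """

    n_tags: int = 2000
    n1: int = 9_246_256
    n2: int = 8_714_768
    de_fraction: float = 0.1
    effect_log2: float = 2.0
    abundance_meanlog: float = 0.0
    abundance_sdlog: float = 1.5
    min_expected_count: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tags < 1:
            raise ValueError("n_tags must be >= 1")
        if not 0 <= self.de_fraction < 1:
            raise ValueError("de_fraction must lie in [0, 1)")
        if self.effect_log2 <= 0:
            raise ValueError("effect_log2 must be positive")
        if self.abundance_sdlog <= 0:
            raise ValueError("abundance_sdlog must be positive")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("library totals must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth for one generated pair, aligned with the count table."""

    tag_ids: list[str]
    abundance_a: np.ndarray          # normalized relative abundance, library A
    abundance_b: np.ndarray          # normalized relative abundance, library B
    log2fc: np.ndarray               # composition-corrected effect; 0 for nulls
    is_de: np.ndarray                # boolean mask of true effects

    @property
    def abs_log2fc(self) -> np.ndarray:
        return np.abs(self.log2fc)

    def expected_counts(self, libs: LibraryPair) -> tuple[np.ndarray, np.ndarray]:
        return libs.n1 * self.abundance_a, libs.n2 * self.abundance_b


@dataclass(frozen=True)
class CalibrationSummary:
    """Confusion tally of calls against truth (R = V + S)."""

    R: int            # rejections
    V: int            # false positives
    S: int            # true positives
    n_true_de: int
    n_null: int
    empirical_q: float    # V / R, 0 when R = 0
    power: float          # S / n_true_de, 0 when no true effects
    type1: float          # V / n_null, 0 when no nulls


def _stream(seed: int, kind: str) -> np.random.Generator:
    key = np.array([np.uint64(seed), np.uint64(_STREAMS[kind])], dtype=np.uint64)
    return np.random.Generator(np.random.Philox(key=key))


def generate_pair(
    config: SyntheticConfig,
) -> tuple[list[CountPair], LibraryPair, SyntheticTruth]:
    """Draw one synthetic library pair and its ground truth."""
    n = config.n_tags

    raw = _stream(config.seed, "abundance").lognormal(
        mean=config.abundance_meanlog, sigma=config.abundance_sdlog, size=n
    )
    abundance_a = raw / raw.sum()
    if config.min_expected_count is not None:
        floor = config.min_expected_count / min(config.n1, config.n2)
        # two lift-and-renormalize passes keep every tag at or near the floor
        for _ in range(2):
            abundance_a = np.maximum(abundance_a, floor)
            abundance_a = abundance_a / abundance_a.sum()

    n_de = int(round(config.de_fraction * n))
    is_de = np.zeros(n, dtype=bool)
    if n_de:
        idx = _stream(config.seed, "de_mask").permutation(n)[:n_de]
        is_de[idx] = True
    signs = np.where(
        _stream(config.seed, "sign").random(n) < 0.5, -1.0, 1.0
    )

    effect = np.where(is_de, signs * config.effect_log2, 0.0)
    raw_b = abundance_a * np.exp2(effect)
    z = raw_b.sum()
    abundance_b = raw_b / z
    # composition-corrected truth: exp2(log2fc) = (b/a) * z, exactly the
    # injected effect for DE tags and exactly 0 for nulls
    log2fc = effect.copy()

    lam_a = config.n1 * abundance_a
    lam_b = config.n2 * abundance_b
    counts_a = _stream(config.seed, "counts_a").poisson(lam_a)
    counts_b = _stream(config.seed, "counts_b").poisson(lam_b)

    tag_ids = [f"tag{i:06d}" for i in range(n)]
    table = [
        CountPair(tag, int(a), int(b))
        for tag, a, b in zip(tag_ids, counts_a, counts_b)
    ]
    libs = LibraryPair("sim_a", "sim_b", config.n1, config.n2)
    truth = SyntheticTruth(
        tag_ids=tag_ids,
        abundance_a=abundance_a,
        abundance_b=abundance_b,
        log2fc=log2fc,
        is_de=is_de,
    )
    return table, libs, truth


def calibrate(
    results: list[TestResult],
    truth: SyntheticTruth,
    thresholds: Thresholds = Thresholds(),
    criterion: str = "de",
) -> CalibrationSummary:
    """Confusion tally of pipeline calls against generator truth.

    ``criterion`` selects the rejection rule: ``"de"`` (p < alpha and
    fold cutoff, the pipeline's DE call), ``"p"`` (p < alpha alone), or
    ``"by"`` (BY q-value <= fdr_cap).
    """
    if [r.tag_id for r in results] != list(truth.tag_ids):
        raise ValueError("results and truth are not aligned by tag_id")
    if criterion == "de":
        rejected = np.array([r.de_call for r in results], dtype=bool)
    elif criterion == "p":
        rejected = np.array([r.p_value < thresholds.alpha for r in results], dtype=bool)
    elif criterion == "by":
        rejected = np.array([r.fdr_pass for r in results], dtype=bool)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    is_de = truth.is_de
    R = int(rejected.sum())
    S = int((rejected & is_de).sum())
    V = R - S
    n_true = int(is_de.sum())
    n_null = len(results) - n_true
    return CalibrationSummary(
        R=R,
        V=V,
        S=S,
        n_true_de=n_true,
        n_null=n_null,
        empirical_q=V / R if R else 0.0,
        power=S / n_true if n_true else 0.0,
        type1=V / n_null if n_null else 0.0,
    )


def write_truth_table(truth: SyntheticTruth, path) -> None:
    """Write truth as TSV (tag_id, abund_a, abund_b, true_l2fc, is_de)."""
    import pandas as pd

    pd.DataFrame(
        {
            "tag_id": truth.tag_ids,
            "abund_a": truth.abundance_a,
            "abund_b": truth.abundance_b,
            "true_l2fc": truth.log2fc,
            "is_de": truth.is_de,
        }
    ).to_csv(path, sep="\t", index=False)
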