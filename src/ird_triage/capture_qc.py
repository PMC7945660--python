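"""Exome-capture evaluation metrics from per-base coverage and callsets.

The evenness score quantifies coverage uniformity over the capture target:
with per-base coverages ``c_b`` and mean coverage ``C``,

    E = 100 * mean_b( min(c_b, C) ) / C .

E is 100% exactly when coverage is constant and decreases as coverage piles
up unevenly.  An equivalent threshold-sum formulation,
``100 * sum_{i=1..floor(C)} F(i) / C`` with ``F(i)`` the fraction of target
bases covered to at least ``i``x, is implemented as an internal cross-check;
the two agree exactly for integer C and within ``100/C`` percentage points
otherwise (discretisation of the truncation threshold).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CoverageProfile:
    """Per-base coverage over the capture target territory."""

    depths: np.ndarray  # non-negative integers, one per target base

    def __post_init__(self) -> None:
        arr = np.asarray(self.depths)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("coverage profile must be a non-empty 1-D array")
        if (arr < 0).any():
            raise ValueError("coverage must be non-negative")
        object.__setattr__(self, "depths", arr.astype(np.int64))

    @property
    def target_size(self) -> int:
        return int(self.depths.size)


@dataclass(frozen=True)
class CaptureMetrics:
    evenness: float
    mean_depth: float
    duplication_rate: float
    frac_ge_20x: float
    sensitivity: float
    ppv: float


def mean_depth(profile: CoverageProfile) -> float:
    return float(profile.depths.mean())


def frac_at_least(profile: CoverageProfile, t: int = 20) -> float:
    """Percentage of target bases covered to at least ``t``x."""
    return float(100.0 * (profile.depths >= t).mean())


def evenness_score(profile: CoverageProfile, cross_check: bool = True) -> float:
    """Coverage-evenness percentage (truncated-mean form; see module docstring)."""
    c_mean = profile.depths.mean()
    if c_mean == 0:
        raise ValueError("evenness undefined for all-zero coverage")
    e = 100.0 * np.minimum(profile.depths, c_mean).mean() / c_mean
    if cross_check:
        e2 = evenness_score_threshold_sum(profile)
        if abs(e - e2) > 100.0 / c_mean + 1e-9:
            raise AssertionError(
                f"evenness formulations disagree beyond discretisation bound: "
                f"{e} vs {e2}"
            )
    return float(e)


def evenness_score_threshold_sum(profile: CoverageProfile) -> float:
    """Evenness via the cumulative coverage-threshold sum formulation."""
    c_mean = profile.depths.mean()
    if c_mean == 0:
        raise ValueError("evenness undefined for all-zero coverage")
    # sum_{i=1..floor(C)} F(i) == mean_b min(c_b, floor(C))
    floor_c = int(np.floor(c_mean))
    total = np.minimum(profile.depths, floor_c).mean()
    return float(100.0 * total / c_mean)


def duplication_rate(total_reads: int, duplicate_reads: int) -> float:
    """PCR-duplicate percentage of all reads."""
    if total_reads == 0:
        raise ValueError("duplication rate undefined for zero reads")
    if not 0 <= duplicate_reads <= total_reads:
        raise ValueError("duplicate_reads must lie in [0, total_reads]")
    return 100.0 * duplicate_reads / total_reads


def callset_concordance(
    test: Iterable, reference: Iterable
) -> tuple[float, float]:
    """(sensitivity %, PPV %) of a test callset against a reference callset."""
    test_set, ref_set = set(test), set(reference)
    if not ref_set:
        raise ValueError("sensitivity undefined for empty reference callset")
    if not test_set:
        raise ValueError("PPV undefined for empty test callset")
    tp = len(test_set & ref_set)
    return 100.0 * tp / len(ref_set), 100.0 * tp / len(test_set)


def compute_capture_metrics(
    profile: CoverageProfile,
    total_reads: int,
    duplicate_reads: int,
    test_callset: Iterable,
    reference_callset: Iterable,
    depth_threshold: int = 20,
) -> CaptureMetrics:
    sens, ppv = callset_concordance(test_callset, reference_callset)
    return CaptureMetrics(
        evenness=evenness_score(profile),
        mean_depth=mean_depth(profile),
        duplication_rate=duplication_rate(total_reads, duplicate_reads),
        frac_ge_20x=frac_at_least(profile, depth_threshold),
        sensitivity=sens,
        ppv=ppv,
    )


def read_coverage(path: str | Path) -> CoverageProfile:
    """Read a coverage track TSV.

    Accepts either per-base rows (chrom, pos, depth) or BedGraph-like
    half-open intervals (chrom, start, end, depth), which are expanded
    internally.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 3:
        depths = df.iloc[:, 2].to_numpy()
    elif df.shape[1] == 4:
        lengths = (df.iloc[:, 2] - df.iloc[:, 1]).to_numpy()
        if (lengths <= 0).any():
            raise ValueError("interval end must exceed start (half-open intervals)")
        depths = np.repeat(df.iloc[:, 3].to_numpy(), lengths)
    else:
        raise ValueError(
            "coverage TSV must have 3 (chrom,pos,depth) or 4 "
            "(chrom,start,end,depth) columns"
        )
    return CoverageProfile(np.asarray(depths))
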