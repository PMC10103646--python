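"""Shared containers for window-depth cohorts.

Coordinates are 0-based half-open throughout the package (BED convention);
GFF3 input is converted on read. A *window* is a fixed-size genomic interval
with a GC fraction; matrices are laid out samples x windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

WINDOW_COLUMNS = ("chrom", "start", "end", "gc")


class CnvpopError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(CnvpopError, ValueError):
    """An argument violates a documented precondition."""


@dataclass(frozen=True)
class PopulationMap:
    """sample -> population assignment for a cohort."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        if not self.assignments:
            raise InvalidArgumentError("population map is empty")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.assignments.values():
            seen.setdefault(pop)
        return list(seen)

    def samples(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    def size(self, population: str) -> int:
        return len(self.samples(population))

    def population_of(self, sample: str) -> str:
        return self.assignments[sample]

    def __len__(self) -> int:
        return len(self.assignments)


def _check_windows(windows: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in WINDOW_COLUMNS if c not in windows.columns]
    if missing:
        raise InvalidArgumentError(f"window table lacks columns {missing}")
    if (windows["end"] <= windows["start"]).any():
        raise InvalidArgumentError("window with end <= start")
    gc = windows["gc"].to_numpy()
    if np.any((gc < 0) | (gc > 1)):
        raise InvalidArgumentError("gc fraction outside [0, 1]")
    return windows.reset_index(drop=True)


@dataclass
class WindowDepthMatrix:
    """Raw read counts per sample per genomic window.

    ``mask`` flags windows excluded from all downstream statistics
    (``True`` = masked). ``warnings`` records samples dropped or other
    non-fatal issues from processing steps.
    """

    windows: pd.DataFrame  # columns chrom, start, end, gc
    counts: np.ndarray  # shape (n_samples, n_windows), non-negative
    sample_ids: list[str]
    mask: np.ndarray = None  # type: ignore[assignment]
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.windows = _check_windows(self.windows)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise InvalidArgumentError("counts must be a 2-D matrix")
        n_samples, n_windows = self.counts.shape
        if n_windows != len(self.windows):
            raise InvalidArgumentError(
                f"counts has {n_windows} windows, window table has {len(self.windows)}"
            )
        if n_samples != len(self.sample_ids):
            raise InvalidArgumentError(
                f"counts has {n_samples} samples, sample_ids has {len(self.sample_ids)}"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise InvalidArgumentError("duplicate sample ids")
        if np.any(self.counts < 0):
            raise InvalidArgumentError("negative counts")
        if self.mask is None:
            self.mask = np.zeros(n_windows, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (n_windows,):
                raise InvalidArgumentError("mask length does not match windows")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_windows(self) -> int:
        return self.counts.shape[1]

    @property
    def unmasked(self) -> np.ndarray:
        return ~self.mask


@dataclass
class CopyNumberMatrix:
    """GC-corrected, diploid-scaled copy numbers (2 = normal) per window."""

    windows: pd.DataFrame
    cn: np.ndarray  # shape (n_samples, n_windows)
    sample_ids: list[str]
    mask: np.ndarray = None  # type: ignore[assignment]
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.windows = _check_windows(self.windows)
        self.cn = np.asarray(self.cn, dtype=float)
        if self.cn.shape != (len(self.sample_ids), len(self.windows)):
            raise InvalidArgumentError("cn shape does not match windows/samples")
        if self.mask is None:
            self.mask = np.zeros(len(self.windows), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.cn.shape[0]

    @property
    def n_windows(self) -> int:
        return self.cn.shape[1]

    @property
    def unmasked(self) -> np.ndarray:
        return ~self.mask
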