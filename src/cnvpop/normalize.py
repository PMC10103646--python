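"""Window masking, GC-bias correction, and diploid copy-number scaling.

Raw window read counts are converted to copy numbers in three steps:

1. ``mask_windows`` — drop windows whose cross-sample median count is
   extreme (stand-in for unmappable/repeat-dense windows that read-level
   callers handle upstream);
2. ``gc_correct`` — per individual, rescale counts within each GC bin so
   the bin median matches the individual's global median (binned-median
   correction, invertible for any multiplicative unimodal bias);
3. ``normalize_cn`` — rescale each individual so its median unmasked
   window sits at copy number 2.

All scaling uses medians, so windows carrying real CNVs do not drag the
baseline. The whole chain is invariant to each individual's total depth
of coverage.
"""

from __future__ import annotations

import numpy as np

from .core import CopyNumberMatrix, InvalidArgumentError, WindowDepthMatrix

__all__ = ["mask_windows", "gc_correct", "normalize_cn", "normalize"]

#: GC bins narrower than this many windows are pooled with the nearest bin.
MIN_BIN_WINDOWS = 20


def mask_windows(
    depth: WindowDepthMatrix, low_q: float = 0.0, high_q: float = 1.0
) -> WindowDepthMatrix:
    """Mask windows with extreme cross-sample median counts.

    A window is masked when its median count across samples falls strictly
    below the ``low_q`` quantile or strictly above the ``high_q`` quantile
    of all window medians. Existing masks are preserved (union).
    """
    if not 0.0 <= low_q < high_q <= 1.0:
        raise InvalidArgumentError("require 0 <= low_q < high_q <= 1")
    if depth.n_windows == 0 or depth.n_samples == 0:
        raise InvalidArgumentError("empty depth matrix")
    medians = np.median(depth.counts, axis=0)
    lo = np.quantile(medians, low_q)
    hi = np.quantile(medians, high_q)
    mask = depth.mask | (medians < lo) | (medians > hi)
    return WindowDepthMatrix(
        windows=depth.windows.copy(),
        counts=depth.counts.copy(),
        sample_ids=list(depth.sample_ids),
        mask=mask,
        warnings=list(depth.warnings),
    )


def _gc_bins(gc: np.ndarray, width: float, min_windows: int) -> np.ndarray:
    """Assign GC bins of the given width, pooling sparse bins with their
    nearest occupied neighbour until all bins hold >= min_windows windows."""
    ids = np.minimum((gc / width).astype(int), int(1.0 / width))
    uniq, counts = np.unique(ids, return_counts=True)
    uniq = list(uniq)
    counts = list(counts)
    while len(uniq) > 1 and min(counts) < min_windows:
        i = int(np.argmin(counts))
        # nearest occupied neighbour by bin id
        if i == 0:
            j = 1
        elif i == len(uniq) - 1:
            j = i - 1
        else:
            j = i - 1 if (uniq[i] - uniq[i - 1]) <= (uniq[i + 1] - uniq[i]) else i + 1
        keep, drop = (j, i)
        ids[ids == uniq[drop]] = uniq[keep]
        counts[keep] += counts[drop]
        del uniq[drop], counts[drop]
    return ids


def gc_correct(
    depth: WindowDepthMatrix,
    gc_bin_width: float = 0.01,
    min_bin_windows: int = MIN_BIN_WINDOWS,
) -> WindowDepthMatrix:
    """Per-individual binned-median GC correction.

    Counts in GC bin *b* are multiplied by
    ``median(individual counts) / median(individual counts in b)`` over
    unmasked windows, so that after correction every bin's median equals the
    individual's global median. Individuals whose counts are all zero are
    dropped with a warning record; a zero bin median leaves that bin
    unscaled (also recorded).
    """
    if not 0.0 < gc_bin_width <= 0.5:
        raise InvalidArgumentError("gc_bin_width must be in (0, 0.5]")
    if depth.n_windows == 0:
        raise InvalidArgumentError("empty depth matrix")

    unmasked = depth.unmasked
    if not unmasked.any():
        raise InvalidArgumentError("all windows are masked")
    gc = depth.windows["gc"].to_numpy()
    bins_unmasked = _gc_bins(gc[unmasked], gc_bin_width, min_bin_windows)
    # propagate the pooled bin assignment to all windows (masked windows get
    # the bin of the nearest unmasked GC value; they are never used downstream)
    bin_of = np.empty(depth.n_windows, dtype=int)
    bin_of[unmasked] = bins_unmasked
    if (~unmasked).any():
        um_gc = gc[unmasked]
        order = np.argsort(um_gc)
        pos = np.searchsorted(um_gc[order], gc[~unmasked])
        pos = np.clip(pos, 0, len(um_gc) - 1)
        bin_of[~unmasked] = bins_unmasked[order][pos]

    warnings = list(depth.warnings)
    keep_rows: list[int] = []
    corrected_rows: list[np.ndarray] = []
    kept_ids: list[str] = []
    for i, sid in enumerate(depth.sample_ids):
        row = depth.counts[i]
        um = row[unmasked]
        global_med = np.median(um)
        if global_med == 0:
            warnings.append(f"sample {sid} has all-zero (median-zero) counts; excluded")
            continue
        out = row.copy()
        for b in np.unique(bin_of[unmasked]):
            sel_um = unmasked & (bin_of == b)
            bin_med = np.median(row[sel_um])
            if bin_med == 0:
                warnings.append(f"sample {sid}: GC bin {b} has zero median; left unscaled")
                continue
            out[bin_of == b] = row[bin_of == b] * (global_med / bin_med)
        corrected_rows.append(out)
        keep_rows.append(i)
        kept_ids.append(sid)

    if not corrected_rows:
        raise InvalidArgumentError("no sample with non-zero counts")
    return WindowDepthMatrix(
        windows=depth.windows.copy(),
        counts=np.vstack(corrected_rows),
        sample_ids=kept_ids,
        mask=depth.mask.copy(),
        warnings=warnings,
    )


def normalize_cn(depth: WindowDepthMatrix) -> CopyNumberMatrix:
    """Diploid scaling: cn[i, w] = 2 * counts[i, w] / median_w(counts[i, .])
    over unmasked windows, so each individual's median copy number is 2."""
    if depth.n_windows == 0 or depth.n_samples == 0:
        raise InvalidArgumentError("empty depth matrix")
    unmasked = depth.unmasked
    if not unmasked.any():
        raise InvalidArgumentError("all windows are masked")
    med = np.median(depth.counts[:, unmasked], axis=1)
    zero = np.flatnonzero(med == 0)
    if zero.size:
        names = ", ".join(depth.sample_ids[i] for i in zero)
        raise InvalidArgumentError(f"zero median count for sample(s): {names}")
    cn = 2.0 * depth.counts / med[:, None]
    return CopyNumberMatrix(
        windows=depth.windows.copy(),
        cn=cn,
        sample_ids=list(depth.sample_ids),
        mask=depth.mask.copy(),
        warnings=list(depth.warnings),
    )


def normalize(
    depth: WindowDepthMatrix,
    low_q: float = 0.0,
    high_q: float = 1.0,
    gc_bin_width: float = 0.01,
) -> CopyNumberMatrix:
    """Full chain: mask extreme windows, GC-correct, scale to diploid."""
    return normalize_cn(gc_correct(mask_windows(depth, low_q, high_q), gc_bin_width))
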