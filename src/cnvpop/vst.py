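"""V_ST differentiation scan over CNVR copy numbers.

V_ST = (V_T - V_S) / V_T, an F_ST-like statistic for quantitative copy
number: V_T is the variance of the pooled copy-number values of the two
populations, and V_S the population-size-weighted mean of the
within-population variances. Variances use the population denominator n
(``ddof=0``), which both matches the size-weighting and makes the
identical-distribution identity exact; ``ddof=1`` is exposed as an
option. A monomorphic CNVR (V_T = 0) scores 0 — no variance, no
differentiation — rather than poisoning the outlier quantile.

Outliers are the records at or above the (1 - q) quantile of the V_ST
distribution (default top 1%), selected per population pair; their
coordinates are then mapped to overlapping transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import InvalidArgumentError, PopulationMap
from .discovery import Cnvr

__all__ = [
    "VstRecord",
    "vst",
    "vst_scan",
    "top_outliers",
    "map_outliers_to_genes",
    "copy_number_profile",
]


@dataclass(frozen=True)
class VstRecord:
    cnvr_id: str
    chrom: str
    start: int
    end: int
    pair: tuple[str, str]
    v_t: float
    v_s: float
    vst: float
    rank: int | None = None
    outlier: bool = False
    genes: tuple[str, ...] = ()


def vst(
    values_a: np.ndarray, values_b: np.ndarray, ddof: int = 0
) -> tuple[float, float, float]:
    """(V_T, V_S, V_ST) for two groups of copy-number values."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidArgumentError("each group needs at least 2 values")
    na, nb = a.size, b.size
    n = na + nb
    # pooled moments combined from per-group moments: every combination is a
    # two-term IEEE addition, so vst(a, b) == vst(b, a) bit-for-bit
    mean_a, mean_b = float(a.mean()), float(b.mean())
    var_a = float(np.var(a, ddof=0))
    var_b = float(np.var(b, ddof=0))
    mean = (na * mean_a + nb * mean_b) / n
    v_t = (na * (var_a + (mean_a - mean) ** 2)
           + nb * (var_b + (mean_b - mean) ** 2)) / n
    v_s = (na * var_a + nb * var_b) / n
    if ddof:
        # unbiased option: rescale to the (n-ddof) denominators
        v_t = v_t * n / (n - ddof)
        v_s = (na * var_a * na / (na - ddof)
               + nb * var_b * nb / (nb - ddof)) / n
    v = 0.0 if v_t == 0.0 else (v_t - v_s) / v_t
    return v_t, v_s, v


def vst_scan(
    cnvrs: list[Cnvr],
    pops: PopulationMap,
    focal: str,
    others: list[str] | None = None,
    ddof: int = 0,
) -> list[VstRecord]:
    """One V_ST record per CNVR per (focal, other) population pair."""
    if focal not in pops.populations:
        raise InvalidArgumentError(f"focal population {focal!r} not in population map")
    if others is None:
        others = [p for p in pops.populations if p != focal]
    for pop in [focal, *others]:
        if pop not in pops.populations:
            raise InvalidArgumentError(f"population {pop!r} not in population map")
        if pops.size(pop) < 2:
            raise InvalidArgumentError(f"population {pop!r} has fewer than 2 samples")

    records: list[VstRecord] = []
    for other in others:
        for c in cnvrs:
            idx = {s: i for i, s in enumerate(c.sample_ids)}
            vals_a = np.array([c.mean_cn[idx[s]] for s in pops.samples(focal)])
            vals_b = np.array([c.mean_cn[idx[s]] for s in pops.samples(other)])
            v_t, v_s, v = vst(vals_a, vals_b, ddof=ddof)
            records.append(
                VstRecord(c.id, c.chrom, c.start, c.end, (focal, other), v_t, v_s, v)
            )
    return records


def top_outliers(records: list[VstRecord], q: float = 0.01) -> list[VstRecord]:
    """Flag records at or above the (1 - q) V_ST quantile, per pair.

    The threshold uses linear quantile interpolation; ties at the threshold
    are all included. Ranks run from 1 by descending V_ST, ties broken by
    genomic order. Returns all records (re-created with rank/outlier set);
    filter on ``.outlier`` for the flagged subset.
    """
    if not records:
        raise InvalidArgumentError("no records")
    if not 0.0 < q < 1.0:
        raise InvalidArgumentError("q must be in (0, 1)")

    out: list[VstRecord] = []
    pairs = sorted({r.pair for r in records})
    for pair in pairs:
        group = [r for r in records if r.pair == pair]
        values = np.array([r.vst for r in group])
        threshold = float(np.quantile(values, 1.0 - q))
        order = sorted(
            range(len(group)),
            key=lambda i: (-group[i].vst, group[i].chrom, group[i].start),
        )
        for rank0, i in enumerate(order):
            r = group[i]
            out.append(
                replace(r, rank=rank0 + 1, outlier=bool(r.vst >= threshold))
            )
    out.sort(key=lambda r: (r.pair, r.rank))
    return out


def map_outliers_to_genes(outliers: list[VstRecord], model) -> pd.DataFrame:
    """Map outlier CNVRs to overlapping transcripts (>= 1 bp, flanks excluded).

    Returns a per-pair, per-gene table with the best (maximum) V_ST among
    the outliers hitting each gene.
    """
    best: dict[tuple[tuple[str, str], str], float] = {}
    annotated: list[VstRecord] = []
    for r in outliers:
        hits = [
            tx
            for tx in model.overlapping(r.chrom, r.start, r.end)
            if tx.start < r.end and tx.end > r.start  # body overlap only
        ]
        genes = tuple(sorted({tx.gene for tx in hits}))
        annotated.append(replace(r, genes=genes))
        for g in genes:
            key = (r.pair, g)
            best[key] = max(best.get(key, -np.inf), r.vst)
    table = pd.DataFrame(
        [
            {"focal": pair[0], "other": pair[1], "gene": gene, "best_vst": v}
            for (pair, gene), v in sorted(best.items())
        ],
        columns=["focal", "other", "gene", "best_vst"],
    )
    table.attrs["records"] = annotated
    return table


def copy_number_profile(cnvr: Cnvr, pops: PopulationMap) -> dict[str, dict]:
    """Per-population mean/median/values of a CNVR's copy numbers — the data
    behind per-gene copy-number comparison panels."""
    idx = {s: i for i, s in enumerate(cnvr.sample_ids)}
    profile: dict[str, dict] = {}
    for pop in pops.populations:
        vals = np.array([cnvr.mean_cn[idx[s]] for s in pops.samples(pop) if s in idx])
        profile[pop] = {
            "mean": float(vals.mean()) if vals.size else float("nan"),
            "median": float(np.median(vals)) if vals.size else float("nan"),
            "values": vals,
        }
    return profile
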