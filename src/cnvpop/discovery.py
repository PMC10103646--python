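"""CNV window detection, CNVR merging, genotyping, and filtering.

The caller follows the population-scale read-depth recipe: windows where
enough individuals deviate from diploid copy number become candidates
(``-f``/``-h`` semantics: minimum deviant fraction and count), adjacent
correlated candidates are merged into copy-number-variable regions
(``-r``: minimum Pearson correlation between neighbouring windows), each
region is genotyped by deterministic 1-D k-means on per-individual mean
copy number, and regions are retained only when the clustering is crisp
(mean silhouette > 0.6) and the region length passes the kind-specific
caps (deletion/both <= 50 kb, duplication < 500 kb).

Regions require at least two candidate windows by default: with
half-overlapping windows any real CNV at least one window long spans two
windows, and isolated single-window excursions are overwhelmingly noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
from sklearn.cluster import KMeans

from .core import CopyNumberMatrix, InvalidArgumentError

__all__ = [
    "CandidateWindow",
    "CandidateRegion",
    "Cnvr",
    "detect_candidates",
    "merge_candidates",
    "silhouette",
    "genotype_cnvr",
    "filter_cnvrs",
    "call_cnvrs",
    "classify_genotypes",
]

LOSS_THRESHOLD = 1.5
GAIN_THRESHOLD = 2.5


@dataclass(frozen=True)
class CandidateWindow:
    """A window where >= max(h, ceil(f*n)) individuals deviate from cn 2."""

    index: int  # position in the full window table
    chrom: str
    start: int
    end: int
    n_loss: int
    n_gain: int
    cn_vector: np.ndarray


@dataclass(frozen=True)
class CandidateRegion:
    """A merged run of candidate windows, prior to genotyping."""

    chrom: str
    start: int
    end: int
    window_indices: tuple[int, ...]

    @property
    def n_windows(self) -> int:
        return len(self.window_indices)


@dataclass
class Cnvr:
    """A genotyped copy-number-variable region.

    ``kind`` is "deletion", "duplication", "both", or "normal" when no
    deviant genotype cluster was found (such regions never survive
    filtering). Genotype classes are "loss" / "normal" / "gain".
    """

    chrom: str
    start: int
    end: int
    kind: str
    n_windows: int
    silhouette: float
    sample_ids: list[str]
    mean_cn: np.ndarray  # per-individual mean cn over constituent windows
    genotypes: np.ndarray  # per-individual class labels
    window_indices: tuple[int, ...] = field(default=(), repr=False)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def classify_genotypes(
    values: np.ndarray,
    loss_threshold: float = LOSS_THRESHOLD,
    gain_threshold: float = GAIN_THRESHOLD,
) -> np.ndarray:
    """Threshold copy numbers into loss/normal/gain classes."""
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, "normal", dtype=object)
    out[values <= loss_threshold] = "loss"
    out[values >= gain_threshold] = "gain"
    return out


def detect_candidates(
    cn: CopyNumberMatrix,
    f: float = 0.1,
    h: int = 3,
    loss_threshold: float = LOSS_THRESHOLD,
    gain_threshold: float = GAIN_THRESHOLD,
) -> list[CandidateWindow]:
    """Windows where max(n_loss, n_gain) >= max(h, ceil(f * n_individuals)).

    Masked windows are never candidates.
    """
    if not 0.0 < f <= 1.0:
        raise InvalidArgumentError("f must be in (0, 1]")
    if h < 1:
        raise InvalidArgumentError("h must be >= 1")
    if not loss_threshold < 2.0 < gain_threshold:
        raise InvalidArgumentError("need loss_threshold < 2 < gain_threshold")

    n = cn.n_samples
    need = max(h, ceil(f * n))
    n_loss = (cn.cn <= loss_threshold).sum(axis=0)
    n_gain = (cn.cn >= gain_threshold).sum(axis=0)
    hits = np.flatnonzero((np.maximum(n_loss, n_gain) >= need) & cn.unmasked)

    win = cn.windows
    chrom = win["chrom"].to_numpy()
    start = win["start"].to_numpy()
    end = win["end"].to_numpy()
    return [
        CandidateWindow(
            index=int(i),
            chrom=str(chrom[i]),
            start=int(start[i]),
            end=int(end[i]),
            n_loss=int(n_loss[i]),
            n_gain=int(n_gain[i]),
            cn_vector=cn.cn[:, i].copy(),
        )
        for i in hits
    ]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def merge_candidates(
    candidates: list[CandidateWindow],
    r: float = 0.1,
    max_gap: int = 1,
    min_windows: int = 2,
) -> list[CandidateRegion]:
    """Merge genomically adjacent, correlated candidate windows.

    Scanning each chromosome in order, the next candidate extends the
    current region iff its gap is at most ``max_gap`` window-steps (gap =
    skipped window positions) and the Pearson correlation between the two
    windows' cn vectors is >= ``r``. Runs shorter than ``min_windows``
    candidate windows are discarded.
    """
    if not -1.0 <= r <= 1.0:
        raise InvalidArgumentError("r must be in [-1, 1]")
    if max_gap < 0:
        raise InvalidArgumentError("max_gap must be >= 0")
    if min_windows < 1:
        raise InvalidArgumentError("min_windows must be >= 1")

    ordered = sorted(candidates, key=lambda c: (c.chrom, c.start))
    regions: list[CandidateRegion] = []
    run: list[CandidateWindow] = []

    def flush() -> None:
        if len(run) >= min_windows:
            regions.append(
                CandidateRegion(
                    chrom=run[0].chrom,
                    start=run[0].start,
                    end=run[-1].end,
                    window_indices=tuple(c.index for c in run),
                )
            )

    for cand in ordered:
        if run and cand.chrom == run[-1].chrom:
            gap = cand.index - run[-1].index - 1
            if gap <= max_gap and _pearson(run[-1].cn_vector, cand.cn_vector) >= r:
                run.append(cand)
                continue
        flush()
        run = [cand]
    if run:
        flush()
    return regions


def silhouette(values: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette score of a 1-D clustering.

    For each point, s = (b - a) / max(a, b) with a the mean distance to its
    own cluster (excluding itself) and b the smallest mean distance to any
    other cluster. Points in singleton clusters contribute 0, as do points
    where a = b = 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.ndim != 1 or values.shape != labels.shape:
        raise InvalidArgumentError("values and labels must be equal-length 1-D arrays")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise InvalidArgumentError("silhouette requires at least 2 clusters")

    d = np.abs(values[:, None] - values[None, :])
    masks = {u: labels == u for u in uniq}
    s = np.zeros(len(values))
    for i in range(len(values)):
        own = masks[labels[i]].copy()
        own[i] = False
        if not own.any():  # singleton cluster
            continue
        a = d[i, own].mean()
        b = min(d[i, masks[u]].mean() for u in uniq if u != labels[i])
        m = max(a, b)
        s[i] = 0.0 if m == 0.0 else (b - a) / m
    return float(s.mean())


def _kmeans_1d(values: np.ndarray, k: int) -> np.ndarray | None:
    """Deterministic 1-D k-means: quantile-spaced init, single run."""
    uniq = np.unique(values)
    if uniq.size < k:
        return None
    qs = (2 * np.arange(k) + 1) / (2 * k)
    centers = np.quantile(values, qs)
    if np.unique(centers).size < k:  # heavily tied data: spread over uniques
        idx = np.floor(np.linspace(0, uniq.size - 1, k)).astype(int)
        centers = uniq[idx]
    km = KMeans(
        n_clusters=k, init=centers.reshape(-1, 1), n_init=1, max_iter=300, tol=1e-6
    )
    return km.fit_predict(values.reshape(-1, 1))


def genotype_cnvr(
    region: CandidateRegion,
    cn: CopyNumberMatrix,
    k_candidates: tuple[int, ...] = (2, 3),
    loss_threshold: float = LOSS_THRESHOLD,
    gain_threshold: float = GAIN_THRESHOLD,
) -> Cnvr:
    """Genotype a merged region by 1-D k-means on per-individual mean cn.

    The k in ``k_candidates`` maximizing mean silhouette wins (ties to the
    smaller k); cluster centers below ``loss_threshold`` label their members
    "loss", above ``gain_threshold`` "gain", otherwise "normal". If no k
    admits a valid clustering (fewer distinct values than every k), the
    silhouette is -1 and all samples are threshold-classified directly.
    """
    if region.n_windows < 1:
        raise InvalidArgumentError("region has no windows")
    idx = list(region.window_indices)
    summary = cn.cn[:, idx].mean(axis=1)

    best_sil = -1.0
    best_labels: np.ndarray | None = None
    best_centers: np.ndarray | None = None
    for k in sorted(k_candidates):
        labels = _kmeans_1d(summary, k)
        if labels is None or np.unique(labels).size < 2:
            continue
        sil = silhouette(summary, labels)
        if sil > best_sil:
            best_sil = sil
            best_labels = labels
            best_centers = np.array(
                [summary[labels == u].mean() for u in np.unique(labels)]
            )

    if best_labels is None:
        genotypes = classify_genotypes(summary, loss_threshold, gain_threshold)
        sil = -1.0
    else:
        uniq = np.unique(best_labels)
        center_class = {
            u: (
                "loss"
                if best_centers[j] < loss_threshold
                else "gain" if best_centers[j] > gain_threshold else "normal"
            )
            for j, u in enumerate(uniq)
        }
        genotypes = np.array([center_class[u] for u in best_labels], dtype=object)
        sil = best_sil

    has_loss = bool((genotypes == "loss").any())
    has_gain = bool((genotypes == "gain").any())
    if has_loss and has_gain:
        kind = "both"
    elif has_loss:
        kind = "deletion"
    elif has_gain:
        kind = "duplication"
    else:
        kind = "normal"

    return Cnvr(
        chrom=region.chrom,
        start=region.start,
        end=region.end,
        kind=kind,
        n_windows=region.n_windows,
        silhouette=sil,
        sample_ids=list(cn.sample_ids),
        mean_cn=summary,
        genotypes=genotypes,
        window_indices=region.window_indices,
    )


def filter_cnvrs(
    cnvrs: list[Cnvr],
    silhouette_min: float = 0.6,
    del_both_max_len: int = 50_000,
    dup_max_len: int = 500_000,
) -> list[Cnvr]:
    """Retain crisp, kind-consistent regions.

    Silhouette must strictly exceed ``silhouette_min``; deletion/both
    regions must be <= ``del_both_max_len`` long, duplications strictly
    < ``dup_max_len``. Regions with no deviant genotype class are dropped.
    """
    kept = []
    for c in cnvrs:
        if c.silhouette <= silhouette_min:
            continue
        if c.kind in ("deletion", "both") and c.length > del_both_max_len:
            continue
        if c.kind == "duplication" and c.length >= dup_max_len:
            continue
        if c.kind == "normal":
            continue
        kept.append(c)
    return kept


def call_cnvrs(
    cn: CopyNumberMatrix,
    f: float = 0.1,
    h: int = 3,
    r: float = 0.1,
    max_gap: int = 1,
    min_windows: int = 2,
    loss_threshold: float = LOSS_THRESHOLD,
    gain_threshold: float = GAIN_THRESHOLD,
    silhouette_min: float = 0.6,
    del_both_max_len: int = 50_000,
    dup_max_len: int = 500_000,
) -> tuple[list[Cnvr], dict[str, int]]:
    """Full discovery chain; returns retained CNVRs plus stage counts."""
    candidates = detect_candidates(cn, f=f, h=h, loss_threshold=loss_threshold,
                                   gain_threshold=gain_threshold)
    regions = merge_candidates(candidates, r=r, max_gap=max_gap, min_windows=min_windows)
    genotyped = [
        genotype_cnvr(reg, cn, loss_threshold=loss_threshold,
                      gain_threshold=gain_threshold)
        for reg in regions
    ]
    kept = filter_cnvrs(genotyped, silhouette_min=silhouette_min,
                        del_both_max_len=del_both_max_len, dup_max_len=dup_max_len)
    stats = {
        "candidate_windows": len(candidates),
        "merged_regions": len(regions),
        "cnvrs_prefilter": len(genotyped),
        "cnvrs_retained": len(kept),
    }
    return kept, stats
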