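"""Population stratification: PCA on CNVR copy-number matrices.

Individuals are decomposed on per-CNVR mean copy numbers restricted to the
deletion, duplication, both, or combined CNVR subsets. Columns are
mean-centered and, by default, variance-standardized (zero-variance
columns dropped); eigenvector signs follow a deterministic convention
(non-negative loading sum) so coordinates are reproducible across
platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA as _SkPCA

from .core import InvalidArgumentError, PopulationMap
from .discovery import Cnvr

__all__ = ["CnvrGenotypeMatrix", "PcaResult", "build_matrix", "pca", "SUBSETS"]

SUBSETS = ("deletions", "duplications", "both", "all")

_SUBSET_KINDS = {
    "deletions": {"deletion", "both"},
    "duplications": {"duplication", "both"},
    "both": {"both"},
    "all": {"deletion", "duplication", "both"},
}


@dataclass
class CnvrGenotypeMatrix:
    """individuals x CNVRs matrix of per-CNVR mean copy number."""

    values: np.ndarray
    sample_ids: list[str]
    cnvr_ids: list[str]
    subset: str
    populations: PopulationMap | None = None

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_cnvrs(self) -> int:
        return self.values.shape[1]


@dataclass
class PcaResult:
    coordinates: np.ndarray  # individuals x k
    variance_explained: np.ndarray  # fraction per component, non-increasing
    loadings: np.ndarray  # k x n_features
    sample_ids: list[str]
    n_dropped_columns: int = 0


def build_matrix(
    cnvrs: list[Cnvr],
    subset: str = "all",
    populations: PopulationMap | None = None,
) -> CnvrGenotypeMatrix:
    """Assemble the PCA input for one CNVR subset.

    "deletions" takes kinds {deletion, both}; "duplications" takes
    {duplication, both}; "both" takes both-type only; "all" takes
    everything.
    """
    if subset not in _SUBSET_KINDS:
        raise InvalidArgumentError(f"subset must be one of {SUBSETS}")
    chosen = [c for c in cnvrs if c.kind in _SUBSET_KINDS[subset]]
    if len(chosen) < 2:
        raise InvalidArgumentError(
            f"subset {subset!r} has {len(chosen)} CNVRs; need at least 2"
        )
    sample_ids = list(chosen[0].sample_ids)
    for c in chosen:
        if list(c.sample_ids) != sample_ids:
            raise InvalidArgumentError("CNVRs carry inconsistent sample orderings")
    values = np.column_stack([c.mean_cn for c in chosen])
    return CnvrGenotypeMatrix(
        values=values,
        sample_ids=sample_ids,
        cnvr_ids=[c.id for c in chosen],
        subset=subset,
        populations=populations,
    )


def pca(matrix: CnvrGenotypeMatrix, k: int = 10, scale: bool = True) -> PcaResult:
    """PCA of the (centered, optionally standardized) CNVR matrix.

    ``variance_explained`` is eigenvalue / trace of the processed matrix's
    covariance. A matrix with no variance at all (identical rows) yields
    all-zero coordinates and variance fractions.
    """
    X = np.asarray(matrix.values, dtype=float)
    n, p = X.shape
    if n < 2:
        raise InvalidArgumentError("PCA needs at least 2 individuals")
    k = int(min(k, n - 1, p))
    if k < 1:
        raise InvalidArgumentError("k must be >= 1 after clipping to rank bounds")

    X = X - X.mean(axis=0)
    dropped = 0
    if scale:
        sd = X.std(axis=0, ddof=0)
        keep = sd > 0
        dropped = int((~keep).sum())
        X = X[:, keep] / sd[keep]
        if X.shape[1] == 0:
            return PcaResult(
                coordinates=np.zeros((n, k)),
                variance_explained=np.zeros(k),
                loadings=np.zeros((k, 0)),
                sample_ids=list(matrix.sample_ids),
                n_dropped_columns=dropped,
            )
    if not np.any(X):
        return PcaResult(
            coordinates=np.zeros((n, k)),
            variance_explained=np.zeros(k),
            loadings=np.zeros((k, X.shape[1])),
            sample_ids=list(matrix.sample_ids),
            n_dropped_columns=dropped,
        )

    k = min(k, X.shape[1])
    model = _SkPCA(n_components=k, svd_solver="full")
    coords = model.fit_transform(X)
    loadings = model.components_
    # deterministic orientation: each loading vector sums non-negative
    for j in range(k):
        s = loadings[j].sum()
        flip = s < 0
        if s == 0:
            nz = np.flatnonzero(loadings[j])
            flip = nz.size > 0 and loadings[j][nz[0]] < 0
        if flip:
            loadings[j] = -loadings[j]
            coords[:, j] = -coords[:, j]
    return PcaResult(
        coordinates=coords,
        variance_explained=model.explained_variance_ratio_,
        loadings=loadings,
        sample_ids=list(matrix.sample_ids),
        n_dropped_columns=dropped,
    )
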