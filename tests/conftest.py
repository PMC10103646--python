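"""Shared fixtures: a toy gene model and CNVR construction helpers."""

from __future__ import annotations

import numpy as np
import pytest

from cnvpop import Cnvr, GeneModel, Transcript


def make_cnvr(
    chrom: str = "chr1",
    start: int = 0,
    end: int = 1_000,
    kind: str = "deletion",
    sil: float = 0.9,
    n_samples: int = 4,
    mean_cn: np.ndarray | None = None,
) -> Cnvr:
    """A minimal CNVR record for fixtures that only need coordinates/kind."""
    if mean_cn is None:
        base = 1.0 if kind == "deletion" else 3.0
        mean_cn = np.array([base] * (n_samples // 2) + [2.0] * (n_samples - n_samples // 2))
    gt = np.where(mean_cn <= 1.5, "loss", np.where(mean_cn >= 2.5, "gain", "normal"))
    return Cnvr(
        chrom=chrom,
        start=start,
        end=end,
        kind=kind,
        n_windows=max(1, (end - start) // 400),
        silhouette=sil,
        sample_ids=[f"s{i}" for i in range(len(mean_cn))],
        mean_cn=np.asarray(mean_cn, dtype=float),
        genotypes=gt.astype(object),
    )


@pytest.fixture
def toy_gene_model() -> GeneModel:
    """Hand-built model exercising every annotation category.

    chr1 layout (0-based half-open):

    * GA (+, coding) tx 1000-9000; exons (1000,3000)(5000,7000)(8000,9000);
      CDS 2000-8500. So 1000-2000 is UTR5, 8500-9000 is UTR3; introns
      3000-5000 and 7000-8000. Upstream flank 0-1000, downstream 9000-10000.
    * GE (+, coding) tx 10500-14000; single exon, CDS 10600-13900. Its
      upstream flank 9500-10500 overlaps GA's downstream flank.
    * GB (+, non-coding) tx 20000-30000; exons (20000,22000)(25000,30000).
    * GC (-, coding) tx 40000-50000; exons (40000,44000)(46000,50000);
      CDS 41000-49000 -> 40000-41000 is UTR3, 49000-50000 is UTR5
      (minus strand); upstream flank 50000-51000, downstream 39000-40000.
    * GD (+, coding) tx 2200-6000 overlapping GA; exons (2200,2400)
      (5600,6000), CDS 2250-5900, so its big intron 2400-5600 covers part of
      GA's first coding exon — positions there are GA-exonic and GD-intronic
      at once (precedence fodder).
    """
    transcripts = [
        Transcript("GA", "GA.t1", "chr1", "+", 1000, 9000,
                   exons=((1000, 3000), (5000, 7000), (8000, 9000)),
                   cds=(2000, 8500)),
        Transcript("GE", "GE.t1", "chr1", "+", 10500, 14000,
                   exons=((10500, 14000),), cds=(10600, 13900)),
        Transcript("GB", "GB.t1", "chr1", "+", 20000, 30000,
                   exons=((20000, 22000), (25000, 30000)), cds=None),
        Transcript("GC", "GC.t1", "chr1", "-", 40000, 50000,
                   exons=((40000, 44000), (46000, 50000)), cds=(41000, 49000)),
        Transcript("GD", "GD.t1", "chr1", "+", 2200, 6000,
                   exons=((2200, 2400), (5600, 6000)), cds=(2250, 5900)),
    ]
    return GeneModel(transcripts)
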