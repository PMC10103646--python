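"""Synthetic multi-population read-depth cohorts with implanted CNVs.

The generator emulates a resequenced cohort at window resolution: a tiled
reference with smoothly varying GC, deletion/duplication alleles segregating
at population-specific frequencies under a diploid Binomial(2, freq) carrier
model, and overdispersed (negative-binomial) window read counts whose
expectation scales with local copy number and a unimodal GC-bias factor.
Every downstream stage can therefore be scored against a known truth set.

Default noise model: the expected diploid count per window is
``mean_depth * window_size / read_length`` (12x, 800 bp, 100-bp reads ->
96 reads/window) with negative-binomial size 300, i.e. a per-window copy
number standard deviation of ~0.23 for a diploid window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import InvalidArgumentError, PopulationMap, WindowDepthMatrix

__all__ = [
    "SimulatedReference",
    "CnvEvent",
    "TruthSet",
    "simulate_reference",
    "implant_cnvs",
    "simulate_depth",
    "random_events",
    "simulate_cohort",
    "simulate_cnvr_cohort",
    "synthetic_gene_model",
]

#: GC random walk bounds. Mammalian windows are AT-rich and sit mostly below
#: the sequencing-coverage optimum, which keeps the realized depth-GC
#: relation predominantly monotone.
GC_BOUNDS = (0.30, 0.55)
GC_MEAN = 0.42
GC_STATIONARY_SD = 0.05


@dataclass(frozen=True)
class SimulatedReference:
    """Tiled windows over one or more synthetic chromosomes."""

    chromosomes: list[tuple[str, int]]
    windows: pd.DataFrame  # chrom, start, end, gc
    window_size: int
    step: int

    @property
    def n_windows(self) -> int:
        return len(self.windows)


@dataclass(frozen=True)
class CnvEvent:
    """One implanted CNV allele segregating in the cohort.

    ``copy_change`` is applied once per carried allele: -1/-2 for deletion
    alleles, +1..+3 for duplication alleles.
    """

    chrom: str
    start: int
    end: int
    kind: str  # "deletion" | "duplication"
    copy_change: int
    allele_freq: dict[str, float]  # population -> allele frequency

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InvalidArgumentError(f"event end <= start at {self.chrom}:{self.start}")
        if self.kind not in ("deletion", "duplication"):
            raise InvalidArgumentError(f"unknown event kind {self.kind!r}")
        if self.kind == "deletion" and self.copy_change not in (-1, -2):
            raise InvalidArgumentError("deletion copy_change must be -1 or -2")
        if self.kind == "duplication" and self.copy_change not in (1, 2, 3):
            raise InvalidArgumentError("duplication copy_change must be +1..+3")
        for pop, f in self.allele_freq.items():
            if not 0.0 <= f <= 1.0:
                raise InvalidArgumentError(f"allele frequency {f} for {pop} outside [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start

    @staticmethod
    def carrier_to_allele_freq(carrier_freq: float) -> float:
        """Allele frequency giving P(>=1 allele) = carrier_freq under HWE."""
        if not 0.0 <= carrier_freq <= 1.0:
            raise InvalidArgumentError("carrier frequency outside [0, 1]")
        return 1.0 - math.sqrt(1.0 - carrier_freq)


@dataclass
class TruthSet:
    """Implanted events plus the integer copy-number track they imply."""

    events: list[CnvEvent]
    copy_number: np.ndarray  # (n_samples, n_windows) integer track
    sample_ids: list[str]
    populations: PopulationMap
    reference: SimulatedReference
    genotypes: np.ndarray = field(default=None)  # (n_samples, n_events) allele counts

    @property
    def pop_sizes(self) -> dict[str, int]:
        return {p: self.populations.size(p) for p in self.populations.populations}


def simulate_reference(
    n_chrom: int = 1,
    chrom_length: int = 10_000_000,
    window_size: int = 800,
    step: int = 400,
    gc_autocorrelation: float = 0.98,
    seed: int = 0,
) -> SimulatedReference:
    """Tile ``n_chrom`` chromosomes into fixed-step windows with AR(1) GC.

    GC follows a stationary AR(1) chain (lag-1 correlation
    ``gc_autocorrelation``) around 0.42, reflected into [0.30, 0.55].
    Deterministic for a fixed seed.
    """
    if n_chrom <= 0 or chrom_length <= 0 or window_size <= 0 or step <= 0:
        raise InvalidArgumentError("reference dimensions must be positive")
    if step not in (window_size, window_size // 2) or window_size % max(step, 1):
        raise InvalidArgumentError("step must equal window_size or window_size/2")
    if chrom_length < 10 * window_size:
        raise InvalidArgumentError("chrom_length must be >= 10 * window_size")
    if not 0.0 <= gc_autocorrelation < 1.0:
        raise InvalidArgumentError("gc_autocorrelation must be in [0, 1)")

    rng = np.random.default_rng(seed)
    lo, hi = GC_BOUNDS
    innov_sd = GC_STATIONARY_SD * math.sqrt(1.0 - gc_autocorrelation**2)

    chroms: list[tuple[str, int]] = []
    frames: list[pd.DataFrame] = []
    for c in range(n_chrom):
        name = f"chr{c + 1}"
        chroms.append((name, chrom_length))
        starts = np.arange(0, chrom_length - window_size + 1, step, dtype=np.int64)
        n = len(starts)
        gc = np.empty(n)
        state = GC_MEAN + GC_STATIONARY_SD * rng.standard_normal()
        eps = rng.standard_normal(n)
        for i in range(n):
            state = GC_MEAN + gc_autocorrelation * (state - GC_MEAN) + innov_sd * eps[i]
            # reflect into bounds
            if state < lo:
                state = lo + (lo - state)
            if state > hi:
                state = hi - (state - hi)
            gc[i] = min(max(state, lo), hi)
        frames.append(
            pd.DataFrame(
                {"chrom": name, "start": starts, "end": starts + window_size, "gc": gc}
            )
        )
    windows = pd.concat(frames, ignore_index=True)
    return SimulatedReference(chroms, windows, window_size, step)


def _check_events(ref: SimulatedReference, events: list[CnvEvent]) -> None:
    lengths = dict(ref.chromosomes)
    by_chrom: dict[str, list[CnvEvent]] = {}
    for ev in events:
        if ev.chrom not in lengths:
            raise InvalidArgumentError(f"event chromosome {ev.chrom} not in reference")
        if ev.start < 0 or ev.end > lengths[ev.chrom]:
            raise InvalidArgumentError(
                f"event {ev.chrom}:{ev.start}-{ev.end} outside chromosome bounds"
            )
        by_chrom.setdefault(ev.chrom, []).append(ev)
    for chrom, evs in by_chrom.items():
        evs = sorted(evs, key=lambda e: e.start)
        for a, b in zip(evs, evs[1:]):
            if b.start < a.end:
                raise InvalidArgumentError(
                    f"overlapping events on {chrom}: {a.start}-{a.end} and {b.start}-{b.end}"
                )


def implant_cnvs(
    ref: SimulatedReference,
    pop_sizes: dict[str, int],
    events: list[CnvEvent],
    seed: int = 0,
) -> TruthSet:
    """Draw diploid genotypes for each event and build the truth CN track.

    Each individual carries ``Binomial(2, allele_freq[pop])`` copies of each
    event allele; the copy-number track is ``2 + sum(alleles * copy_change)``
    over events overlapping the window, floored at 0.
    """
    _check_events(ref, events)
    if not pop_sizes or any(n <= 0 for n in pop_sizes.values()):
        raise InvalidArgumentError("population sizes must be positive")

    rng = np.random.default_rng(seed)
    sample_ids: list[str] = []
    assignments: dict[str, str] = {}
    for pop, n in pop_sizes.items():
        for i in range(n):
            sid = f"{pop}_{i:03d}"
            sample_ids.append(sid)
            assignments[sid] = pop
    popmap = PopulationMap(assignments)
    pops = np.array([assignments[s] for s in sample_ids])

    n_samples = len(sample_ids)
    win = ref.windows
    starts = win["start"].to_numpy()
    ends = win["end"].to_numpy()
    chrom_arr = win["chrom"].to_numpy()

    delta = np.zeros((n_samples, len(win)), dtype=np.int64)
    genotypes = np.zeros((n_samples, len(events)), dtype=np.int64)
    for j, ev in enumerate(events):
        alleles = np.zeros(n_samples, dtype=np.int64)
        for pop in pop_sizes:
            sel = pops == pop
            freq = ev.allele_freq.get(pop, 0.0)
            alleles[sel] = rng.binomial(2, freq, size=int(sel.sum()))
        genotypes[:, j] = alleles
        hit = (chrom_arr == ev.chrom) & (starts < ev.end) & (ends > ev.start)
        delta[:, hit] += (alleles * ev.copy_change)[:, None]

    cn = np.maximum(2 + delta, 0)
    return TruthSet(list(events), cn, sample_ids, popmap, ref, genotypes)


def gc_bias_factor(gc: np.ndarray, amplitude: float) -> np.ndarray:
    """Unimodal multiplicative depth bias, peak at GC 0.5.

    ``amplitude`` is the fractional depth loss at |gc - 0.5| = 0.2; the
    factor is clipped to [0.1, 1].
    """
    gc = np.asarray(gc, dtype=float)
    return np.clip(1.0 - amplitude * ((gc - 0.5) / 0.2) ** 2, 0.1, 1.0)


def simulate_depth(
    truth: TruthSet,
    ref: SimulatedReference | None = None,
    mean_depth: float = 12.0,
    gc_bias_amplitude: float = 0.2,
    dispersion: float = 300.0,
    read_length: int = 100,
    seed: int = 0,
) -> WindowDepthMatrix:
    """Draw window read counts from the truth copy-number track.

    Expected count = (mean_depth * window_size / read_length)
    * (copy_number / 2) * gc_bias(gc). Counts are negative binomial with
    size ``dispersion`` (variance = mu + mu^2/dispersion); ``math.inf``
    selects the Poisson limit.
    """
    if ref is None:
        ref = truth.reference
    if mean_depth <= 0:
        raise InvalidArgumentError("mean_depth must be positive")
    if dispersion <= 0:
        raise InvalidArgumentError("dispersion must be positive")
    if read_length <= 0:
        raise InvalidArgumentError("read_length must be positive")

    rng = np.random.default_rng(seed)
    mu0 = mean_depth * ref.window_size / read_length
    bias = gc_bias_factor(ref.windows["gc"].to_numpy(), gc_bias_amplitude)
    mu = mu0 * (truth.copy_number / 2.0) * bias[None, :]

    if math.isinf(dispersion):
        counts = rng.poisson(mu).astype(float)
    else:
        # NB(size=k, p=k/(k+mu)) has mean mu and variance mu + mu^2/k;
        # mu = 0 gives p = 1 and a deterministic zero count.
        k = float(dispersion)
        p = k / (k + mu)
        counts = rng.negative_binomial(k, p).astype(float)

    return WindowDepthMatrix(
        windows=ref.windows.copy(), counts=counts, sample_ids=list(truth.sample_ids)
    )


def random_events(
    ref: SimulatedReference,
    populations: tuple[str, ...] = ("A", "B"),
    n_events: int = 50,
    length_range: tuple[int, int] = (2_000, 50_000),
    carrier_freq: float | tuple[float, float] = (0.2, 0.8),
    min_gap: int | None = None,
    seed: int = 0,
) -> list[CnvEvent]:
    """Place non-overlapping deletion/duplication events on the reference.

    Lengths are log-uniform over ``length_range``; coordinates are snapped
    to the window step (the truth track is window-granular). ``carrier_freq``
    is either a fixed carrier frequency (shared by all populations) or a
    (lo, hi) range sampled per event; kinds alternate deletion/duplication
    with copy change -1/+1.
    """
    if n_events <= 0:
        raise InvalidArgumentError("n_events must be positive")
    rng = np.random.default_rng(seed)
    step = ref.step
    if min_gap is None:
        min_gap = 8 * step
    lengths_by_chrom = dict(ref.chromosomes)
    chrom_names = list(lengths_by_chrom)

    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    events: list[CnvEvent] = []
    attempts = 0
    lo_len, hi_len = length_range
    while len(events) < n_events:
        attempts += 1
        if attempts > 200 * n_events:
            raise InvalidArgumentError("could not place events; reduce n_events or lengths")
        chrom = chrom_names[int(rng.integers(len(chrom_names))) ]
        length = int(math.exp(rng.uniform(math.log(lo_len), math.log(hi_len))))
        length = max(2 * step, int(round(length / step)) * step)
        max_start = lengths_by_chrom[chrom] - length
        if max_start <= 0:
            continue
        start = int(rng.integers(0, max_start // step + 1)) * step
        end = start + length
        if any(start - min_gap < e and end + min_gap > s for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, end))
        kind = "deletion" if len(events) % 2 == 0 else "duplication"
        change = -1 if kind == "deletion" else 1
        if isinstance(carrier_freq, tuple):
            cf = float(rng.uniform(*carrier_freq))
        else:
            cf = float(carrier_freq)
        af = CnvEvent.carrier_to_allele_freq(cf)
        events.append(
            CnvEvent(chrom, start, end, kind, change, {p: af for p in populations})
        )
    events.sort(key=lambda e: (e.chrom, e.start))
    return events


def simulate_cohort(
    pop_sizes: dict[str, int] | None = None,
    n_chrom: int = 1,
    chrom_length: int = 10_000_000,
    window_size: int = 800,
    step: int = 400,
    n_events: int = 50,
    carrier_freq: float | tuple[float, float] = (0.2, 0.8),
    length_range: tuple[int, int] = (2_000, 50_000),
    mean_depth: float = 12.0,
    gc_bias_amplitude: float = 0.2,
    dispersion: float = 300.0,
    seed: int = 0,
) -> tuple[WindowDepthMatrix, TruthSet]:
    """Reference + events + genotypes + depths in one call (default desk-scale
    study: 2 populations x 20 individuals, 10 Mb, 800-bp windows, 400-bp step,
    12x mean depth)."""
    if pop_sizes is None:
        pop_sizes = {"A": 20, "B": 20}
    ss = np.random.SeedSequence(seed)
    s_ref, s_ev, s_geno, s_depth = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    ref = simulate_reference(
        n_chrom=n_chrom, chrom_length=chrom_length, window_size=window_size,
        step=step, seed=s_ref,
    )
    events = random_events(
        ref, populations=tuple(pop_sizes), n_events=n_events,
        length_range=length_range, carrier_freq=carrier_freq, seed=s_ev,
    )
    truth = implant_cnvs(ref, pop_sizes, events, seed=s_geno)
    depth = simulate_depth(
        truth, ref, mean_depth=mean_depth, gc_bias_amplitude=gc_bias_amplitude,
        dispersion=dispersion, seed=s_depth,
    )
    return depth, truth


def synthetic_gene_model(
    ref: SimulatedReference, n_genes: int = 200, seed: int = 0
):
    """A random, non-overlapping gene model on the simulated reference.

    Genes are 5–60 kb with 2–8 exons, alternating strand, ~15% non-coding;
    coding transcripts get a CDS trimmed inside the outer exons. Synthetic
    stand-in for a real annotation, for exercising the annotation stage.
    """
    from .annotation import GeneModel, Transcript

    rng = np.random.default_rng(seed)
    transcripts = []
    for chrom, length in ref.chromosomes:
        cursor = int(rng.integers(1_000, 10_000))
        g = 0
        while g < n_genes and cursor < length - 70_000:
            span = int(rng.integers(5_000, 60_000))
            start = cursor
            end = min(start + span, length)
            n_exons = int(rng.integers(2, 9))
            cuts = np.sort(rng.choice(np.arange(1, span // 100), size=2 * n_exons, replace=False)) * 100
            exons = []
            for i in range(n_exons):
                es, ee = start + int(cuts[2 * i]), start + int(cuts[2 * i + 1])
                exons.append((es, min(ee, end)))
            coding = rng.random() > 0.15
            cds = None
            if coding:
                cds = (exons[0][0] + 100, exons[-1][1] - 100)
                if cds[1] <= cds[0]:
                    cds = (exons[0][0], exons[-1][1])
            name = f"GENE{len(transcripts) + 1:04d}"
            transcripts.append(
                Transcript(
                    gene=name,
                    transcript_id=f"{name}.t1",
                    chrom=chrom,
                    strand="+" if g % 2 == 0 else "-",
                    start=start,
                    end=end,
                    exons=tuple(exons),
                    cds=cds,
                )
            )
            g += 1
            cursor = end + int(rng.integers(5_000, 40_000))
    return GeneModel(transcripts)


def simulate_cnvr_cohort(
    n_background: int = 500,
    n_differential: int = 5,
    pop_sizes: dict[str, int] | None = None,
    focal: str = "A",
    differential_carrier_freqs: tuple[float, float] = (0.9, 0.1),
    background_carrier_freq: tuple[float, float] = (0.05, 0.95),
    differential_kind: str = "mixed",
    noise_sd: float = 0.15,
    seed: int = 0,
):
    """Directly simulate a per-CNVR mean-copy-number cohort.

    Used for differentiation-scan and stratification studies where window-level
    detail is irrelevant: each CNVR gets a carrier frequency per population,
    per-individual diploid allele draws, and Gaussian measurement noise on the
    mean copy number. Returns ``(cnvrs, popmap, differential_flags)`` where
    ``cnvrs`` are :class:`~cnvpop.discovery.Cnvr` records (silhouette set to
    1.0 by construction).

    ``differential_kind``: "mixed" alternates deletion/duplication for the
    differential CNVRs, or force "deletion"/"duplication".
    """
    from .discovery import Cnvr, classify_genotypes

    if pop_sizes is None:
        pop_sizes = {"A": 20, "B": 20}
    if focal not in pop_sizes:
        raise InvalidArgumentError(f"focal population {focal!r} not in pop_sizes")
    rng = np.random.default_rng(seed)

    sample_ids: list[str] = []
    assignments: dict[str, str] = {}
    for pop, n in pop_sizes.items():
        for i in range(n):
            sid = f"{pop}_{i:03d}"
            sample_ids.append(sid)
            assignments[sid] = pop
    popmap = PopulationMap(assignments)
    pops = np.array([assignments[s] for s in sample_ids])

    n_total = n_background + n_differential
    cnvrs: list[Cnvr] = []
    flags = np.zeros(n_total, dtype=bool)
    spacing = 10_000
    length = 4_000
    for j in range(n_total):
        differential = j >= n_background
        flags[j] = differential
        if differential:
            d_idx = j - n_background
            if differential_kind == "mixed":
                kind = "deletion" if d_idx % 2 == 0 else "duplication"
            else:
                kind = differential_kind
            cf_focal, cf_other = differential_carrier_freqs
            cf = {p: (cf_focal if p == focal else cf_other) for p in pop_sizes}
        else:
            kind = "deletion" if j % 2 == 0 else "duplication"
            shared = float(rng.uniform(*background_carrier_freq))
            cf = {p: shared for p in pop_sizes}
        change = -1 if kind == "deletion" else 1
        af = {p: CnvEvent.carrier_to_allele_freq(f) for p, f in cf.items()}
        alleles = np.empty(len(sample_ids), dtype=np.int64)
        for pop in pop_sizes:
            sel = pops == pop
            alleles[sel] = rng.binomial(2, af[pop], size=int(sel.sum()))
        cn = np.maximum(2.0 + alleles * change, 0.0)
        cn = np.maximum(cn + rng.normal(0.0, noise_sd, size=cn.shape), 0.0)
        start = j * spacing
        cnvrs.append(
            Cnvr(
                chrom="chr1",
                start=start,
                end=start + length,
                kind=kind,
                n_windows=max(1, length // 400),
                silhouette=1.0,
                sample_ids=list(sample_ids),
                mean_cn=cn,
                genotypes=classify_genotypes(cn),
            )
        )
    return cnvrs, popmap, flags
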