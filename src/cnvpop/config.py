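"""Pipeline configuration and the run-all driver.

A :class:`PipelineConfig` collects every stage parameter (the discovery
defaults are the standard population-scale caller settings: 800-bp windows,
f=0.1, h=3, r=0.1, silhouette > 0.6, deletion/both <= 50 kb, duplication
< 500 kb, top-1% V_ST outliers). ``run_pipeline`` executes
simulate -> normalize -> call -> annotate -> pca -> vst and writes a
manifest recording the config, seed, per-stage row counts, and output
checksums; a rerun with identical config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import InvalidArgumentError

logger = logging.getLogger("cnvpop")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    # simulation
    window_size: int = 800
    step: int = 400
    n_chrom: int = 1
    chrom_length: int = 10_000_000
    pop_sizes: dict = field(default_factory=lambda: {"A": 20, "B": 20})
    n_events: int = 50
    carrier_freq_low: float = 0.2
    carrier_freq_high: float = 0.8
    event_min_len: int = 2_000
    event_max_len: int = 50_000
    mean_depth: float = 12.0
    gc_bias_amplitude: float = 0.2
    dispersion: float = 300.0
    n_genes: int = 200
    # normalization
    mask_low_q: float = 0.0
    mask_high_q: float = 1.0
    gc_bin_width: float = 0.01
    # discovery
    f: float = 0.1
    h: int = 3
    r: float = 0.1
    max_gap: int = 1
    min_windows: int = 2
    loss_threshold: float = 1.5
    gain_threshold: float = 2.5
    silhouette_min: float = 0.6
    del_both_max_len: int = 50_000
    dup_max_len: int = 500_000
    # pca
    pca_subset: str = "all"
    pca_k: int = 10
    pca_scale: bool = True
    # vst
    vst_q: float = 0.01
    vst_focal: str = "A"
    # run
    seed: int = 0
    outdir: str = "cnvpop_run"
    # optional user inputs; when depth_path is set the simulate stage is skipped
    depth_path: str | None = None
    popmap_path: str | None = None
    gene_model_path: str | None = None

    def __post_init__(self) -> None:
        checks = [
            (self.window_size > 0, "window_size must be positive"),
            (self.step in (self.window_size, self.window_size // 2),
             "step must equal window_size or window_size/2"),
            (0 < self.f <= 1, "f must be in (0, 1]"),
            (self.h >= 1, "h must be >= 1"),
            (-1 <= self.r <= 1, "r must be in [-1, 1]"),
            (self.loss_threshold < 2 < self.gain_threshold,
             "need loss_threshold < 2 < gain_threshold"),
            (-1 <= self.silhouette_min <= 1, "silhouette_min must be in [-1, 1]"),
            (0 <= self.mask_low_q < self.mask_high_q <= 1,
             "need 0 <= mask_low_q < mask_high_q <= 1"),
            (0 < self.gc_bin_width <= 0.5, "gc_bin_width must be in (0, 0.5]"),
            (0 < self.vst_q < 1, "vst_q must be in (0, 1)"),
            (self.pca_subset in ("deletions", "duplications", "both", "all"),
             "bad pca_subset"),
            (self.mean_depth > 0, "mean_depth must be positive"),
            (self.dispersion > 0, "dispersion must be positive"),
            (0 <= self.carrier_freq_low <= self.carrier_freq_high <= 1,
             "carrier frequency bounds out of order"),
            (self.del_both_max_len > 0 and self.dup_max_len > 0,
             "length caps must be positive"),
        ]
        for ok, msg in checks:
            if not ok:
                raise InvalidArgumentError(msg)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the manifest (also written to disk)."""
    from . import io as pio
    from .annotation import annotate_cnvrs, feature_fractions, summarize_lengths
    from .discovery import call_cnvrs
    from .normalize import normalize
    from .pca import build_matrix, pca
    from .simulate import simulate_cohort, synthetic_gene_model
    from .vst import map_outliers_to_genes, top_outliers, vst_scan

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "seed": config.seed, "stages": []}
    outputs: dict[str, Path] = {}

    def stage(name: str, **counts) -> None:
        logger.info("stage %s: %s", name, counts)
        manifest["stages"].append({"name": name, **counts})

    # ---- simulate (or load user inputs)
    if config.depth_path is None:
        depth, truth = simulate_cohort(
            pop_sizes=dict(config.pop_sizes),
            n_chrom=config.n_chrom,
            chrom_length=config.chrom_length,
            window_size=config.window_size,
            step=config.step,
            n_events=config.n_events,
            carrier_freq=(config.carrier_freq_low, config.carrier_freq_high),
            length_range=(config.event_min_len, config.event_max_len),
            mean_depth=config.mean_depth,
            gc_bias_amplitude=config.gc_bias_amplitude,
            dispersion=config.dispersion,
            seed=config.seed,
        )
        popmap = truth.populations
        pio.write_depth_matrix(depth, outdir / "depth.tsv")
        pio.write_truth_bed(truth.events, outdir / "truth.bed")
        pio.write_population_map(popmap, outdir / "popmap.tsv")
        outputs.update(
            depth=outdir / "depth.tsv",
            truth=outdir / "truth.bed",
            popmap=outdir / "popmap.tsv",
        )
        stage("simulate", windows=depth.n_windows, samples=depth.n_samples,
              events=len(truth.events))
        if config.gene_model_path is None:
            model = synthetic_gene_model(
                truth.reference, n_genes=config.n_genes, seed=config.seed + 1
            )
            pio.write_gene_model_gff3(model, outdir / "genes.gff3")
            outputs["genes"] = outdir / "genes.gff3"
        else:
            model = pio.read_gene_model(config.gene_model_path)
    else:
        depth = pio.read_depth_matrix(config.depth_path)
        if config.popmap_path is None:
            raise InvalidArgumentError("popmap_path required with depth_path")
        popmap = pio.read_population_map(config.popmap_path)
        model = (
            pio.read_gene_model(config.gene_model_path)
            if config.gene_model_path
            else None
        )
        stage("load", windows=depth.n_windows, samples=depth.n_samples)

    # ---- normalize
    cn = normalize(
        depth,
        low_q=config.mask_low_q,
        high_q=config.mask_high_q,
        gc_bin_width=config.gc_bin_width,
    )
    pio.write_cn_matrix(cn, outdir / "cn.tsv")
    outputs["cn"] = outdir / "cn.tsv"
    stage("normalize", windows=cn.n_windows, masked=int(cn.mask.sum()),
          samples=cn.n_samples)

    # ---- call
    cnvrs, call_stats = call_cnvrs(
        cn,
        f=config.f, h=config.h, r=config.r,
        max_gap=config.max_gap, min_windows=config.min_windows,
        loss_threshold=config.loss_threshold,
        gain_threshold=config.gain_threshold,
        silhouette_min=config.silhouette_min,
        del_both_max_len=config.del_both_max_len,
        dup_max_len=config.dup_max_len,
    )
    pio.write_cnvr_table(cnvrs, outdir / "cnvr.tsv")
    outputs["cnvr"] = outdir / "cnvr.tsv"
    stage("call", **call_stats)

    # ---- annotate
    if model is not None and cnvrs:
        annotations = annotate_cnvrs(cnvrs, model)
        with open(outdir / "annotation.tsv", "w") as fh:
            fh.write("cnvr\tcategory\tgenes\n")
            for a in annotations:
                fh.write(f"{a.cnvr_id}\t{a.category}\t{','.join(a.gene_names)}\n")
        summarize_lengths(cnvrs).to_csv(outdir / "length_summary.tsv", sep="\t")
        fractions = feature_fractions(annotations)
        outputs["annotation"] = outdir / "annotation.tsv"
        outputs["length_summary"] = outdir / "length_summary.tsv"
        stage("annotate", cnvrs=len(annotations),
              categories=len(fractions))
    else:
        stage("annotate", cnvrs=0, categories=0)

    # ---- pca
    try:
        matrix = build_matrix(cnvrs, subset=config.pca_subset, populations=popmap)
        result = pca(matrix, k=config.pca_k, scale=config.pca_scale)
        pio.write_pca_results(result, popmap, outdir / "pca")
        outputs["pca_coords"] = outdir / "pca.coords.tsv"
        outputs["pca_variance"] = outdir / "pca.variance.tsv"
        stage("pca", cnvrs=matrix.n_cnvrs, components=len(result.variance_explained))
    except InvalidArgumentError as exc:
        stage("pca", cnvrs=0, components=0, skipped=str(exc))

    # ---- vst
    if cnvrs:
        records = vst_scan(cnvrs, popmap, focal=config.vst_focal)
        records = top_outliers(records, q=config.vst_q)
        if model is not None:
            outliers = [r for r in records if r.outlier]
            gene_table = map_outliers_to_genes(outliers, model)
            gene_table.to_csv(outdir / "vst_outlier_genes.tsv", sep="\t", index=False)
            outputs["vst_genes"] = outdir / "vst_outlier_genes.tsv"
        pio.write_vst_table(records, outdir / "vst.tsv")
        outputs["vst"] = outdir / "vst.tsv"
        stage("vst", records=len(records),
              outliers=sum(r.outlier for r in records))
    else:
        stage("vst", records=0, outliers=0)

    manifest["outputs"] = {
        name: {"path": str(p), "sha256": _sha256(p)} for name, p in outputs.items()
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
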