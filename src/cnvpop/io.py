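"""Readers and writers for the pipeline's plain-text formats.

Dialects (all tab-separated, all coordinates 0-based half-open except GFF3,
which is converted on read):

* depth matrix  — ``chrom start end gc <sample>...``
* CN matrix     — ``chrom start end gc mask <sample>...``
* population map — ``sample population``
* truth BED     — ``chrom start end kind copy_change freqs`` with freqs as
  ``pop=allele_freq`` pairs joined by ``;``
* CNVR table    — ``chrom start end kind n_windows silhouette cn:<sample>...
  gt:<sample>...``
* gene model    — GFF3 (via gffutils) or BED12

Writers and readers round-trip exactly (floats serialized at %.17g).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel, Transcript
from .core import (
    CopyNumberMatrix,
    InvalidArgumentError,
    PopulationMap,
    WindowDepthMatrix,
)
from .discovery import Cnvr
from .simulate import CnvEvent

__all__ = [
    "read_depth_matrix",
    "write_depth_matrix",
    "read_cn_matrix",
    "write_cn_matrix",
    "read_population_map",
    "write_population_map",
    "read_truth_bed",
    "write_truth_bed",
    "read_cnvr_table",
    "write_cnvr_table",
    "read_gene_model",
    "write_gene_model_gff3",
    "write_vst_table",
    "write_pca_results",
]

_FLOAT = "%.17g"


def _fmt(x: float) -> str:
    return _FLOAT % x


class FormatError(InvalidArgumentError):
    """A file does not parse under its declared dialect."""


def _parse_error(path, line_no: int, reason: str) -> FormatError:
    return FormatError(f"{path}:{line_no}: {reason}")


# ---------------------------------------------------------------- matrices

def write_depth_matrix(depth: WindowDepthMatrix, path) -> None:
    df = depth.windows.copy()
    for i, sid in enumerate(depth.sample_ids):
        df[sid] = depth.counts[i]
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT)


def read_depth_matrix(path) -> WindowDepthMatrix:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("chrom", "start", "end", "gc"):
        if col not in df.columns:
            raise _parse_error(path, 1, f"missing column {col!r}")
    samples = [c for c in df.columns if c not in ("chrom", "start", "end", "gc")]
    if not samples:
        raise _parse_error(path, 1, "no sample columns")
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        raise _parse_error(path, int(bad[0]) + 2, "window end <= start")
    return WindowDepthMatrix(
        windows=df[["chrom", "start", "end", "gc"]].copy(),
        counts=df[samples].to_numpy(dtype=float).T,
        sample_ids=samples,
    )


def write_cn_matrix(cn: CopyNumberMatrix, path) -> None:
    df = cn.windows.copy()
    df["mask"] = cn.mask.astype(int)
    for i, sid in enumerate(cn.sample_ids):
        df[sid] = cn.cn[i]
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT)


def read_cn_matrix(path) -> CopyNumberMatrix:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("chrom", "start", "end", "gc", "mask"):
        if col not in df.columns:
            raise _parse_error(path, 1, f"missing column {col!r}")
    samples = [c for c in df.columns if c not in ("chrom", "start", "end", "gc", "mask")]
    if not samples:
        raise _parse_error(path, 1, "no sample columns")
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        raise _parse_error(path, int(bad[0]) + 2, "window end <= start")
    return CopyNumberMatrix(
        windows=df[["chrom", "start", "end", "gc"]].copy(),
        cn=df[samples].to_numpy(dtype=float).T,
        sample_ids=samples,
        mask=df["mask"].to_numpy(dtype=bool),
    )


# ---------------------------------------------------------- population map

def write_population_map(pops: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\n")
        for sample, pop in pops.assignments.items():
            fh.write(f"{sample}\t{pop}\n")


def read_population_map(path) -> PopulationMap:
    assignments: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["sample", "population"]:
            raise _parse_error(path, 1, "expected header 'sample\\tpopulation'")
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not all(parts):
                raise _parse_error(path, line_no, f"expected 2 fields, got {line!r}")
            sample, pop = parts
            if sample in assignments:
                raise _parse_error(path, line_no, f"duplicate sample {sample!r}")
            assignments[sample] = pop
    if not assignments:
        raise _parse_error(path, 2, "no samples")
    return PopulationMap(assignments)


# ---------------------------------------------------------------- truth BED

def write_truth_bed(events: list[CnvEvent], path) -> None:
    with open(path, "w") as fh:
        for ev in events:
            freqs = ";".join(f"{p}={_fmt(f)}" for p, f in sorted(ev.allele_freq.items()))
            fh.write(
                f"{ev.chrom}\t{ev.start}\t{ev.end}\t{ev.kind}\t{ev.copy_change}\t{freqs}\n"
            )


def read_truth_bed(path) -> list[CnvEvent]:
    events: list[CnvEvent] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise _parse_error(path, line_no, f"expected 6 fields, got {len(parts)}")
            chrom, start, end, kind, change, freqs = parts
            try:
                start_i, end_i, change_i = int(start), int(end), int(change)
            except ValueError as exc:
                raise _parse_error(path, line_no, f"non-integer coordinate: {exc}")
            if end_i <= start_i:
                raise _parse_error(path, line_no, "end <= start")
            allele_freq = {}
            for item in freqs.split(";"):
                if "=" not in item:
                    raise _parse_error(path, line_no, f"bad frequency field {item!r}")
                pop, f = item.split("=", 1)
                allele_freq[pop] = float(f)
            events.append(CnvEvent(chrom, start_i, end_i, kind, change_i, allele_freq))
    return events


# --------------------------------------------------------------- CNVR table

def write_cnvr_table(cnvrs: list[Cnvr], path) -> None:
    if not cnvrs:
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tend\tkind\tn_windows\tsilhouette\n")
        return
    samples = cnvrs[0].sample_ids
    cols = ["chrom", "start", "end", "kind", "n_windows", "silhouette"]
    cols += [f"cn:{s}" for s in samples] + [f"gt:{s}" for s in samples]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in cnvrs:
            row = [c.chrom, str(c.start), str(c.end), c.kind, str(c.n_windows),
                   _fmt(c.silhouette)]
            row += [_fmt(v) for v in c.mean_cn]
            row += [str(g) for g in c.genotypes]
            fh.write("\t".join(row) + "\n")


def read_cnvr_table(path) -> list[Cnvr]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        fixed = ["chrom", "start", "end", "kind", "n_windows", "silhouette"]
        if header[: len(fixed)] != fixed:
            raise _parse_error(path, 1, f"expected leading columns {fixed}")
        samples = [c[3:] for c in header[len(fixed):] if c.startswith("cn:")]
        gt_cols = [c[3:] for c in header[len(fixed):] if c.startswith("gt:")]
        if samples != gt_cols:
            raise _parse_error(path, 1, "cn: and gt: sample columns do not match")
        cnvrs: list[Cnvr] = []
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise _parse_error(
                    path, line_no, f"expected {len(header)} fields, got {len(parts)}"
                )
            chrom, start, end, kind, n_windows, sil = parts[:6]
            start_i, end_i = int(start), int(end)
            if end_i <= start_i:
                raise _parse_error(path, line_no, "end <= start")
            n = len(samples)
            cn = np.array([float(x) for x in parts[6 : 6 + n]])
            gt = np.array(parts[6 + n : 6 + 2 * n], dtype=object)
            cnvrs.append(
                Cnvr(
                    chrom=chrom,
                    start=start_i,
                    end=end_i,
                    kind=kind,
                    n_windows=int(n_windows),
                    silhouette=float(sil),
                    sample_ids=list(samples),
                    mean_cn=cn,
                    genotypes=gt,
                )
            )
    return cnvrs


# --------------------------------------------------------------- gene model

def write_gene_model_gff3(model: GeneModel, path) -> None:
    """GFF3 writer (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tx in sorted(model.transcripts, key=lambda t: (t.chrom, t.start)):
            gid = f"gene:{tx.gene}"
            tid = f"tx:{tx.transcript_id}"
            attrs_gene = f"ID={gid};Name={tx.gene}"
            fh.write(
                f"{tx.chrom}\tcnvpop\tgene\t{tx.start + 1}\t{tx.end}\t.\t{tx.strand}\t.\t{attrs_gene}\n"
            )
            ttype = "mRNA" if tx.coding else "ncRNA"
            fh.write(
                f"{tx.chrom}\tcnvpop\t{ttype}\t{tx.start + 1}\t{tx.end}\t.\t{tx.strand}\t.\t"
                f"ID={tid};Parent={gid};Name={tx.transcript_id}\n"
            )
            for i, (es, ee) in enumerate(tx.exons, 1):
                fh.write(
                    f"{tx.chrom}\tcnvpop\texon\t{es + 1}\t{ee}\t.\t{tx.strand}\t.\t"
                    f"ID={tid}.exon{i};Parent={tid}\n"
                )
            if tx.coding:
                cs, ce = tx.cds
                for i, (es, ee) in enumerate(tx.exons, 1):
                    s, e = max(es, cs), min(ee, ce)
                    if e > s:
                        fh.write(
                            f"{tx.chrom}\tcnvpop\tCDS\t{s + 1}\t{e}\t.\t{tx.strand}\t0\t"
                            f"ID={tid}.cds{i};Parent={tid}\n"
                        )


def _read_gff3(path) -> GeneModel:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        force=True,
    )
    transcripts: list[Transcript] = []
    tx_types = {"mRNA", "transcript", "ncRNA", "lnc_RNA", "lincRNA"}
    for feat in db.all_features():
        if feat.featuretype not in tx_types:
            continue
        exons = sorted(
            (e.start - 1, e.end) for e in db.children(feat, featuretype="exon")
        )
        cds_parts = [(c.start - 1, c.end) for c in db.children(feat, featuretype="CDS")]
        cds = None
        if cds_parts:
            cds = (min(s for s, _ in cds_parts), max(e for _, e in cds_parts))
        gene_name = None
        for parent in db.parents(feat, featuretype="gene"):
            gene_name = parent.attributes.get("Name", [parent.id])[0]
            break
        if gene_name is None:
            gene_name = feat.attributes.get("gene", [feat.id])[0]
        if not exons:
            exons = [(feat.start - 1, feat.end)]
        transcripts.append(
            Transcript(
                gene=gene_name,
                transcript_id=feat.attributes.get("Name", [feat.id])[0],
                chrom=feat.seqid,
                strand=feat.strand if feat.strand in "+-" else "+",
                start=feat.start - 1,
                end=feat.end,
                exons=tuple(exons),
                cds=cds,
            )
        )
    if not transcripts:
        raise FormatError(f"{path}: no transcript features found")
    return GeneModel(transcripts)


def _read_bed12(path) -> GeneModel:
    transcripts: list[Transcript] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise _parse_error(path, line_no, f"BED12 needs 12 fields, got {len(parts)}")
            chrom = parts[0]
            start, end = int(parts[1]), int(parts[2])
            name = parts[3]
            strand = parts[5] if parts[5] in "+-" else "+"
            thick_start, thick_end = int(parts[6]), int(parts[7])
            n_blocks = int(parts[9])
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            starts = [int(x) for x in parts[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise _parse_error(path, line_no, "block count mismatch")
            exons = tuple(
                (start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)
            )
            cds = (thick_start, thick_end) if thick_end > thick_start else None
            transcripts.append(
                Transcript(
                    gene=name,
                    transcript_id=name,
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    exons=exons,
                    cds=cds,
                )
            )
    if not transcripts:
        raise FormatError(f"{path}: empty BED12")
    return GeneModel(transcripts)


def read_gene_model(path) -> GeneModel:
    """Dispatch on extension: .gff/.gff3 via gffutils, .bed as BED12."""
    suffix = Path(path).suffix.lower()
    if suffix in (".gff", ".gff3"):
        return _read_gff3(path)
    if suffix == ".bed":
        return _read_bed12(path)
    raise InvalidArgumentError(f"unknown gene model format {suffix!r} for {path}")


# ------------------------------------------------------------------ results

def write_vst_table(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tfocal\tother\tv_t\tv_s\tvst\trank\toutlier\tgenes\n")
        for r in records:
            rank = "" if r.rank is None else str(r.rank)
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.pair[0]}\t{r.pair[1]}\t"
                f"{_fmt(r.v_t)}\t{_fmt(r.v_s)}\t{_fmt(r.vst)}\t{rank}\t"
                f"{int(r.outlier)}\t{','.join(r.genes)}\n"
            )


def write_pca_results(result, populations: PopulationMap | None, prefix) -> None:
    """Write <prefix>.coords.tsv (sample, population, PC1..PCk) and
    <prefix>.variance.tsv."""
    prefix = os.fspath(prefix)
    k = result.coordinates.shape[1]
    with open(prefix + ".coords.tsv", "w") as fh:
        fh.write("sample\tpopulation\t" + "\t".join(f"PC{i+1}" for i in range(k)) + "\n")
        for i, sid in enumerate(result.sample_ids):
            pop = populations.population_of(sid) if populations else "."
            coords = "\t".join(_fmt(v) for v in result.coordinates[i])
            fh.write(f"{sid}\t{pop}\t{coords}\n")
    with open(prefix + ".variance.tsv", "w") as fh:
        fh.write("component\tvariance_explained\n")
        for i, v in enumerate(result.variance_explained):
            fh.write(f"PC{i+1}\t{_fmt(v)}\n")
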