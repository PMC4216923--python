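"""Readers and writers for the pipeline's on-disk formats.

Cytosine tables use the Bismark cytosine-report layout (chromosome,
1-based position, strand, methylated count, unmethylated count, context,
trinucleotide), one file per sample; variant tables are minimal VCF
(per-sample AD/DP) or an equivalent TSV; annotations are BED (0-based
half-open) or GFF3; sample manifests and truth tables are TSV.  Leading
``#`` comment lines carry run metadata (seed, config hash) and are
skipped on read.  VCF reading goes through pysam.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .genome import AnnotationSet, SyntheticGenome
from .pedigree import PedigreeSample, samples_from_frame, samples_to_frame

CYTOSINE_COLUMNS = ["chrom", "pos", "strand", "meth", "unmeth", "context", "tri"]


def _header_lines(meta: Optional[dict]) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in sorted(meta.items()))


def write_cytosine_report(records: pd.DataFrame, sample: str, path,
                          meta: Optional[dict] = None) -> None:
    """One sample's counts as a Bismark-style cytosine report TSV."""
    df = records[["chrom", "pos", "strand"]].copy()
    df["meth"] = records[f"{sample}:meth"]
    df["unmeth"] = records[f"{sample}:unmeth"]
    df["context"] = records["context"]
    df["tri"] = records["tri"] if "tri" in records else "NNN"
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_cytosine_report(path, sample: str) -> pd.DataFrame:
    """Read one Bismark-style cytosine report into the wide convention."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=CYTOSINE_COLUMNS,
                     dtype={"chrom": str, "pos": np.int64, "strand": str,
                            "meth": np.int64, "unmeth": np.int64,
                            "context": str, "tri": str})
    _validate_cytosines(df, path)
    df = df.rename(columns={"meth": f"{sample}:meth",
                            "unmeth": f"{sample}:unmeth"})
    return df


def _validate_cytosines(df: pd.DataFrame, path) -> None:
    bad_ctx = ~df["context"].isin(["CG", "CHG", "CHH"])
    if bad_ctx.any():
        line = int(df.index[bad_ctx][0]) + 1
        raise ValueError(f"{path}: bad context at data line {line}")
    neg = (df["meth"] < 0) | (df["unmeth"] < 0)
    if neg.any():
        line = int(df.index[neg][0]) + 1
        raise ValueError(f"{path}: negative count at data line {line}")


def merge_cytosine_reports(paths: Dict[str, object]) -> pd.DataFrame:
    """Outer-merge per-sample reports on (chrom, pos, strand, context, tri).

    Sites missing from a sample get zero counts (hence 'not evaluable'
    downstream).
    """
    merged: Optional[pd.DataFrame] = None
    for sample, path in paths.items():
        df = read_cytosine_report(path, sample)
        if merged is None:
            merged = df
        else:
            merged = merged.merge(df, on=["chrom", "pos", "strand",
                                          "context", "tri"], how="outer")
    assert merged is not None, "no reports given"
    count_cols = [c for c in merged.columns if ":" in c]
    merged[count_cols] = merged[count_cols].fillna(0).astype(np.int64)
    merged = merged.sort_values(["chrom", "pos", "strand"],
                                kind="mergesort").reset_index(drop=True)
    return merged


def write_manifest(samples: Sequence[PedigreeSample], path,
                   files: Optional[Dict[str, str]] = None,
                   meta: Optional[dict] = None) -> None:
    frame = samples_to_frame(list(samples))
    if files:
        frame["file"] = frame["sample_id"].map(files)
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        frame.to_csv(fh, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#",
                       dtype={"sample_id": str, "lineage_id": str})


def manifest_samples(frame: pd.DataFrame) -> List[PedigreeSample]:
    return samples_from_frame(frame)


# ---------------------------------------------------------------- variants

def write_variants_tsv(candidates: pd.DataFrame, path,
                       meta: Optional[dict] = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        candidates.to_csv(fh, sep="\t", index=False)


def read_variants_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})


def write_vcf(candidates: pd.DataFrame, samples: Sequence[str], path,
              chrom_sizes: Optional[Dict[str, int]] = None,
              meta: Optional[dict] = None) -> None:
    """Minimal VCFv4.2 with per-sample AD (ref,alt) and DP."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for k, v in sorted((meta or {}).items()):
            fh.write(f"##{k}={v}\n")
        for chrom, size in sorted((chrom_sizes or {}).items()):
            fh.write(f"##contig=<ID={chrom},length={size}>\n")
        fh.write('##INFO=<ID=VCLASS,Number=1,Type=String,'
                 'Description="Variant class">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,'
                 'Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        cols = list(candidates.columns)
        for values in candidates.itertuples(index=False, name=None):
            d = dict(zip(cols, values))
            cells = [d["chrom"], str(d["pos"]), ".", d["ref"], d["alt"], ".",
                     ".", f"VCLASS={d['vclass']}", "AD:DP"]
            for s in samples:
                alt = int(d[f"{s}:alt"])
                dp = int(d[f"{s}:dp"])
                cells.append(f"{dp - alt},{alt}:{dp}")
            fh.write("\t".join(cells) + "\n")


def read_vcf(path) -> pd.DataFrame:
    """Read a minimal VCF back into the wide candidate-table convention."""
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"{path}: multi-allelic record at {rec.chrom}:{rec.pos}")
            row = {"chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref,
                   "alt": rec.alts[0],
                   "vclass": rec.info.get("VCLASS", "SBS")}
            for s in samples:
                ad = rec.samples[s].get("AD")
                dp = rec.samples[s].get("DP")
                row[f"{s}:alt"] = int(ad[1]) if ad is not None else 0
                row[f"{s}:dp"] = int(dp) if dp is not None else 0
            rows.append(row)
    return pd.DataFrame(rows)


# -------------------------------------------------------------- annotation

def write_annotation_bed(annotation: AnnotationSet, path,
                         meta: Optional[dict] = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        for row in annotation.intervals.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.category}\n")


def read_annotation_bed(path, chrom_sizes: Dict[str, int]) -> AnnotationSet:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "category"],
                     dtype={"chrom": str, "start": np.int64, "end": np.int64,
                            "category": str})
    return AnnotationSet(df, dict(chrom_sizes))


def write_annotation_gff3(annotation: AnnotationSet, path,
                          meta: Optional[dict] = None) -> None:
    type_of = {"CDS": "CDS", "UTR": "UTR", "intron": "intron",
               "ncRNA": "ncRNA_gene", "pseudogene": "pseudogene",
               "TE": "transposable_element", "intergenic": "region"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(_header_lines(meta))
        for i, row in enumerate(annotation.intervals.itertuples(index=False)):
            fh.write(f"{row.chrom}\tmaepi\t{type_of[row.category]}\t"
                     f"{row.start + 1}\t{row.end}\t.\t+\t.\t"
                     f"ID=feat{i};category={row.category}\n")


def write_fasta(genome: SyntheticGenome, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_chrom_sizes(chrom_sizes: Dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, size in sorted(chrom_sizes.items()):
            fh.write(f"{name}\t{size}\n")


def read_chrom_sizes(path) -> Dict[str, int]:
    out = {}
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                name, size = line.split()[:2]
                out[name] = int(size)
    return out


# ------------------------------------------------------------------- misc

def write_dmps_bed(dmps: pd.DataFrame, path) -> None:
    """DMP calls as BED6 (0-based half-open), score = -log10 q."""
    with open(path, "w") as fh:
        for row in dmps.itertuples(index=False):
            score = -np.log10(max(row.q, 1e-300))
            fh.write(f"{row.chrom}\t{row.pos - 1}\t{row.pos}\t"
                     f"{row.sample}:{row.direction}\t{score:.3f}\t{row.strand}\n")


def write_dmrs_bed(dmrs: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in dmrs.itertuples(index=False):
            score = -np.log10(max(row.q, 1e-300))
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t"
                     f"{row.sample}\t{score:.3f}\t.\n")


def write_tsv(frame: pd.DataFrame, path, meta: Optional[dict] = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        frame.to_csv(fh, sep="\t", index=False)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, Path):
        return str(x)
    raise TypeError(f"not JSON serialisable: {type(x)}")
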