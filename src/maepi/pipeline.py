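"""End-to-end pipeline: variants -> methylome -> DMPs -> DMRs -> distribution.

``make_fixture`` materialises a complete synthetic input set on disk
(cytosine reports, VCF, annotation, manifest, truth tables);
``run_pipeline`` executes every analysis stage from such an input set
and writes stage outputs plus a JSON run report.  Identical config and
seed give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .annotation import (chromosome_profile, genic_enrichment_test,
                         regional_dmp_fraction)
from .config import SimulationConfig
from .counts import simulate_bisulfite_counts, simulate_variant_counts
from .genome import generate_genome
from .methylation import (MethylationCallPolicy, call_dmps, call_dmrs,
                          cluster_samples, dmp_summary,
                          estimate_conversion_rate, remove_parental_dmps,
                          retention_analysis, site_universe)
from .pedigree import simulate_pedigree
from .variants import (FilterPolicy, UndefinedTiTvError, filter_variants,
                       lineage_rates, rate_comparison_table, titv_ratio)

logger = logging.getLogger(__name__)

STAGES = ("variants", "methylated_sites", "parental_removal", "dmps",
          "dmrs", "retention", "clustering", "distribution")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths, policies and seed for one pipeline run."""

    out_dir: str
    manifest: str
    variants: str
    annotation: str
    chrom_sizes: str
    spikein: Optional[str] = None
    centromeres: Optional[str] = None
    seed: int = 0
    generations: int = 10
    gc_content: float = 0.36
    cluster_sites: int = 20_000
    filter_policy: FilterPolicy = field(default_factory=FilterPolicy)
    methylation_policy: MethylationCallPolicy = field(
        default_factory=MethylationCallPolicy)
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("manifest", "variants", "annotation", "chrom_sizes"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        for name in ("spikein", "centromeres"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["filter_policy"]["het_band"] = list(self.filter_policy.het_band)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        fp = d.pop("filter_policy", {})
        if "het_band" in fp:
            fp["het_band"] = tuple(fp["het_band"])
        mp = d.pop("methylation_policy", {})
        return cls(filter_policy=FilterPolicy(**fp),
                   methylation_policy=MethylationCallPolicy(**mp), **d)


@dataclass
class RunReport:
    """Per-stage record counts and a parameter echo for one run."""

    version: str
    seed: int
    stages: List[str]
    counts: Dict[str, object]
    parameters: Dict[str, object]

    def to_json(self, path) -> None:
        mio.write_json(asdict(self), path)

    def sha256(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def _config_hash(obj: dict) -> str:
    return hashlib.sha1(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


def make_fixture(config: SimulationConfig, out_dir) -> RunConfig:
    """Write a full synthetic input set plus truth tables to ``out_dir``.

    Emits the reference FASTA, annotation (BED + GFF3), centromere and
    chromosome-size tables, a sample manifest, the candidate-variant
    VCF/TSV over the progenitor and all genomically sequenced plants,
    one cytosine report per bisulfite sample, a spike-in control table,
    truth tables, the simulation config, and a ready-to-run pipeline
    config (run.yaml).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config": _config_hash(config.to_dict())}

    genome, annotation = generate_genome(config)
    truth, samples = simulate_pedigree(config, genome, annotation)
    candidates = simulate_variant_counts(truth, config)
    cytosines, spikein = simulate_bisulfite_counts(truth, config)

    mio.write_fasta(genome, out / "genome.fa")
    mio.write_chrom_sizes(genome.chrom_sizes, out / "chrom.sizes")
    mio.write_annotation_bed(annotation, out / "annotation.bed", meta)
    mio.write_annotation_gff3(annotation, out / "annotation.gff3", meta)
    cen = pd.DataFrame(
        [{"chrom": c, "start": s, "end": e}
         for c, (s, e) in genome.centromeres.items()])
    mio.write_tsv(cen, out / "centromeres.tsv", meta)

    gsample_ids = [s.sample_id for s in truth.genomic_samples]
    mio.write_vcf(candidates, gsample_ids, out / "variants.vcf",
                  genome.chrom_sizes, meta)
    mio.write_variants_tsv(candidates, out / "variants.tsv", meta)

    cyt_dir = out / "cytosine"
    cyt_dir.mkdir(exist_ok=True)
    files = {}
    for s in truth.bisulfite_samples:
        path = cyt_dir / f"{s.sample_id}.CX_report.txt"
        mio.write_cytosine_report(cytosines, s.sample_id, path, meta)
        files[s.sample_id] = str(path.relative_to(out))
    mio.write_tsv(spikein, out / "spikein.tsv", meta)

    gframe = pd.DataFrame([vars(s) for s in truth.genomic_samples])
    gframe["assay"] = "genomic"
    bframe = pd.DataFrame([vars(s) for s in truth.bisulfite_samples])
    bframe["assay"] = "bisulfite"
    frame = pd.concat([gframe, bframe], ignore_index=True)
    frame["file"] = frame["sample_id"].map(files).fillna("")
    frame.loc[frame["assay"] == "genomic", "file"] = ""
    with open(out / "manifest.tsv", "w") as fh:
        fh.write("".join(f"# {k}={v}\n" for k, v in sorted(meta.items())))
        frame.to_csv(fh, sep="\t", index=False)

    mio.write_tsv(truth.mutations, out / "truth_mutations.tsv", meta)
    mio.write_tsv(truth.genotypes, out / "truth_genotypes.tsv", meta)
    mio.write_tsv(truth.epimutations, out / "truth_epimutations.tsv", meta)
    with open(out / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    run_cfg = RunConfig(
        out_dir=str(out / "results"), manifest=str(out / "manifest.tsv"),
        variants=str(out / "variants.vcf"),
        annotation=str(out / "annotation.bed"),
        chrom_sizes=str(out / "chrom.sizes"),
        spikein=str(out / "spikein.tsv"),
        centromeres=str(out / "centromeres.tsv"),
        seed=config.seed, generations=config.generations,
        gc_content=config.gc_content,
    )
    run_cfg.to_yaml(out / "run.yaml")
    return run_cfg


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute all stages and write outputs under ``cfg.out_dir``."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20),
                        format="%(name)s: %(message)s")
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: Dict[str, object] = {}
    stages_run: List[str] = []
    base = Path(cfg.manifest).parent

    manifest = mio.read_manifest(cfg.manifest)
    chrom_sizes = mio.read_chrom_sizes(cfg.chrom_sizes)
    annotation = mio.read_annotation_bed(cfg.annotation, chrom_sizes)
    genome_length = sum(chrom_sizes.values())
    pol = cfg.methylation_policy

    # ---- variants -------------------------------------------------------
    stage = "variants"
    try:
        vpath = Path(cfg.variants)
        candidates = (mio.read_vcf(vpath) if vpath.suffix == ".vcf"
                      else mio.read_variants_tsv(vpath))
        gmask = manifest["assay"] == "genomic" if "assay" in manifest else (
            slice(None))
        gsamples = mio.manifest_samples(
            manifest[gmask].drop(columns=["assay", "file"], errors="ignore"))
        mutations = filter_variants(candidates, gsamples, cfg.filter_policy)
        counts["candidate_variants"] = len(candidates)
        counts["called_mutations"] = len(mutations)
        mio.write_tsv(mutations, out / "mutations.tsv")
        rates = lineage_rates(mutations, gsamples, cfg.generations)
        cmp_table = rate_comparison_table(rates)
        summary = {
            "n_candidates": len(candidates),
            "n_mutations": len(mutations),
            "by_class": mutations["vclass"].value_counts().to_dict(),
            "by_titv": mutations["titv"].value_counts().to_dict(),
        }
        try:
            summary["titv_raw"] = titv_ratio(mutations)
            summary["titv_normalized"] = titv_ratio(
                mutations, genome_length, cfg.gc_content, normalized=True)
        except UndefinedTiTvError:
            summary["titv_raw"] = summary["titv_normalized"] = None
        mio.write_tsv(rates, out / "lineage_rates.tsv")
        mio.write_tsv(cmp_table, out / "rate_comparison.tsv")
        mio.write_json(summary, out / "mutation_summary.json")
        stages_run.append(stage)
    except Exception as e:  # noqa: BLE001 - stage-tagged abort
        raise PipelineError(stage, e) from e

    # ---- methylome loading & site calling -------------------------------
    stage = "methylated_sites"
    try:
        bmask = manifest["assay"] == "bisulfite" if "assay" in manifest else (
            manifest["file"] != "")
        bis = manifest[bmask]
        paths = {r.sample_id: base / r.file for r in bis.itertuples(index=False)}
        records = mio.merge_cytosine_reports(paths)
        parental = list(bis.loc[bis["role"] == "parental", "sample_id"])
        derived = list(bis.loc[bis["role"] == "derived", "sample_id"])
        offspring = bis[bis["role"] == "post_stress"]
        treatments = dict(zip(bis["sample_id"], bis["treatment"]))
        meth_summary: Dict[str, object] = {}
        if cfg.spikein:
            spike = pd.read_csv(cfg.spikein, sep="\t", comment="#")
            meth_summary["conversion_rate"] = estimate_conversion_rate(spike)
        evaluable, analyzable = site_universe(records, parental, derived, pol)
        counts["cytosine_positions"] = len(records)
        counts["evaluable_positions"] = int(evaluable.sum())
        counts["analyzable_positions"] = int(analyzable.sum())
        stages_run.append(stage)
    except Exception as e:
        raise PipelineError(stage, e) from e

    # ---- parental removal ----------------------------------------------
    stage = "parental_removal"
    try:
        site_mask, n_removed = remove_parental_dmps(records, parental, pol,
                                                    analyzable)
        counts["parental_dmps_removed"] = n_removed
        counts["tested_positions"] = int(site_mask.sum())
        stages_run.append(stage)
    except Exception as e:
        raise PipelineError(stage, e) from e

    # ---- DMPs -----------------------------------------------------------
    stage = "dmps"
    try:
        dmps = call_dmps(records, parental, derived, pol, site_mask)
        counts["dmp_calls"] = len(dmps)
        mio.write_tsv(dmps.drop(columns=["site_idx"]), out / "dmps.tsv")
        if len(dmps):
            mio.write_dmps_bed(dmps, out / "dmps.bed")
        summary = dmp_summary(dmps, treatments)
        mio.write_tsv(summary, out / "dmp_summary.tsv")
        meth_summary["dmp_calls"] = len(dmps)
        meth_summary["dmp_positions_by_treatment"] = {
            r.treatment: int(r.n_positions)
            for r in summary.itertuples(index=False) if r.context == "CG"
        }
        stages_run.append(stage)
    except Exception as e:
        raise PipelineError(stage, e) from e

    # ---- DMRs -----------------------------------------------------------
    stage = "dmrs"
    try:
        dmrs = call_dmrs(dmps, records, parental, derived, pol)
        counts["dmr_calls"] = len(dmrs)
        mio.write_tsv(dmrs, out / "dmrs.tsv")
        if len(dmrs):
            mio.write_dmrs_bed(dmrs, out / "dmrs.bed")
        stages_run.append(stage)
    except Exception as e:
        raise PipelineError(stage, e) from e

    # ---- retention ------------------------------------------------------
    stage = "retention"
    try:
        retention = {}
        for r in offspring.itertuples(index=False):
            carrier = next((d for d in derived
                            if treatments[d] == r.treatment
                            and bis.set_index("sample_id").loc[d, "lineage_id"]
                            == r.lineage_id), None)
            if carrier is None:
                continue
            kept, lost, frac = retention_analysis(
                dmps, records, parental, carrier, r.sample_id, pol, site_mask)
            retention[r.sample_id] = {
                "carrier": carrier, "retained": kept, "not_retained": lost,
                "fraction": None if np.isnan(frac) else frac,
            }
        counts["retention"] = retention
        meth_summary["retention"] = retention
        stages_run.append(stage)
    except Exception as e:
        raise PipelineError(stage, e) from e

    # ---- clustering -----------------------------------------------------
    stage = "clustering"
    try:
        cg_dmps = dmps[dmps["context"] == "CG"]
        if len(cg_dmps) and len(parental) + len(derived) >= 2:
            _, labels, newick = cluster_samples(
                records, cg_dmps["site_idx"].unique(),
                parental + derived, cfg.cluster_sites, cfg.seed)
            (out / "dendrogram.nwk").write_text(newick + "\n")
            counts["clustered_samples"] = len(labels)
        stages_run.append(stage)
    except Exception as e:
        raise PipelineError(stage, e) from e

    # ---- distribution ---------------------------------------------------
    stage = "distribution"
    try:
        is_cg = (records["context"] == "CG").to_numpy()
        meth_any = analyzable & is_cg
        universe = records.loc[meth_any, ["chrom", "pos"]]
        by_treatment = {}
        for t in sorted(set(treatments.values())):
            t_samples = [s for s in derived if treatments[s] == t]
            sub = cg_dmps[cg_dmps["sample"].isin(t_samples)]
            pos = sub[["chrom", "pos"]].drop_duplicates()
            by_treatment[t] = pos
            frac = regional_dmp_fraction(pos, universe, annotation)
            mio.write_tsv(frac, out / f"regional_fractions_{t}.tsv")
        if all(len(p) for p in by_treatment.values()) and len(by_treatment) == 2:
            gres = genic_enrichment_test(by_treatment, annotation)
            mio.write_json(gres, out / "gtest.json")
            counts["gtest_p"] = gres["p_value"]
        dmp_pos = cg_dmps[["chrom", "pos"]].drop_duplicates()
        ndmp_pos = universe.merge(dmp_pos, how="left", indicator=True)
        ndmp_pos = ndmp_pos[ndmp_pos["_merge"] == "left_only"][["chrom", "pos"]]
        centromeres = None
        if cfg.centromeres:
            cen = pd.read_csv(cfg.centromeres, sep="\t", comment="#")
            centromeres = {r.chrom: (int(r.start), int(r.end))
                           for r in cen.itertuples(index=False)}
        profile = chromosome_profile(dmp_pos, ndmp_pos, chrom_sizes,
                                     centromeres=centromeres)
        mio.write_tsv(profile, out / "chromosome_profile.tsv")
        stages_run.append(stage)
    except Exception as e:
        raise PipelineError(stage, e) from e

    mio.write_json(meth_summary, out / "methylation_summary.json")
    report = RunReport(
        version=_pkg_version(), seed=cfg.seed, stages=stages_run,
        counts=counts,
        parameters={"filter_policy": asdict(cfg.filter_policy),
                    "methylation_policy": asdict(cfg.methylation_policy),
                    "generations": cfg.generations,
                    "gc_content": cfg.gc_content},
    )
    report.to_json(out / "run_report.json")
    return report


def _pkg_version() -> str:
    from . import __version__
    return __version__
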