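"""Read-count emulation for genomic and bisulfite sequencing.

No reads are simulated — only the per-site count summaries the analysis
consumes: per-sample (alt, depth) pairs for variant candidates and
per-cytosine (methylated, unmethylated) pairs for methylomes, with
Poisson depth and binomial allele/methylation sampling.

Wide-table convention used throughout the package: one row per site,
plus two columns per sample named ``{sample}:alt``/``{sample}:dp`` for
variants and ``{sample}:meth``/``{sample}:unmeth`` for cytosines.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .pedigree import TruthTable

_ALL = "ACGT"


def simulate_variant_counts(
    truth: TruthTable,
    config: SimulationConfig,
    samples: Optional[List[str]] = None,
) -> pd.DataFrame:
    """Per-sample allele-support counts for every true variant.

    Depth is Poisson(genomic coverage); alt reads are Binomial(depth,
    1 - error) for homozygous carriers, Binomial(depth, 1/2) for
    heterozygotes and Binomial(depth, error) for non-carriers.  False
    candidates (alignment/sequencing artefacts) are injected at
    ``false_candidate_rate`` per genome site with low-level alt support
    in a random subset of samples.
    """
    rng = config.rng(3)
    if samples is None:
        samples = [s.sample_id for s in truth.genomic_samples]
    eps = config.seq_error_rate
    muts = truth.mutations.reset_index(drop=True)
    zyg = {(r.sample_id, r.mut_id): r.zygosity
           for r in truth.genotypes.itertuples(index=False)}

    out = muts[["chrom", "pos", "ref", "alt", "vclass"]].copy()
    n = len(out)
    for s in samples:
        depth = rng.poisson(config.genomic_coverage, n)
        p = np.full(n, eps)
        for i, mid in enumerate(muts["mut_id"]):
            z = zyg.get((s, mid))
            if z == "homozygous":
                p[i] = 1.0 - eps
            elif z == "heterozygous":
                p[i] = 0.5
        out[f"{s}:alt"] = rng.binomial(depth, p)
        out[f"{s}:dp"] = depth

    false_rows = _false_candidates(rng, truth, config, samples)
    if false_rows is not None and len(false_rows):
        out = pd.concat([out, false_rows], ignore_index=True)
    out = out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return out


def _false_candidates(rng, truth, config, samples):
    chrom_sizes = (truth.sites.groupby("chrom")["pos"].max().to_dict()
                   if len(truth.sites) else {})
    if not chrom_sizes:
        return None
    total = sum(chrom_sizes.values())
    k = rng.poisson(config.false_candidate_rate * total)
    rows = []
    names = list(chrom_sizes)
    for _ in range(k):
        chrom = names[int(rng.integers(len(names)))]
        pos = int(rng.integers(1, chrom_sizes[chrom] + 1))
        ref = _ALL[int(rng.integers(4))]
        alt = _ALL[int(rng.integers(4))]
        while alt == ref:
            alt = _ALL[int(rng.integers(4))]
        row = {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
               "vclass": "SBS"}
        affected = rng.random(len(samples)) < 0.3
        for s, a in zip(samples, affected):
            depth = int(rng.poisson(config.genomic_coverage))
            frac = float(rng.uniform(0.02, 0.15)) if a else config.seq_error_rate
            row[f"{s}:alt"] = int(rng.binomial(depth, frac))
            row[f"{s}:dp"] = depth
        rows.append(row)
    return pd.DataFrame(rows) if rows else None


def simulate_bisulfite_counts(
    truth: TruthTable,
    config: SimulationConfig,
    samples: Optional[List[str]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cytosine methylated/unmethylated read counts per sample.

    Depth is Poisson(bisulfite coverage).  A methylated site emits
    methylated reads at its per-site level (Beta-distributed, stable
    across samples); an unmethylated site emits them only through
    bisulfite non-conversion.  Also returns an unmethylated spike-in
    control table (lambda-phage stand-in) for conversion-rate estimation.
    """
    rng = config.rng(4)
    if samples is None:
        samples = [s.sample_id for s in truth.bisulfite_samples]
    sites = truth.sites
    n = len(sites)
    out = sites[["chrom", "pos", "strand", "context", "tri"]].copy()
    level = truth.methylation_level
    for s in samples:
        state = truth.meth_states[s]
        depth = rng.poisson(config.bisulfite_coverage, n)
        p = np.where(state, level, config.nonconversion_rate)
        meth = rng.binomial(depth, p)
        out[f"{s}:meth"] = meth
        out[f"{s}:unmeth"] = depth - meth

    m = config.spikein_sites
    depth = rng.poisson(config.bisulfite_coverage, m)
    meth = rng.binomial(depth, config.nonconversion_rate)
    spike = pd.DataFrame({
        "chrom": "lambda", "pos": np.arange(1, m + 1), "strand": "+",
        "context": rng.choice(["CG", "CHG", "CHH"], m),
        "tri": "CNN",
        "spikein:meth": meth, "spikein:unmeth": depth - meth,
    })
    return out, spike
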