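"""Methylated-site, DMP and DMR calling against two parental methylomes.

The workflow mirrors a two-parent mutation-accumulation methylome design:

1. restrict to cytosines with 3-200 reads in every sample (evaluable)
   that are methylated (>= 3 methylated reads) in at least one sample
   (analyzable);
2. remove positions already differing between the two first-generation
   parental plants at a relaxed FDR of 10%;
3. for each derived (tenth-generation) sample, Fisher-test each
   remaining position against both parents, take the worse of the two
   p-values, Bonferroni-correct by the number of pairwise tests in the
   family (2 x number of derived samples), and control FDR at 5% by
   Benjamini-Hochberg over all (position, sample) units; a DMP must
   also sit on the same side of both parental methylation proportions
   (gain or loss);
4. consolidate each sample's DMPs into regions (DMRs): chain positions
   less than 50 bp apart, discard runs with fewer than five DMPs or a
   span under 10 bp, and re-test region-level count tables (member-DMP
   averages) against both parents with the same correction scheme.

Cytosine tables are wide pandas frames: chrom, pos (1-based), strand,
context plus ``{sample}:meth``/``{sample}:unmeth`` columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from ._stats import bh_adjust, fisher_two_sided, fisher_vector

logger = logging.getLogger(__name__)


@dataclass
class MethylationCallPolicy:
    """Depth gates and FDR levels for methylation calling."""

    min_depth: int = 3
    max_depth: int = 200
    min_meth_reads: int = 3
    parental_fdr: float = 0.10
    dmp_fdr: float = 0.05
    # DMR consolidation
    dmr_gap: int = 50          # chain DMPs strictly closer than this
    dmr_min_dmps: int = 5
    dmr_min_span: int = 10     # 1-based inclusive width
    dmr_fdr: float = 0.05
    region_aggregate: str = "mean"  # or "sum"
    # retained = re-significant DMP in the offspring (vs plain status match)
    retention_requires_significance: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_depth <= self.max_depth:
            raise ValueError("need 0 < min_depth <= max_depth")
        for f in (self.parental_fdr, self.dmp_fdr, self.dmr_fdr):
            if not 0 <= f < 1:
                raise ValueError("FDRs must lie in [0, 1)")
        if self.region_aggregate not in ("mean", "sum"):
            raise ValueError("region_aggregate must be 'mean' or 'sum'")


def _counts(records: pd.DataFrame, sample: str) -> Tuple[np.ndarray, np.ndarray]:
    try:
        meth = records[f"{sample}:meth"].to_numpy(np.int64)
        unmeth = records[f"{sample}:unmeth"].to_numpy(np.int64)
    except KeyError as e:
        raise ValueError(f"sample {sample!r} absent from cytosine table") from e
    return meth, unmeth


def table_samples(records: pd.DataFrame) -> List[str]:
    """Sample ids present in a wide cytosine table."""
    return [c[:-5] for c in records.columns if c.endswith(":meth")]


def estimate_conversion_rate(spikein: pd.DataFrame) -> float:
    """Bisulfite conversion rate from an unmethylated spike-in genome.

    Every cytosine read-base in the spike-in should read converted
    (unmethylated); the estimate is converted / total read-bases.
    """
    meth_cols = [c for c in spikein.columns if c.endswith(":meth")]
    unmeth_cols = [c for c in spikein.columns if c.endswith(":unmeth")]
    meth = spikein[meth_cols].to_numpy().sum()
    unmeth = spikein[unmeth_cols].to_numpy().sum()
    total = meth + unmeth
    if total == 0:
        raise ValueError("spike-in table has zero coverage")
    return unmeth / total


def call_methylated_sites(
    records: pd.DataFrame,
    policy: MethylationCallPolicy = MethylationCallPolicy(),
    samples: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-sample methylation status: methylated / unmethylated / not_evaluable.

    A site is evaluable in a sample when its depth lies in
    [min_depth, max_depth]; it is methylated when additionally at least
    ``min_meth_reads`` methylated reads support it.
    """
    samples = list(samples or table_samples(records))
    out = pd.DataFrame(index=records.index)
    for s in samples:
        meth, unmeth = _counts(records, s)
        depth = meth + unmeth
        evaluable = (depth >= policy.min_depth) & (depth <= policy.max_depth)
        status = np.where(~evaluable, "not_evaluable",
                          np.where(meth >= policy.min_meth_reads,
                                   "methylated", "unmethylated"))
        out[s] = status
    return out


def site_universe(
    records: pd.DataFrame,
    parental: Sequence[str],
    derived: Sequence[str],
    policy: MethylationCallPolicy = MethylationCallPolicy(),
) -> Tuple[np.ndarray, np.ndarray]:
    """(evaluable, analyzable) boolean masks over the cytosine table.

    Evaluable: depth within [min, max] in every listed sample.
    Analyzable: evaluable and methylated in at least one sample.
    """
    if len(parental) < 2 or len(derived) < 1:
        raise ValueError("need >= 2 parental and >= 1 derived samples")
    samples = list(parental) + list(derived)
    evaluable = np.ones(len(records), dtype=bool)
    any_meth = np.zeros(len(records), dtype=bool)
    for s in samples:
        meth, unmeth = _counts(records, s)
        depth = meth + unmeth
        evaluable &= (depth >= policy.min_depth) & (depth <= policy.max_depth)
        any_meth |= meth >= policy.min_meth_reads
    return evaluable, evaluable & any_meth


def pairwise_fisher(
    counts_a: Tuple[int, int], counts_b: Tuple[int, int]
) -> float:
    """Two-sided Fisher exact p for one site between two samples.

    ``counts_*`` are (methylated, unmethylated) read counts.
    """
    return fisher_two_sided(counts_a[0], counts_a[1], counts_b[0], counts_b[1])


def remove_parental_dmps(
    records: pd.DataFrame,
    parental: Sequence[str],
    policy: MethylationCallPolicy = MethylationCallPolicy(),
    analyzable: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, int]:
    """Drop positions already differing between the two parental plants.

    Fisher per site between the parents, BH over analyzable sites at the
    relaxed parental FDR; returns (mask of retained analyzable sites,
    number removed).
    """
    if len(parental) != 2:
        raise ValueError("exactly two parental samples required")
    if analyzable is None:
        analyzable = np.ones(len(records), dtype=bool)
    idx = np.nonzero(analyzable)[0]
    if len(idx) == 0:
        return analyzable.copy(), 0
    m1, u1 = _counts(records, parental[0])
    m2, u2 = _counts(records, parental[1])
    p = fisher_vector(m1[idx], u1[idx], m2[idx], u2[idx])
    q = bh_adjust(p)
    removed = q <= policy.parental_fdr
    keep = analyzable.copy()
    keep[idx[removed]] = False
    logger.info("parental filter: %d of %d analyzable sites removed",
                int(removed.sum()), len(idx))
    return keep, int(removed.sum())


def call_dmps(
    records: pd.DataFrame,
    parental: Sequence[str],
    derived: Sequence[str],
    policy: MethylationCallPolicy = MethylationCallPolicy(),
    site_mask: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Call differentially methylated positions per derived sample.

    Returns one row per significant (site, sample) unit with direction
    (gain/loss relative to both parents), Bonferroni-corrected p and BH
    q-value.
    """
    if len(parental) != 2:
        raise ValueError("exactly two parental samples required")
    if site_mask is None:
        site_mask = np.ones(len(records), dtype=bool)
    idx = np.nonzero(site_mask)[0]
    n_tests = 2 * len(derived)  # pairwise-test family per site
    m1, u1 = _counts(records, parental[0])
    m2, u2 = _counts(records, parental[1])
    with np.errstate(invalid="ignore"):
        prop1 = m1 / np.maximum(m1 + u1, 1)
        prop2 = m2 / np.maximum(m2 + u2, 1)

    units = []
    for s in derived:
        md, ud = _counts(records, s)
        p1 = fisher_vector(md[idx], ud[idx], m1[idx], u1[idx])
        p2 = fisher_vector(md[idx], ud[idx], m2[idx], u2[idx])
        p = np.maximum(p1, p2)  # must differ from BOTH parents
        p_bonf = np.minimum(p * n_tests, 1.0)
        prop_d = md[idx] / np.maximum(md[idx] + ud[idx], 1)
        gain = (prop_d > prop1[idx]) & (prop_d > prop2[idx])
        loss = (prop_d < prop1[idx]) & (prop_d < prop2[idx])
        units.append(pd.DataFrame({
            "site_idx": idx, "sample": s, "p_bonf": p_bonf,
            "direction": np.where(gain, "gain", np.where(loss, "loss", "none")),
        }))
    all_units = pd.concat(units, ignore_index=True)
    all_units["q"] = bh_adjust(all_units["p_bonf"].to_numpy())
    sig = (all_units["q"] <= policy.dmp_fdr) & (all_units["direction"] != "none")
    calls = all_units[sig].copy()
    site_cols = records[["chrom", "pos", "strand", "context"]]
    calls = calls.join(site_cols, on="site_idx")
    calls = calls[["chrom", "pos", "strand", "context", "sample",
                   "direction", "p_bonf", "q", "site_idx"]]
    calls = calls.sort_values(["sample", "chrom", "pos", "strand"],
                              kind="mergesort").reset_index(drop=True)
    logger.info("DMP calling: %d calls across %d derived samples "
                "(%d candidate sites)", len(calls), len(derived), len(idx))
    return calls


def dmp_summary(dmps: pd.DataFrame, treatments: Dict[str, str]) -> pd.DataFrame:
    """Per-treatment DMP position counts (union over samples), per context."""
    if dmps.empty:
        return pd.DataFrame(columns=["treatment", "context", "n_positions"])
    d = dmps.copy()
    d["treatment"] = d["sample"].map(treatments)
    rows = []
    for (t, c), sub in d.groupby(["treatment", "context"]):
        n = sub[["chrom", "pos", "strand"]].drop_duplicates().shape[0]
        rows.append({"treatment": t, "context": c, "n_positions": n})
    return pd.DataFrame(rows)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(np.int64)


def call_dmrs(
    dmps: pd.DataFrame,
    records: pd.DataFrame,
    parental: Sequence[str],
    derived: Sequence[str],
    policy: MethylationCallPolicy = MethylationCallPolicy(),
) -> pd.DataFrame:
    """Consolidate each sample's DMPs into differentially methylated regions.

    Chain a sample's DMPs when consecutive positions are < ``dmr_gap``
    bp apart; keep runs with >= ``dmr_min_dmps`` members spanning >=
    ``dmr_min_span`` bp; test the aggregated (mean, rounded half-up, or
    summed) member counts against both parents; Bonferroni by the
    pairwise-test family then BH at the DMR FDR.
    """
    m1, u1 = _counts(records, parental[0])
    m2, u2 = _counts(records, parental[1])
    n_tests = 2 * len(derived)
    candidates = []
    for s in derived:
        sub = dmps[dmps["sample"] == s]
        if sub.empty:
            continue
        md, ud = _counts(records, s)
        for chrom, block in sub.groupby("chrom"):
            block = block.sort_values(["pos", "strand"], kind="mergesort")
            pos = block["pos"].to_numpy()
            site_idx = block["site_idx"].to_numpy()
            breaks = np.nonzero(np.diff(pos) >= policy.dmr_gap)[0] + 1
            for run in np.split(np.arange(len(pos)), breaks):
                run_pos = pos[run]
                span = int(run_pos[-1] - run_pos[0] + 1)
                if len(run) < policy.dmr_min_dmps or span < policy.dmr_min_span:
                    continue
                members = site_idx[run]
                agg = (np.mean if policy.region_aggregate == "mean" else np.sum)
                tbl = [agg(x[members]) for x in (md, ud, m1, u1, m2, u2)]
                if policy.region_aggregate == "mean":
                    tbl = list(_round_half_up(np.asarray(tbl, dtype=float)))
                p1 = fisher_two_sided(tbl[0], tbl[1], tbl[2], tbl[3])
                p2 = fisher_two_sided(tbl[0], tbl[1], tbl[4], tbl[5])
                p_bonf = min(max(p1, p2) * n_tests, 1.0)
                candidates.append({
                    "chrom": chrom, "start": int(run_pos[0]),
                    "end": int(run_pos[-1]), "sample": s,
                    "n_dmps": len(run), "span": span, "p_bonf": p_bonf,
                })
    out = pd.DataFrame(candidates,
                       columns=["chrom", "start", "end", "sample", "n_dmps",
                                "span", "p_bonf"])
    if out.empty:
        out["q"] = pd.Series(dtype=float)
        return out
    out["q"] = bh_adjust(out["p_bonf"].to_numpy())
    out = out[out["q"] <= policy.dmr_fdr]
    out = out.sort_values(["sample", "chrom", "start"],
                          kind="mergesort").reset_index(drop=True)
    return out


def retention_analysis(
    dmps: pd.DataFrame,
    records: pd.DataFrame,
    parental: Sequence[str],
    carrier: str,
    offspring: str,
    policy: MethylationCallPolicy = MethylationCallPolicy(),
    site_mask: Optional[np.ndarray] = None,
) -> Tuple[int, int, float]:
    """Fraction of a sample's DMPs retained in its selfed offspring.

    A carrier DMP is retained when the offspring is itself
    DMP-significant versus both parents at that position with the same
    direction (default), or — with ``retention_requires_significance``
    off — when the offspring's methylated/unmethylated status matches
    the carrier's.  Positions not evaluable in the offspring are
    excluded from the denominator.
    """
    if f"{offspring}:meth" not in records.columns:
        raise ValueError(f"offspring sample {offspring!r} absent from table")
    carrier_dmps = dmps[dmps["sample"] == carrier]
    if carrier_dmps.empty:
        return 0, 0, float("nan")
    mo, uo = _counts(records, offspring)
    depth = mo + uo
    evaluable = (depth >= policy.min_depth) & (depth <= policy.max_depth)
    sites = carrier_dmps["site_idx"].to_numpy()
    ok = evaluable[sites]
    eligible = carrier_dmps[ok]
    if eligible.empty:
        return 0, 0, float("nan")

    if policy.retention_requires_significance:
        off_calls = call_dmps(records, parental, [offspring], policy,
                              site_mask=site_mask)
        key = off_calls.set_index("site_idx")["direction"]
        off_dir = eligible["site_idx"].map(key)
        retained = (off_dir == eligible["direction"]).sum()
    else:
        mc, uc = _counts(records, carrier)
        meth_off = mo >= policy.min_meth_reads
        meth_car = mc >= policy.min_meth_reads
        s = eligible["site_idx"].to_numpy()
        retained = int((meth_off[s] == meth_car[s]).sum())
    retained = int(retained)
    not_retained = len(eligible) - retained
    return retained, not_retained, retained / len(eligible)


def cluster_samples(
    records: pd.DataFrame,
    dmp_sites: Sequence[int],
    samples: Sequence[str],
    n_sites: int = 20_000,
    seed: int = 0,
) -> Tuple[np.ndarray, List[str], str]:
    """Hierarchically cluster samples on methylation proportions at DMPs.

    Draws ``n_sites`` DMP positions at random (seeded; all of them if
    fewer are available), drops sites without depth in every sample,
    and clusters with Euclidean distance and average linkage.  Returns
    (scipy linkage matrix, sample labels, newick string).
    """
    samples = list(samples)
    if len(samples) < 2:
        raise ValueError("need >= 2 samples to cluster")
    sites = np.asarray(sorted(set(dmp_sites)), dtype=np.int64)
    depth_ok = np.ones(len(sites), dtype=bool)
    props = []
    for s in samples:
        meth, unmeth = _counts(records, s)
        depth = (meth + unmeth)[sites]
        depth_ok &= depth > 0
        with np.errstate(invalid="ignore"):
            props.append(meth[sites] / np.maximum(depth, 1))
    sites_ok = np.nonzero(depth_ok)[0]
    if len(sites_ok) == 0:
        raise ValueError("no DMP sites with depth in every sample")
    rng = np.random.default_rng(seed)
    if len(sites_ok) > n_sites:
        chosen = np.sort(rng.choice(sites_ok, size=n_sites, replace=False))
    else:
        if len(sites_ok) < n_sites:
            logger.info("only %d usable DMP sites (< %d requested); using all",
                        len(sites_ok), n_sites)
        chosen = sites_ok
    X = np.stack([p[chosen] for p in props])
    Z = hierarchy.linkage(X, method="average", metric="euclidean")
    return Z, samples, linkage_to_newick(Z, samples)


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def render(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        kids = ",".join(render(c, node.dist) for c in
                        (node.get_left(), node.get_right()))
        return f"({kids}):{length:.6g}"

    inner = ",".join(render(c, tree.dist) for c in
                     (tree.get_left(), tree.get_right()))
    return f"({inner});"
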