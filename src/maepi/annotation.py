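"""Genomic-feature assignment and distribution statistics for DMPs.

Positions are assigned to exactly one category by the fixed priority
CDS > UTR > intron > ncRNA > pseudogene > TE > intergenic; anything not
covered by a feature is intergenic.  Regional fractions express DMPs per
methylated site within each category; the G-test (likelihood-ratio
chi-square, 1 df, no continuity correction) contrasts genic vs nongenic
DMP counts between treatments.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .genome import AnnotationSet, CATEGORIES, GENIC_CATEGORIES

PRIORITY = ("CDS", "UTR", "intron", "ncRNA", "pseudogene", "TE")


def annotate_positions(
    positions: pd.DataFrame,
    annotation: AnnotationSet,
    genic_categories: frozenset = GENIC_CATEGORIES,
) -> pd.DataFrame:
    """Assign each (chrom, pos) row a single feature category.

    ``positions`` needs chrom and 1-based pos columns.  Returns a copy
    with ``category`` and boolean ``genic`` columns appended.
    """
    unknown = set(positions["chrom"]) - set(annotation.chrom_sizes)
    if unknown:
        raise ValueError(f"positions on unknown chromosome(s): {sorted(unknown)}")
    out = positions.copy()
    category = np.full(len(out), "intergenic", dtype=object)
    pos0_all = out["pos"].to_numpy() - 1
    chrom_all = out["chrom"].to_numpy()
    iv = annotation.intervals
    for chrom in pd.unique(chrom_all):
        sel = chrom_all == chrom
        pos0 = pos0_all[sel]
        assigned = np.zeros(sel.sum(), dtype=bool)
        chrom_iv = iv[iv["chrom"] == chrom]
        for cat in PRIORITY:
            block = chrom_iv[chrom_iv["category"] == cat]
            if block.empty:
                continue
            starts = block["start"].to_numpy()
            order = np.argsort(starts)
            starts = starts[order]
            ends = block["end"].to_numpy()[order]
            j = np.searchsorted(starts, pos0, side="right") - 1
            hit = (j >= 0) & (pos0 < ends[np.clip(j, 0, None)])
            take = hit & ~assigned
            if take.any():
                idx = np.nonzero(sel)[0][take]
                category[idx] = cat
                assigned |= hit
    out["category"] = category
    out["genic"] = out["category"].isin(genic_categories)
    return out


def regional_dmp_fraction(
    dmp_positions: pd.DataFrame,
    universe_positions: pd.DataFrame,
    annotation: AnnotationSet,
) -> pd.DataFrame:
    """DMPs per methylated site in each feature category.

    ``universe_positions`` is the methylated-site universe (e.g. all
    methylated CG positions); fractions are DMP count / universe count
    per category, NaN where a category has an empty universe.
    """
    dmp_cat = annotate_positions(dmp_positions, annotation)["category"]
    uni_cat = annotate_positions(universe_positions, annotation)["category"]
    rows = []
    for cat in CATEGORIES:
        n_dmp = int((dmp_cat == cat).sum())
        n_uni = int((uni_cat == cat).sum())
        frac = n_dmp / n_uni if n_uni else float("nan")
        rows.append({"category": cat, "n_dmps": n_dmp, "n_universe": n_uni,
                     "fraction": frac})
    return pd.DataFrame(rows)


def gtest_2x2(table) -> Tuple[float, float]:
    """Log-likelihood-ratio (G) test of independence on a 2x2 table.

    G = 2 * sum O*ln(O/E) with expectations from the margins; the
    p-value comes from chi-square with 1 df, no continuity correction.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be >= 0")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero margin: G-test undefined")
    expected = np.outer(row, col) / obs.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g = 2.0 * terms.sum()
    return float(g), float(chi2.sf(g, df=1))


def genic_enrichment_test(
    dmps_by_treatment: Dict[str, pd.DataFrame],
    annotation: AnnotationSet,
    genic_categories: frozenset = GENIC_CATEGORIES,
) -> Dict[str, object]:
    """G-test of genic-vs-nongenic DMP counts between two treatments."""
    counts = {}
    for t, pos in dmps_by_treatment.items():
        ann = annotate_positions(pos, annotation, genic_categories)
        counts[t] = (int(ann["genic"].sum()), int((~ann["genic"]).sum()))
    (t1, (g1, n1)), (t2, (g2, n2)) = sorted(counts.items())
    g, p = gtest_2x2([[g1, n1], [g2, n2]])
    return {"treatments": [t1, t2], "table": [[g1, n1], [g2, n2]],
            "G": g, "p_value": p}


def chromosome_profile(
    dmp_positions: pd.DataFrame,
    ndmp_positions: pd.DataFrame,
    chrom_sizes: Dict[str, int],
    bin_size: Optional[int] = None,
    centromeres: Optional[Dict[str, Tuple[int, int]]] = None,
) -> pd.DataFrame:
    """Binned, per-chromosome max-normalised densities of DMPs and N-DMPs.

    Each class (changed positions vs unchanged methylated positions) is
    normalised so its per-chromosome maximum equals 1; all-empty classes
    stay zero and are flagged.  Default bin size is chromosome length/50.
    """
    if bin_size is not None and bin_size <= 0:
        raise ValueError("bin size must be > 0")
    rows = []
    for chrom, size in chrom_sizes.items():
        bs = bin_size or max(size // 50, 1)
        edges = np.arange(0, size + bs, bs)
        n_bins = len(edges) - 1
        series = {}
        empty = {}
        for name, frame in (("dmp", dmp_positions), ("ndmp", ndmp_positions)):
            pos = frame.loc[frame["chrom"] == chrom, "pos"].to_numpy() - 1
            hist, _ = np.histogram(pos, bins=edges)
            top = hist.max()
            empty[name] = top == 0
            series[name] = hist / top if top else hist.astype(float)
        cen = (centromeres or {}).get(chrom)
        for b in range(n_bins):
            lo, hi = int(edges[b]), int(min(edges[b + 1], size))
            in_cen = bool(cen and lo < cen[1] and hi > cen[0])
            rows.append({
                "chrom": chrom, "bin_start": lo, "bin_end": hi,
                "dmp_density": series["dmp"][b],
                "ndmp_density": series["ndmp"][b],
                "centromere": in_cen,
                "dmp_empty": empty["dmp"], "ndmp_empty": empty["ndmp"],
            })
    return pd.DataFrame(rows)
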