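"""De novo mutation calling from candidate variants, and rate estimation.

Candidates arrive as a wide table (chrom, pos, ref, alt, vclass plus
``{sample}:alt``/``{sample}:dp`` columns).  Filtering retains homozygous
de novo mutations unique to one lineage: absent from the progenitor,
strongly supported (>95% of reads) in the carrier at class-specific
depth, not heterozygous-looking, with enough progenitor coverage to
verify absence.

Rates follow the selfing-accumulation bookkeeping: with n identified
homozygous mutations over ``lines`` lineages and g generations, the
per-genome per-generation frequency is m = (n/lines)/g.  Because new
mutations arise heterozygous and need extra selfing generations to fix,
the identified count g*mu + (g-2)*tau/2 underestimates the accumulated
count g*(mu + tau/2) — by 20% at g=10 when all mutations arise
heterozygous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import PedigreeSample

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

#: the six strand-symmetric substitution classes (source pair -> target pair)
SUBSTITUTION_CLASSES = (
    "GC>AT", "AT>GC",            # transitions
    "GC>TA", "GC>CG", "AT>TA", "AT>CG",  # transversions
)
TRANSITION_CLASSES = ("GC>AT", "AT>GC")


class UndefinedTiTvError(ZeroDivisionError):
    """Raised when a Ti/Tv ratio is requested but no transversions exist."""


@dataclass
class FilterPolicy:
    """Depth and allele-fraction thresholds for mutation calling."""

    sbs_min_depth: int = 8
    sbs_max_depth: int = 75
    indel_min_depth: int = 5
    hom_threshold: float = 0.95
    het_band: Tuple[float, float] = (0.20, 0.80)

    def __post_init__(self) -> None:
        if not self.sbs_min_depth < self.sbs_max_depth:
            raise ValueError("sbs depth min must be < max")
        if not 0 < self.hom_threshold < 1:
            raise ValueError("hom_threshold must lie in (0, 1)")
        lo, hi = self.het_band
        if not 0 < lo < hi < 1:
            raise ValueError("het_band must satisfy 0 < lo < hi < 1")

    def min_depth(self, vclass: str) -> int:
        return self.sbs_min_depth if vclass == "SBS" else self.indel_min_depth

    def max_depth(self, vclass: str) -> float:
        return self.sbs_max_depth if vclass == "SBS" else np.inf


def classify_substitution(ref: str, alt: str) -> Tuple[str, str]:
    """Classify an SBS as transition/transversion with its source pair.

    Returns ``(titv, pair)`` where titv is "transition" or "transversion"
    and pair is the source base pair, "G:C" or "A:T".
    """
    if ref not in "ACGT" or alt not in "ACGT" or len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"invalid bases {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    titv = "transition" if (ref, alt) in TRANSITIONS else "transversion"
    pair = "G:C" if ref in "GC" else "A:T"
    return titv, pair


def substitution_class(ref: str, alt: str) -> str:
    """Collapse a directed SBS onto one of the six strand-symmetric classes."""
    classify_substitution(ref, alt)  # validation
    if ref in "GC":
        alt_c = alt if ref == "C" else _COMP[alt]  # change expressed as C>x
        return {"T": "GC>AT", "A": "GC>TA", "G": "GC>CG"}[alt_c]
    alt_a = alt if ref == "A" else _COMP[alt]      # change expressed as A>x
    return {"G": "AT>GC", "T": "AT>TA", "C": "AT>CG"}[alt_a]


_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def filter_variants(
    candidates: pd.DataFrame,
    pedigree: Sequence[PedigreeSample],
    policy: FilterPolicy = FilterPolicy(),
) -> pd.DataFrame:
    """Call homozygous de novo mutations from a candidate table.

    A candidate is retained iff (i) it is absent from the progenitor,
    (ii) its carriers lie in a single lineage, (iii) the carrier meets
    class-specific depth bounds, (iv) carrier alt fraction exceeds the
    homozygous threshold, (v) no adequately covered sample shows a
    heterozygous allele fraction, and (vi) the progenitor has at least
    the class-minimum depth.  One record per (candidate, lineage);
    re-filtering the output is a no-op.
    """
    prog = [s for s in pedigree if s.role == "progenitor"]
    if not prog:
        raise ValueError("pedigree must contain a progenitor sample")
    prog_id = prog[0].sample_id
    lineage_of = {s.sample_id: s.lineage_id for s in pedigree}
    derived = [s.sample_id for s in pedigree if s.role != "progenitor"]
    for sid in [prog_id, *derived]:
        if f"{sid}:alt" not in candidates.columns:
            raise ValueError(f"candidate table lacks counts for sample {sid!r}")

    lo_het, hi_het = policy.het_band
    keep_rows = []
    for idx, row in candidates.iterrows():
        vclass = row["vclass"]
        dmin = policy.min_depth(vclass)
        dmax = policy.max_depth(vclass)
        p_alt, p_dp = row[f"{prog_id}:alt"], row[f"{prog_id}:dp"]
        if p_dp < dmin:
            continue  # cannot verify absence in progenitor
        if p_dp > 0 and p_alt / p_dp > 1 - policy.hom_threshold:
            continue  # present in progenitor
        carriers = []
        het_seen = False
        for sid in derived:
            alt, dp = row[f"{sid}:alt"], row[f"{sid}:dp"]
            if dp <= 0:
                continue
            af = alt / dp
            if dp >= dmin and lo_het <= af <= hi_het:
                het_seen = True
            if af > policy.hom_threshold and dmin <= dp <= dmax:
                carriers.append(sid)
        if het_seen or not carriers:
            continue
        lineages = {lineage_of[s] for s in carriers}
        if len(lineages) != 1:
            continue  # shared across lineages: ancestral/systematic
        lineage = lineages.pop()
        if vclass == "SBS":
            titv, pair = classify_substitution(row["ref"], row["alt"])
            sub6 = substitution_class(row["ref"], row["alt"])
        else:
            titv, pair, sub6 = "NA", "NA", "NA"
        rec = row.to_dict()
        rec.update(lineage=lineage, zygosity="homozygous",
                   carrier=",".join(carriers), titv=titv, pair=pair,
                   sub_class=sub6)
        keep_rows.append(rec)
    cols = list(candidates.columns) + ["lineage", "zygosity", "carrier",
                                       "titv", "pair", "sub_class"]
    out = pd.DataFrame(keep_rows, columns=cols)
    out = out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return out


def titv_ratio(
    mutations: pd.DataFrame,
    genome_length: int | None = None,
    gc_content: float | None = None,
    normalized: bool = False,
) -> float:
    """Transition/transversion ratio of the SBS spectrum.

    Raw mode divides transition by transversion counts.  Normalized mode
    first converts each of the six strand-symmetric classes to a
    per-site rate using the genome's base composition (G:C sites =
    gc*L, A:T sites = (1-gc)*L) and returns the transition-rate sum over
    the transversion-rate sum.
    """
    sbs = mutations[mutations["vclass"] == "SBS"]
    if not normalized:
        n_ti = (sbs["titv"] == "transition").sum()
        n_tv = (sbs["titv"] == "transversion").sum()
        if n_tv == 0:
            raise UndefinedTiTvError("no transversions observed")
        return n_ti / n_tv
    if genome_length is None or gc_content is None:
        raise ValueError("normalized mode needs genome_length and gc_content")
    gc_sites = gc_content * genome_length
    at_sites = (1 - gc_content) * genome_length
    if gc_sites <= 0 or at_sites <= 0:
        raise ValueError("degenerate base composition")
    counts = sbs["sub_class"].value_counts()
    rate = {}
    for cls in SUBSTITUTION_CLASSES:
        denom = gc_sites if cls.startswith("GC") else at_sites
        rate[cls] = counts.get(cls, 0) / denom
    ti = sum(rate[c] for c in TRANSITION_CLASSES)
    tv = sum(rate[c] for c in SUBSTITUTION_CLASSES if c not in TRANSITION_CLASSES)
    if tv == 0:
        raise UndefinedTiTvError("no transversions observed")
    return ti / tv


def mutation_rate(n: float, lines: int, g: int) -> float:
    """Per-genome per-generation mutation frequency m = (n/lines)/g."""
    if lines < 1 or g < 1:
        raise ValueError("lines and g must be >= 1")
    if n < 0:
        raise ValueError("n must be >= 0")
    return (n / lines) / g


@dataclass
class AccumulationResult:
    expected_accumulated: float
    expected_identified: float
    underestimation_fraction: float


def accumulation_model(mu: float, tau: float, g: int) -> AccumulationResult:
    """Expected accumulated vs identified homozygous mutation counts.

    New mutations arise homozygous at rate mu and heterozygous at rate
    tau per generation.  Over g generations the accumulated homozygous
    count is g*(mu + tau/2); mutations still segregating at sampling
    reduce the identified count to g*mu + (g-2)*tau/2.
    """
    if g < 2:
        raise ValueError("g must be >= 2")
    if mu < 0 or tau < 0:
        raise ValueError("rates must be >= 0")
    accumulated = g * (mu + tau / 2.0)
    identified = g * mu + (g - 2) * tau / 2.0
    under = 0.0 if accumulated == 0 else 1.0 - identified / accumulated
    return AccumulationResult(accumulated, identified, under)


@dataclass
class RateComparison:
    ratio: float
    t_statistic: float
    p_value: float
    mean_a: float
    mean_b: float


def compare_rates(control: Sequence[float], saline: Sequence[float]) -> RateComparison:
    """Welch two-sample t-test on per-lineage per-generation rates.

    Returns the saline/control ratio of group means.  Two identical
    zero-variance groups are reported as t=0, p=1 (no evidence of a
    difference) rather than NaN.
    """
    a = np.asarray(control, dtype=float)
    b = np.asarray(saline, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 lineages per group")
    ratio = np.nan if a.mean() == 0 else b.mean() / a.mean()
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return RateComparison(ratio, 0.0, 1.0, a.mean(), b.mean())
        return RateComparison(ratio, np.inf, 0.0, a.mean(), b.mean())
    t, p = stats.ttest_ind(b, a, equal_var=False)
    return RateComparison(ratio, float(t), float(p), float(a.mean()), float(b.mean()))


def lineage_rates(
    mutations: pd.DataFrame,
    pedigree: Sequence[PedigreeSample],
    g: int,
) -> pd.DataFrame:
    """Per-lineage per-generation mutation rates, overall and per class.

    Counts each mutation once per owner lineage (m = n/g with lines=1).
    """
    treatment_of = {s.lineage_id: s.treatment for s in pedigree
                    if s.role != "progenitor"}
    rows = []
    for lineage, treatment in sorted(treatment_of.items()):
        sub = mutations[mutations["lineage"] == lineage]
        row = {"lineage": lineage, "treatment": treatment,
               "overall": mutation_rate(len(sub), 1, g)}
        for cls, sel in (("transition", sub["titv"] == "transition"),
                         ("transversion", sub["titv"] == "transversion"),
                         ("indel", sub["vclass"].isin(["insertion", "deletion"]))):
            row[cls] = mutation_rate(int(sel.sum()), 1, g)
        rows.append(row)
    return pd.DataFrame(rows)


def rate_comparison_table(rates: pd.DataFrame) -> pd.DataFrame:
    """compare_rates per mutation class from a lineage_rates frame."""
    ctrl = rates[rates["treatment"] == "control"]
    sal = rates[rates["treatment"] == "saline"]
    rows = []
    for cls in ("overall", "transition", "transversion", "indel"):
        cmp = compare_rates(ctrl[cls], sal[cls])
        rows.append({"class": cls, "control_mean": cmp.mean_a,
                     "saline_mean": cmp.mean_b, "ratio": cmp.ratio,
                     "t_statistic": cmp.t_statistic, "p_value": cmp.p_value})
    return pd.DataFrame(rows)
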