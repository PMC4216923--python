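"""Mutation-accumulation pedigree simulation under selfing.

Each lineage is propagated by single-seed descent.  New mutations arise
each generation as Poisson events per class and are heterozygous with
probability ``het_fraction`` (otherwise homozygous at birth).  A
heterozygous mutation segregates per selfing generation to the
homozygous-mutant state with probability 1/4, is lost with probability
1/4, and stays heterozygous with probability 1/2 — so the probability a
heterozygote born t generations ago is now fixed homozygous is
(1/2)(1 - (1/2)^t).

Methylation states per cytosine evolve by per-generation gain/loss rates
(genic sites use enriched rates, saline lineages a CG multiplier) and are
inherited clonally through selfing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .genome import AnnotationSet, GENIC_CATEGORIES, SyntheticGenome, cytosine_sites

ROLES = ("progenitor", "parental", "derived", "post_stress")

# zygosity codes
ABSENT, HET, HOM = 0, 1, 2
ZYGOSITY_LABELS = {ABSENT: "absent", HET: "heterozygous", HOM: "homozygous"}


@dataclass
class PedigreeSample:
    """One sequenced plant in the MA design."""

    sample_id: str
    lineage_id: str
    generation: int
    treatment: str  # control | saline
    role: str       # progenitor | parental | derived | post_stress

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.treatment not in ("control", "saline"):
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.role == "progenitor" and self.generation != 0:
            raise ValueError("progenitor must be generation 0")


def samples_to_frame(samples: List[PedigreeSample]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in samples])


def samples_from_frame(frame: pd.DataFrame) -> List[PedigreeSample]:
    return [PedigreeSample(r.sample_id, r.lineage_id, int(r.generation),
                           r.treatment, r.role)
            for r in frame.itertuples(index=False)]


@dataclass
class TruthTable:
    """Ground truth emitted by the simulator, for recovery tests.

    ``mutations`` has one row per germline event (mut_id, lineage, chrom,
    pos, ref, alt, vclass, birth_gen); ``genotypes`` gives each
    genomically sequenced plant's zygosity per event; ``meth_states``
    holds each bisulfite sample's boolean methylation vector over
    ``sites``; ``epimutations`` logs every state flip with its generation.
    """

    sites: pd.DataFrame
    genic: np.ndarray
    mutations: pd.DataFrame
    genotypes: pd.DataFrame
    meth_states: Dict[str, np.ndarray]
    epimutations: pd.DataFrame
    initial_state: np.ndarray
    methylation_level: np.ndarray
    genomic_samples: List[PedigreeSample] = field(default_factory=list)
    bisulfite_samples: List[PedigreeSample] = field(default_factory=list)

    @property
    def all_samples(self) -> List[PedigreeSample]:
        return self.genomic_samples + self.bisulfite_samples


def segregate(rng: np.random.Generator, n: int) -> np.ndarray:
    """One selfing generation for n heterozygous events.

    Returns zygosity codes drawn 1/4 ABSENT : 1/2 HET : 1/4 HOM.
    """
    u = rng.random(n)
    out = np.full(n, HET, dtype=np.int8)
    out[u < 0.25] = HOM
    out[u >= 0.75] = ABSENT
    return out


def fixation_probability(t: int) -> float:
    """P(homozygous mutant) t selfing generations after a het event."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return 0.5 * (1.0 - 0.5 ** t)


def simulate_pedigree(
    config: SimulationConfig,
    genome: Optional[SyntheticGenome] = None,
    annotation: Optional[AnnotationSet] = None,
    n_lineages_per_treatment: Optional[int] = None,
    g: Optional[int] = None,
    include_offspring: bool = True,
    methylomes: bool = True,
) -> Tuple[TruthTable, List[PedigreeSample]]:
    """Simulate the full MA design and return truth plus the sample sheet.

    Genomic-sequencing samples: the G0 progenitor plus
    ``plants_per_lineage`` G10 siblings per lineage (the germline runs to
    G(g-1); siblings independently segregate its heterozygotes and add
    their own G(g) events).  Bisulfite samples: two G1 parental plants
    plus one G(g) plant per lineage, and optionally one selfed offspring
    (G(g+1)) of the first lineage of each treatment.
    """
    from .genome import generate_genome

    if genome is None or annotation is None:
        genome, annotation = generate_genome(config)
    n_lin = n_lineages_per_treatment or config.n_lineages_per_treatment
    g = g or config.generations
    if g < 1:
        raise ValueError("g must be >= 1")

    rng = config.rng(2)
    sites = cytosine_sites(genome)
    genic = genic_mask(sites, annotation)
    level = _methylation_levels(rng, sites, config)
    init_state = _initial_state(rng, sites, config)

    lineages = ([("control", f"C{i + 1}") for i in range(n_lin)]
                + [("saline", f"S{i + 1}") for i in range(n_lin)])

    genomic_samples = [PedigreeSample("G0", "progenitor", 0, "control", "progenitor")]
    bisulfite_samples = [
        PedigreeSample("G1-1", "progenitor", 1, "control", "parental"),
        PedigreeSample("G1-2", "progenitor", 1, "control", "parental"),
    ]

    mut_rows: List[tuple] = []
    geno_rows: List[tuple] = []
    epi_rows: List[tuple] = []
    meth_states: Dict[str, np.ndarray] = {}

    # parental G1 methylomes: one generation of drift from the progenitor
    if methylomes:
        for s in bisulfite_samples:
            state = init_state.copy()
            _evolve_methylome(rng, state, sites, genic, config, "control",
                              generations=1, events=epi_rows,
                              sample_id=s.sample_id)
            meth_states[s.sample_id] = state

    for treatment, lin in lineages:
        _simulate_lineage(rng, config, genome, sites, genic, init_state,
                          treatment, lin, g, mut_rows, geno_rows, epi_rows,
                          meth_states, genomic_samples, bisulfite_samples,
                          methylomes)

    if include_offspring and methylomes:
        for treatment, lin in (("control", "C1"), ("saline", "S1")):
            tag = f"G{g + 1}-{lin}"
            parent_id = f"G{g}-{lin}"
            if parent_id in meth_states:
                state = _offspring_methylome(
                    rng, meth_states[parent_id], init_state,
                    config.epimutation_retention)
                meth_states[tag] = state
                bisulfite_samples.append(
                    PedigreeSample(tag, lin, g + 1, treatment, "post_stress"))

    mutations = pd.DataFrame(
        mut_rows,
        columns=["mut_id", "lineage", "chrom", "pos", "ref", "alt",
                 "vclass", "birth_gen"],
    )
    genotypes = pd.DataFrame(
        geno_rows, columns=["sample_id", "mut_id", "zygosity"])
    epimutations = pd.DataFrame(
        epi_rows,
        columns=["sample_id", "site_idx", "chrom", "pos", "context",
                 "direction", "generation"],
    )
    truth = TruthTable(
        sites=sites, genic=genic, mutations=mutations, genotypes=genotypes,
        meth_states=meth_states, epimutations=epimutations,
        initial_state=init_state, methylation_level=level,
        genomic_samples=genomic_samples, bisulfite_samples=bisulfite_samples,
    )
    return truth, truth.all_samples


def genic_mask(sites: pd.DataFrame, annotation: AnnotationSet) -> np.ndarray:
    """Boolean mask of sites inside genic features (CDS/UTR/intron/ncRNA)."""
    mask = np.zeros(len(sites), dtype=bool)
    iv = annotation.intervals
    genic_iv = iv[iv["category"].isin(GENIC_CATEGORIES)]
    for chrom, sub in genic_iv.groupby("chrom"):
        sel = sites["chrom"] == chrom
        if not sel.any():
            continue
        pos0 = sites.loc[sel, "pos"].to_numpy() - 1
        starts = np.sort(sub["start"].to_numpy())
        ends = np.sort(sub["end"].to_numpy())
        # non-overlapping per category but categories may abut; merge
        merged_s, merged_e = _merge(starts, ends, sub)
        j = np.searchsorted(merged_s, pos0, side="right") - 1
        hit = (j >= 0) & (pos0 < merged_e[np.clip(j, 0, None)])
        mask[np.nonzero(sel.to_numpy())[0]] = hit
    return mask


def _merge(starts, ends, sub):
    iv = sub[["start", "end"]].sort_values("start").to_numpy()
    out_s, out_e = [], []
    for s, e in iv:
        if out_e and s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s), np.asarray(out_e)


def _initial_state(rng, sites, config):
    p = sites["context"].map(config.initial_methylation).to_numpy(float)
    return rng.random(len(sites)) < p


def _methylation_levels(rng, sites, config):
    level = np.empty(len(sites))
    ctx = sites["context"].to_numpy()
    for c, (a, b) in config.methylation_level_beta.items():
        sel = ctx == c
        level[sel] = rng.beta(a, b, sel.sum())
    return level


def _flip_probs(sites, genic, config, treatment):
    gain = sites["context"].map(config.epimutation_gain).to_numpy(float).copy()
    loss = sites["context"].map(config.epimutation_loss).to_numpy(float).copy()
    cg = (sites["context"] == "CG").to_numpy()
    if treatment == "saline":
        gain[cg] *= config.saline_cg_multiplier
        loss[cg] *= config.saline_cg_multiplier
    gain[genic] *= config.genic_enrichment
    loss[genic] *= config.genic_enrichment
    return np.clip(gain, 0, 1), np.clip(loss, 0, 1)


def _evolve_methylome(rng, state, sites, genic, config, treatment,
                      generations, events, sample_id, start_gen=1):
    gain, loss = _flip_probs(sites, genic, config, treatment)
    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    ctx = sites["context"].to_numpy()
    cg_idx = np.nonzero(ctx == "CG")[0]
    region_rate = config.regional_epimutation_rate * len(state)
    if treatment == "saline":
        region_rate *= config.saline_cg_multiplier
    for gen in range(start_gen, start_gen + generations):
        u = rng.random(len(state))
        flip = np.where(state, u < loss, u < gain)
        idx = np.nonzero(flip)[0]
        for i in idx:
            events.append((sample_id, int(i), chrom[i], int(pos[i]), ctx[i],
                           "loss" if state[i] else "gain", gen))
        state[idx] = ~state[idx]
        # regional events: a run of neighbouring CG sites switches together
        for _ in range(rng.poisson(region_rate)):
            if len(cg_idx) == 0:
                break
            anchor = int(cg_idx[rng.integers(len(cg_idx))])
            half = config.regional_window // 2
            near = cg_idx[(chrom[cg_idx] == chrom[anchor])
                          & (np.abs(pos[cg_idx] - pos[anchor]) <= half)]
            target = not state[anchor]
            for i in near[state[near] != target]:
                events.append((sample_id, int(i), chrom[i], int(pos[i]),
                               ctx[i], "gain" if target else "loss", gen))
            state[near] = target


def _offspring_methylome(rng, parent_state, init_state, retention):
    """Selfed offspring: each inherited epimutation survives w.p. retention."""
    state = parent_state.copy()
    changed = np.nonzero(state != init_state)[0]
    revert = changed[rng.random(len(changed)) > retention]
    state[revert] = init_state[revert]
    return state


_PURINES = {"A": "G", "G": "A"}
_PYRIMIDINES = {"C": "T", "T": "C"}
_ALL = "ACGT"


def _simulate_lineage(rng, config, genome, sites, genic, init_state,
                      treatment, lin, g, mut_rows, geno_rows, epi_rows,
                      meth_states, genomic_samples, bisulfite_samples,
                      methylomes=True):
    mults = config.saline_mutation_multiplier if treatment == "saline" else {}
    length = sum(genome.chrom_sizes.values())
    rates = {c: r * mults.get(c, 1.0) if treatment == "saline" else r
             for c, r in config.mutation_rates.items()}

    # germline events up to G(g-1): list of dicts with zygosity tracking
    germline: List[dict] = []

    def new_events(gen):
        for vclass, rate in rates.items():
            k = rng.poisson(rate * length)
            for _ in range(k):
                ev = _draw_event(rng, config, genome, vclass)
                ev["birth_gen"] = gen
                ev["zygosity"] = HET if rng.random() < config.het_fraction else HOM
                germline.append(ev)

    for gen in range(1, g):
        new_events(gen)
        het_idx = [i for i, ev in enumerate(germline) if ev["zygosity"] == HET]
        if het_idx:
            outcome = segregate(rng, len(het_idx))
            for i, z in zip(het_idx, outcome):
                germline[i]["zygosity"] = int(z)

    # three G(g) sibling plants from the G(g-1) germline
    for p in range(config.plants_per_lineage):
        sid = f"G{g}-{lin}" if p == 0 else f"G{g}-{lin}.{p + 1}"
        plant_events = []
        for ev in germline:
            z = ev["zygosity"]
            if z == HET:
                z = int(segregate(rng, 1)[0])
            if z != ABSENT:
                plant_events.append((ev, z))
        # plant-private G(g) events
        own: List[dict] = []
        for vclass, rate in rates.items():
            k = rng.poisson(rate * length)
            for _ in range(k):
                ev = _draw_event(rng, config, genome, vclass)
                ev["birth_gen"] = g
                ev["zygosity"] = HET if rng.random() < config.het_fraction else HOM
                own.append(ev)
        plant_events.extend((ev, ev["zygosity"]) for ev in own)
        for ev, z in plant_events:
            mid = ev.setdefault("mut_id", f"{lin}_{len(mut_rows)}")
            if not ev.get("_recorded"):
                ev["_recorded"] = True
                mut_rows.append((mid, lin, ev["chrom"], ev["pos"], ev["ref"],
                                 ev["alt"], ev["vclass"], ev["birth_gen"]))
            geno_rows.append((sid, mid, ZYGOSITY_LABELS[z]))
        genomic_samples.append(
            PedigreeSample(sid, lin, g, treatment, "derived"))

    # bisulfite methylome for the first plant of the lineage
    if methylomes:
        state = init_state.copy()
        bs_id = f"G{g}-{lin}"
        _evolve_methylome(rng, state, sites, genic, config, treatment,
                          generations=g, events=epi_rows, sample_id=bs_id)
        meth_states[bs_id] = state
        bisulfite_samples.append(
            PedigreeSample(bs_id, lin, g, treatment, "derived"))


def _draw_event(rng, config, genome, vclass):
    names = [n for n, _ in genome.chromosomes]
    sizes = np.array([genome.chrom_sizes[n] for n in names], dtype=float)
    chrom = names[int(rng.choice(len(names), p=sizes / sizes.sum()))]
    seq = genome.sequence(chrom)
    # keep an anchor base available for indel VCF representation
    pos = int(rng.integers(2, len(seq)))  # 1-based
    ref_base = seq[pos - 1]
    if vclass == "transition":
        alt = _PURINES.get(ref_base) or _PYRIMIDINES[ref_base]
        return {"chrom": chrom, "pos": pos, "ref": ref_base, "alt": alt,
                "vclass": "SBS"}
    if vclass == "transversion":
        choices = [b for b in _ALL if b != ref_base
                   and b != (_PURINES.get(ref_base) or _PYRIMIDINES[ref_base])]
        return {"chrom": chrom, "pos": pos, "ref": ref_base,
                "alt": choices[int(rng.integers(len(choices)))], "vclass": "SBS"}
    ln = _indel_length(rng, config)
    if vclass == "insertion":
        ins = "".join(_ALL[int(rng.integers(4))] for _ in range(ln))
        return {"chrom": chrom, "pos": pos, "ref": ref_base,
                "alt": ref_base + ins, "vclass": "insertion"}
    # deletion: anchor base + deleted run
    end = min(pos + ln, len(seq))
    return {"chrom": chrom, "pos": pos, "ref": seq[pos - 1:end],
            "alt": ref_base, "vclass": "deletion"}


def _indel_length(rng, config):
    """Geometric indel length truncated at the configured maximum."""
    while True:
        ln = int(rng.geometric(config.indel_geom_p))
        if ln <= config.indel_max_len:
            return ln
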