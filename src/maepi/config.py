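"""Simulation parameters for the synthetic mutation-accumulation study.

The defaults emulate a selfed *Arabidopsis*-like mutation-accumulation
design: six lineages (three control, three grown on saline soil) propagated
for ten generations by single-seed descent, with whole-genome resequencing
of three tenth-generation siblings per lineage plus the progenitor, and
whole-genome bisulfite sequencing of one tenth-generation plant per lineage
plus two first-generation plants.

All event rates are per site per generation.  The mutation-rate defaults
fold the 119 Mb -> 2 Mb genome scale factor into the per-site rate, so the
default two-chromosome 1 Mb genome accumulates per-genome event counts
comparable to the full-size study (roughly 0.33 transitions, 0.16
transversions and 0.09 indels per genome per generation in control
lineages, doubled under salt stress).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

MUTATION_CLASSES = ("transition", "transversion", "insertion", "deletion")
CONTEXTS = ("CG", "CHG", "CHH")


@dataclass
class SimulationConfig:
    """Bag of knobs for the synthetic-data generator.

    Rates live in [0, 1]; multipliers are positive; coverages are mean read
    depths of Poisson-distributed per-site depth.
    """

    seed: int = 0

    # genome
    chromosome_lengths: Sequence[int] = (1_000_000, 1_000_000)
    gc_content: float = 0.36
    centromere_fraction: float = 0.15

    # pedigree / design
    n_lineages_per_treatment: int = 3
    generations: int = 10
    plants_per_lineage: int = 3  # genomic-sequencing G10 siblings

    # per-site per-generation mutation rates, control arm
    transition_rate: float = 1.67e-7
    transversion_rate: float = 7.8e-8
    insertion_rate: float = 2.2e-8
    deletion_rate: float = 2.2e-8
    # saline multiplier per mutation class
    saline_mutation_multiplier: Mapping[str, float] = field(
        default_factory=lambda: {c: 2.0 for c in MUTATION_CLASSES}
    )
    # fraction of new mutations arising heterozygous (tau share); the
    # remainder arise homozygous (mu share)
    het_fraction: float = 1.0
    indel_max_len: int = 226
    indel_geom_p: float = 0.5

    # per-site per-generation epimutation rates, control arm
    epimutation_gain: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 1.0e-4, "CHG": 2.0e-5, "CHH": 1.0e-5}
    )
    epimutation_loss: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 3.0e-4, "CHG": 1.0e-4, "CHH": 1.0e-4}
    )
    saline_cg_multiplier: float = 1.45
    genic_enrichment: float = 2.0
    # regional events: a window of adjacent CG sites switching state
    # together (source of DMRs); rate per site per generation
    regional_epimutation_rate: float = 3.0e-8
    regional_window: int = 120
    # initial (progenitor) methylation probability per context
    initial_methylation: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 0.24, "CHG": 0.10, "CHH": 0.03}
    )
    # Beta(a, b) parameters for the per-site methylation level of
    # methylated sites (partial methylation; CG concentrated near 1)
    methylation_level_beta: Mapping[str, tuple] = field(
        default_factory=lambda: {"CG": (20.0, 2.0), "CHG": (5.0, 5.0), "CHH": (2.0, 8.0)}
    )
    # probability a G10 epimutation survives into a G11 offspring
    epimutation_retention: float = 0.76

    # sequencing emulation
    bisulfite_coverage: float = 75.0
    genomic_coverage: float = 22.0
    nonconversion_rate: float = 0.004
    seq_error_rate: float = 0.001
    false_candidate_rate: float = 5.0e-6
    spikein_sites: int = 2_000

    def __post_init__(self) -> None:
        if min(self.chromosome_lengths) < 10_000:
            raise ValueError("chromosome length must be >= 10^4")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        rates = [
            self.transition_rate, self.transversion_rate,
            self.insertion_rate, self.deletion_rate,
            self.het_fraction, self.nonconversion_rate, self.seq_error_rate,
            self.false_candidate_rate, self.epimutation_retention,
            self.regional_epimutation_rate,
            *self.epimutation_gain.values(), *self.epimutation_loss.values(),
            *self.initial_methylation.values(),
        ]
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        mults = [*self.saline_mutation_multiplier.values(),
                 self.saline_cg_multiplier, self.genic_enrichment]
        if any(m <= 0 for m in mults):
            raise ValueError("multipliers must be > 0")
        if self.bisulfite_coverage <= 0 or self.genomic_coverage <= 0:
            raise ValueError("coverage means must be > 0")
        if not 0.0 <= self.centromere_fraction < 1.0:
            raise ValueError("centromere_fraction must lie in [0, 1)")

    @property
    def mutation_rates(self) -> dict:
        return {
            "transition": self.transition_rate,
            "transversion": self.transversion_rate,
            "insertion": self.insertion_rate,
            "deletion": self.deletion_rate,
        }

    def rng(self, stream: int) -> np.random.Generator:
        """Deterministic child generator for one simulation stage."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["chromosome_lengths"] = list(self.chromosome_lengths)
        d["saline_mutation_multiplier"] = dict(self.saline_mutation_multiplier)
        d["epimutation_gain"] = dict(self.epimutation_gain)
        d["epimutation_loss"] = dict(self.epimutation_loss)
        d["initial_methylation"] = dict(self.initial_methylation)
        d["methylation_level_beta"] = {
            k: list(v) for k, v in self.methylation_level_beta.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "methylation_level_beta" in d:
            d["methylation_level_beta"] = {
                k: tuple(v) for k, v in d["methylation_level_beta"].items()
            }
        if "chromosome_lengths" in d:
            d["chromosome_lengths"] = tuple(d["chromosome_lengths"])
        return cls(**d)
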