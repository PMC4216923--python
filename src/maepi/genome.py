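"""Synthetic reference genome and feature annotation.

The genome is an i.i.d. nucleotide sequence at a requested GC content with
a centromeric interval per chromosome.  The annotation tiles each
chromosome with genes (UTR-CDS-intron-CDS-UTR), ncRNAs, pseudogenes and
transposable elements, with pseudogene/TE blocks laid down more densely
inside centromeres, mirroring the repeat-rich pericentromeric organisation
of plant genomes.  Every position not covered by a feature resolves to
"intergenic".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .config import SimulationConfig

CATEGORIES = ("CDS", "UTR", "intron", "ncRNA", "pseudogene", "TE", "intergenic")
GENIC_CATEGORIES = frozenset({"CDS", "UTR", "intron", "ncRNA"})

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SyntheticGenome:
    """Chromosome sequences plus centromere intervals (0-based half-open)."""

    chromosomes: List[Tuple[str, str]]
    gc_content: float
    centromeres: Dict[str, Tuple[int, int]]

    @property
    def chrom_sizes(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes}

    def sequence(self, name: str) -> str:
        for n, s in self.chromosomes:
            if n == name:
                return s
        raise KeyError(name)

    def realized_gc(self) -> float:
        gc = total = 0
        for _, seq in self.chromosomes:
            gc += seq.count("G") + seq.count("C")
            total += len(seq)
        return gc / total if total else 0.0


@dataclass
class AnnotationSet:
    """Feature intervals (0-based half-open), non-overlapping per category."""

    intervals: pd.DataFrame  # columns: chrom, start, end, category
    chrom_sizes: Dict[str, int]

    def for_category(self, chrom: str, category: str) -> pd.DataFrame:
        iv = self.intervals
        return iv[(iv["chrom"] == chrom) & (iv["category"] == category)]


def generate_genome(config: SimulationConfig) -> Tuple[SyntheticGenome, AnnotationSet]:
    """Draw a random genome and annotation; deterministic for a fixed seed."""
    rng = config.rng(1)
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    chroms: List[Tuple[str, str]] = []
    centromeres: Dict[str, Tuple[int, int]] = {}
    rows = []
    for i, length in enumerate(config.chromosome_lengths):
        name = f"chr{i + 1}"
        seq = _BASES[rng.choice(4, size=length, p=p)].tobytes().decode()
        chroms.append((name, seq))
        half = int(length * config.centromere_fraction) // 2
        mid = length // 2
        cen = (mid - half, mid + half)
        centromeres[name] = cen
        rows.extend(_annotate_chromosome(rng, name, length, cen))
    intervals = pd.DataFrame(rows, columns=["chrom", "start", "end", "category"])
    genome = SyntheticGenome(chroms, gc, centromeres)
    annotation = AnnotationSet(intervals, genome.chrom_sizes)
    return genome, annotation


def _annotate_chromosome(rng, name, length, centromere):
    """Tile one chromosome with feature blocks."""
    rows = []
    pos = 0
    cen_lo, cen_hi = centromere
    while pos < length:
        in_cen = cen_lo <= pos < cen_hi
        u = rng.random()
        if in_cen:
            # repeat-rich pericentromere: mostly TE/pseudogene
            if u < 0.45:
                end = min(pos + int(rng.integers(300, 3000)), length)
                rows.append((name, pos, end, "TE"))
            elif u < 0.65:
                end = min(pos + int(rng.integers(200, 1500)), length)
                rows.append((name, pos, end, "pseudogene"))
            else:
                end = min(pos + int(rng.integers(200, 1000)), length)
            pos = end
        else:
            if u < 0.40:
                pos = _emit_gene(rng, rows, name, pos, length)
            elif u < 0.45:
                end = min(pos + int(rng.integers(200, 800)), length)
                rows.append((name, pos, end, "ncRNA"))
                pos = end
            elif u < 0.55:
                end = min(pos + int(rng.integers(300, 2000)), length)
                rows.append((name, pos, end, "TE"))
            elif u < 0.60:
                end = min(pos + int(rng.integers(200, 1000)), length)
                rows.append((name, pos, end, "pseudogene"))
            else:
                end = min(pos + int(rng.integers(200, 2000)), length)
                pos = end  # intergenic gap (implicit category)
    return rows


def _emit_gene(rng, rows, name, pos, length):
    """UTR-CDS-intron-CDS-UTR gene model."""
    for cat, lo, hi in (("UTR", 100, 300), ("CDS", 200, 500),
                        ("intron", 80, 300), ("CDS", 200, 500),
                        ("UTR", 100, 300)):
        if pos >= length:
            break
        end = min(pos + int(rng.integers(lo, hi)), length)
        rows.append((name, pos, end, cat))
        pos = end
    return pos


def cytosine_sites(genome: SyntheticGenome) -> pd.DataFrame:
    """Enumerate every cytosine on both strands with its sequence context.

    Contexts follow the plant convention: CG, CHG, CHH with H in {A,T,C},
    read 5'->3' on the cytosine's own strand.  Cytosines within 2 bp of a
    chromosome end (context undefined) are skipped.

    Returns a frame with 1-based ``pos`` and columns chrom, pos, strand,
    context, trinucleotide.
    """
    frames = []
    for name, seq in genome.chromosomes:
        arr = np.frombuffer(seq.encode(), dtype="S1")
        n = len(arr)
        if n < 3:
            continue
        # + strand: C at i, context from seq[i:i+3]
        is_c = arr == b"C"
        is_c[-2:] = False
        idx = np.nonzero(is_c)[0]
        nxt1 = arr[idx + 1]
        nxt2 = arr[idx + 2]
        ctx = np.where(nxt1 == b"G", "CG", np.where(nxt2 == b"G", "CHG", "CHH"))
        tri = _tri(arr, idx, plus=True)
        frames.append(pd.DataFrame({
            "chrom": name, "pos": idx + 1, "strand": "+", "context": ctx,
            "tri": tri,
        }))
        # - strand: G at i is a C on the reverse strand; context from
        # reverse-complement of seq[i-2:i+1]
        is_g = arr == b"G"
        is_g[:2] = False
        idx = np.nonzero(is_g)[0]
        prv1 = arr[idx - 1]
        prv2 = arr[idx - 2]
        ctx = np.where(prv1 == b"C", "CG", np.where(prv2 == b"C", "CHG", "CHH"))
        tri = _tri(arr, idx, plus=False)
        frames.append(pd.DataFrame({
            "chrom": name, "pos": idx + 1, "strand": "-", "context": ctx,
            "tri": tri,
        }))
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context", "tri"])
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["chrom", "pos", "strand"], kind="mergesort")
    return out.reset_index(drop=True)


_COMP = bytes.maketrans(b"ACGT", b"TGCA")


def _tri(arr, idx, plus):
    if len(idx) == 0:
        return np.array([], dtype=object)
    if plus:
        stacked = np.char.add(np.char.add(arr[idx].astype("U1"),
                                          arr[idx + 1].astype("U1")),
                              arr[idx + 2].astype("U1"))
        return stacked.astype(object)
    # reverse complement of [i-2, i]
    a = arr[idx].tobytes().translate(_COMP).decode()
    b = arr[idx - 1].tobytes().translate(_COMP).decode()
    c = arr[idx - 2].tobytes().translate(_COMP).decode()
    return np.array([x + y + z for x, y, z in zip(a, b, c)], dtype=object)
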