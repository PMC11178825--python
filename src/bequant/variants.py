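"""Per-plant DNA/RNA variant profiling.

Works on variant tables (one per regenerated plant, DNA from WGS or RNA
from transcriptome variant calling) and answers the questions asked of an
edited-plant cohort: how many SNVs/indels per plant, what is their six-type
substitution spectrum, which calls are subclonal / heterozygous / homozygous
by allele frequency, which plants carry on-target edits at which sites, and
whether the flanking sequence context of C>T / A>G calls is conserved.

RNA mode reuses every operation unchanged: C-to-U deamination products are
observed as C>T calls and A-to-I as A>G, so they land in the C>T and T>C
pyrimidine-anchored classes respectively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .offtarget import CONSISTENT_CONVERSIONS, CandidateSite
from .sites import complement, revcomp

_BASES = "ACGT"

#: the six pyrimidine-anchored substitution classes
SNV_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

ZYGOSITY_CLASSES = ("subclonal", "heterozygous", "homozygous")

#: allele-frequency cutoffs: af > 0.3 -> mutation call, af > 0.7 -> biallelic
DEFAULT_AF_CUTOFFS = (0.3, 0.7)


@dataclass(frozen=True)
class SNVRecord:
    """One single-nucleotide variant call with its allele frequency."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    allele_frequency: float
    depth: int = 0
    sample_id: str = ""
    molecule: str = "DNA"

    def __post_init__(self) -> None:
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"ref/alt must be single ACGT bases, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if not 0 < self.allele_frequency <= 1:
            raise ValueError("allele frequency must lie in (0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class IndelRecord:
    """One small insertion/deletion call (counted, never spectrum-classified)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    allele_frequency: float
    depth: int = 0
    sample_id: str = ""


@dataclass
class PlantVariantSet:
    """All variant calls for one plant (one sample), DNA or RNA."""

    sample_id: str
    snvs: list[SNVRecord] = field(default_factory=list)
    indels: list[IndelRecord] = field(default_factory=list)
    molecule: str = "DNA"
    n_rejected: int = 0  # records lacking any usable AF, counted on ingest


def classify_snv_type(ref: str, alt: str) -> str:
    """Collapse a ref>alt pair onto the six pyrimidine-anchored classes.

    Purine-anchored pairs are complemented, so e.g. G>A maps to C>T and
    A>C maps to T>G; complementing both bases never changes the class.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in _BASES or alt not in _BASES:
        raise ValueError(f"invalid bases {ref}>{alt}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref in "AG":
        ref, alt = complement(ref), complement(alt)
    return f"{ref}>{alt}"


def call_zygosity(af: float, cutoffs: tuple[float, float] = DEFAULT_AF_CUTOFFS) -> str:
    """Zygosity class of a diploid-plant variant from its allele frequency.

    Strict inequalities: af > 0.7 is homozygous/biallelic, 0.3 < af <= 0.7
    heterozygous, af <= 0.3 subclonal (boundary values fall to the lower
    class).
    """
    lo, hi = cutoffs
    if not 0 < af <= 1:
        raise ValueError("allele frequency must lie in (0, 1]")
    if af > hi:
        return "homozygous"
    if af > lo:
        return "heterozygous"
    return "subclonal"


def intersect_callsets(callsets: Sequence[Sequence[SNVRecord]]) -> list[SNVRecord]:
    """Variants present in every callset, keyed by (chrom, pos, ref, alt).

    AF and depth are taken from the first callset; output preserves the
    first callset's order.  Commutative and idempotent over the key sets.
    """
    if len(callsets) < 2:
        raise ValueError("need at least two callsets to intersect")
    common = set.intersection(*({rec.key for rec in cs} for cs in callsets))
    return [rec for rec in callsets[0] if rec.key in common]


def per_plant_counts(plants: Sequence[PlantVariantSet]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-plant variant tallies.

    Returns ``(class_table, chrom_table)``: the first has one row per plant
    with n_indels, n_snvs and one column per six-type class (classes sum to
    n_snvs); the second has per-chromosome SNV counts.
    """
    class_rows, chrom_rows = [], []
    for plant in plants:
        row = {"sample_id": plant.sample_id,
               "n_indels": len(plant.indels), "n_snvs": len(plant.snvs)}
        for cls in SNV_CLASSES:
            row[cls] = 0
        chrom_row: dict[str, object] = {"sample_id": plant.sample_id}
        for snv in plant.snvs:
            row[classify_snv_type(snv.ref, snv.alt)] += 1
            chrom_row[snv.chrom] = chrom_row.get(snv.chrom, 0) + 1
        class_rows.append(row)
        chrom_rows.append(chrom_row)
    class_table = pd.DataFrame(class_rows).set_index("sample_id")
    chrom_table = pd.DataFrame(chrom_rows).set_index("sample_id").fillna(0).astype(int)
    return class_table, chrom_table


def germline_fraction(plant: PlantVariantSet,
                      cutoffs: tuple[float, float] = DEFAULT_AF_CUTOFFS) -> float:
    """Fraction of a plant's SNVs that are likely germline-transmittable.

    Defined as the heterozygous-or-homozygous fraction, i.e. calls with
    allele frequency above the lower cutoff.
    """
    if not plant.snvs:
        raise ValueError(f"plant {plant.sample_id}: no SNVs; fraction undefined")
    calls = [call_zygosity(s.allele_frequency, cutoffs) for s in plant.snvs]
    return sum(c != "subclonal" for c in calls) / len(calls)


def on_target_genotype_matrix(
    plants: Sequence[PlantVariantSet],
    sites: Sequence[CandidateSite],
    conversion: str = "C>T",
    cutoffs: tuple[float, float] = DEFAULT_AF_CUTOFFS,
) -> pd.DataFrame:
    """Plant x site genotype matrix for one conversion type.

    A cell is ``biallelic`` when some SNV of the requested protospacer-strand
    conversion inside the site's protospacer interval has af above the upper
    cutoff, ``edited`` when above the lower cutoff only, else ``unedited``.
    """
    lo, hi = cutoffs
    site_ids = [f"{s.source_grna}" for s in sites]
    matrix = pd.DataFrame("unedited",
                          index=[p.sample_id for p in plants], columns=site_ids)
    for plant in plants:
        for site, sid in zip(sites, site_ids):
            best = 0.0
            for snv in plant.snvs:
                if snv.chrom != site.chrom or not site.start <= snv.pos - 1 < site.end:
                    continue
                if site.strand == "+":
                    conv = f"{snv.ref}>{snv.alt}"
                else:
                    conv = f"{complement(snv.ref)}>{complement(snv.alt)}"
                if conv == conversion:
                    best = max(best, snv.allele_frequency)
            if best > hi:
                matrix.loc[plant.sample_id, sid] = "biallelic"
            elif best > lo:
                matrix.loc[plant.sample_id, sid] = "edited"
    return matrix


@dataclass
class MotifMatrix:
    """Flanking-context base frequencies around mutated bases.

    Positions 1..3 with the mutated base at position 2; ``information`` is
    the per-position information content R = 2 - H in bits (no small-sample
    correction).
    """

    frequencies: pd.DataFrame  # index 1..3, columns A,C,G,T
    information: pd.Series  # bits per position
    n_used: int
    n_skipped: int


def motif_context(snvs: Iterable[SNVRecord], genome: Mapping[str, str]) -> MotifMatrix:
    """3-mer sequence context of SNVs, oriented onto the deaminated strand.

    Each SNV contributes the genomic 3-mer centered on its mutated base,
    reported on the strand where that base is a C (for C>T / G>A calls) or
    an A (for A>G / T>C calls) — i.e. purine-anchored C>T-class calls and
    pyrimidine-anchored A>G-class calls are reverse-complemented.  SNVs at
    a chromosome edge lacking a full flank are skipped and counted.
    """
    contexts: list[str] = []
    n_skipped = 0
    chroms = {name: str(seq).upper() for name, seq in genome.items()}
    for snv in snvs:
        seq = chroms[snv.chrom]
        idx = snv.pos - 1
        if idx - 1 < 0 or idx + 2 > len(seq):
            n_skipped += 1
            continue
        trimer = seq[idx - 1 : idx + 2]
        # orient so the mutated base reads as the deaminated C or A
        if snv.ref in "GT":
            trimer = revcomp(trimer)
        contexts.append(trimer)
    if not contexts:
        raise ValueError("no SNV with a full flanking context")
    counts = np.zeros((3, 4))
    for trimer in contexts:
        for i, base in enumerate(trimer):
            counts[i, _BASES.index(base)] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    info = []
    for row in freqs:
        entropy = -sum(f * math.log2(f) for f in row if f > 0)
        info.append(2.0 - entropy)
    return MotifMatrix(
        frequencies=pd.DataFrame(freqs, index=[1, 2, 3], columns=list(_BASES)),
        information=pd.Series(info, index=[1, 2, 3]),
        n_used=len(contexts),
        n_skipped=n_skipped,
    )
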