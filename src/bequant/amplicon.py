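"""Read-level base-editing outcome classification and site quantification.

Each amplicon read is aligned to its target amplicon, classified into one
of the outcome classes (WT, C-to-T, A-to-G, simultaneous C-to-T + A-to-G,
C-to-G, other substitution, indel), and the retained reads are summarized
into per-protospacer-position conversion efficiencies, site-level
efficiencies, an indel frequency, and a ranked allele (genotype) table.

Conventions
-----------
* Substitution efficiencies and the indel frequency are separate
  quantities: per-position and site-level efficiencies are computed over
  *informative* reads (aligned, gap-free over the protospacer + PAM), while
  the indel frequency is indel reads over all retained reads.
* A read carrying both a C-to-T and an A-to-G edit counts once in the
  SIMULTANEOUS class tally but contributes to both the per-position C>T
  and A>G numerators, keeping per-position profiles marginal while class
  tallies partition the reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align

from .sites import PROTOSPACER_LEN, TargetSite, complement

#: outcome classes in precedence order (INDEL checked first, WT is the default)
OUTCOME_CLASSES = ("WT", "C_TO_T", "A_TO_G", "SIMULTANEOUS", "C_TO_G", "OTHER_SUB", "INDEL")

#: conversions tracked per position
TRACKED_CONVERSIONS = ("C>T", "A>G", "C>G")

#: alignment scoring: match +2, mismatch -1, gap open -6, gap extend -1
_ALIGNER = Align.PairwiseAligner()
_ALIGNER.mode = "global"
_ALIGNER.match_score = 2
_ALIGNER.mismatch_score = -1
_ALIGNER.open_gap_score = -6
_ALIGNER.extend_gap_score = -1

DEFAULT_MIN_IDENTITY = 0.6


def outcome_class(conversions: Iterable[tuple[int, str]], has_indel: bool) -> str:
    """Outcome class of a read from its conversion set and indel status.

    Precedence: INDEL, then SIMULTANEOUS (at least one C>T and one A>G),
    C_TO_T, A_TO_G, C_TO_G, OTHER_SUB, WT.
    """
    if has_indel:
        return "INDEL"
    kinds = {conv for _, conv in conversions}
    if "C>T" in kinds and "A>G" in kinds:
        return "SIMULTANEOUS"
    if "C>T" in kinds:
        return "C_TO_T"
    if "A>G" in kinds:
        return "A_TO_G"
    if "C>G" in kinds:
        return "C_TO_G"
    if kinds:
        return "OTHER_SUB"
    return "WT"


@dataclass
class ReadAlignment:
    """A read globally aligned to the amplicon.

    ``bases`` holds, for every amplicon position, the aligned read base
    ('-' where the read has a deletion); ``gaps`` holds (kind, start,
    length) records in amplicon coordinates, kind 'del' (gap in read) or
    'ins' (extra read bases between two amplicon positions, anchored at
    ``start``).
    """

    read_id: str
    identity: float
    bases: str
    gaps: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class ReadOutcome:
    """Classified outcome of one retained read."""

    read_id: str
    outcome: str
    edited_positions: frozenset[tuple[int, str]]
    allele: str | None  # protospacer-region sequence as read; None for indel reads


def align_read(read: str, site: TargetSite, read_id: str = "read",
               min_identity: float = DEFAULT_MIN_IDENTITY) -> ReadAlignment | None:
    """Globally align a read to the site's amplicon.

    Length-preserving reads that already meet the identity floor are mapped
    gaplessly; anything else goes through affine-gap global alignment
    (match +2, mismatch -1, gap open -6, gap extend -1).  Identity is
    matched bases over the amplicon length.  Reads below ``min_identity``
    are discarded (``None``), to be counted by the caller.
    """
    if not read:
        raise ValueError("empty read")
    read = read.upper()
    amp = site.amplicon
    if len(read) == len(amp):
        matches = sum(1 for a, b in zip(read, amp) if a == b)
        identity = matches / len(amp)
        if identity >= min_identity:
            return ReadAlignment(read_id=read_id, identity=identity, bases=read)
    aln = _ALIGNER.align(amp, read)[0]
    target_blocks, query_blocks = aln.aligned
    bases = ["-"] * len(amp)
    gaps: list[tuple[str, int, int]] = []
    matches = 0
    prev_te = prev_qe = 0
    for (ts, te), (qs, qe) in zip(target_blocks, query_blocks):
        if ts > prev_te:
            gaps.append(("del", prev_te, ts - prev_te))
        if qs > prev_qe:
            gaps.append(("ins", ts, qs - prev_qe))
        for k in range(te - ts):
            bases[ts + k] = read[qs + k]
            if read[qs + k] == amp[ts + k]:
                matches += 1
        prev_te, prev_qe = te, qe
    if prev_te < len(amp):
        gaps.append(("del", prev_te, len(amp) - prev_te))
    if prev_qe < len(read):
        gaps.append(("ins", len(amp), len(read) - prev_qe))
    identity = matches / len(amp)
    if identity < min_identity:
        return None
    return ReadAlignment(read_id=read_id, identity=identity, bases="".join(bases), gaps=gaps)


def _gap_overlaps(gap: tuple[str, int, int], lo: int, hi: int) -> bool:
    kind, start, length = gap
    if kind == "del":
        return start < hi and start + length > lo
    # insertion: a point event between amplicon positions start-1 and start;
    # it disrupts the footprint only when strictly inside it
    return lo < start < hi


def classify_read(aln: ReadAlignment, site: TargetSite) -> ReadOutcome:
    """Classify an aligned read into a base-editing outcome.

    Any alignment gap overlapping the protospacer + PAM footprint makes the
    read an INDEL.  Otherwise substitutions are collected over protospacer
    positions 1..20 in protospacer-strand orientation.
    """
    lo, hi = site.footprint
    if any(_gap_overlaps(gap, lo, hi) for gap in aln.gaps):
        return ReadOutcome(read_id=aln.read_id, outcome="INDEL",
                           edited_positions=frozenset(), allele=None)
    edits: set[tuple[int, str]] = set()
    allele_chars = []
    for pos in range(1, PROTOSPACER_LEN + 1):
        idx = site.amplicon_index(pos)
        base = aln.bases[idx]
        if site.strand == "-":
            base = complement(base)
        allele_chars.append(base)
        ref = site.protospacer[pos - 1]
        if base != ref and base in "ACGT":
            edits.add((pos, f"{ref}>{base}"))
    return ReadOutcome(
        read_id=aln.read_id,
        outcome=outcome_class(edits, has_indel=False),
        edited_positions=frozenset(edits),
        allele="".join(allele_chars),
    )


def process_reads(reads: Sequence[str], site: TargetSite,
                  read_ids: Sequence[str] | None = None,
                  min_identity: float = DEFAULT_MIN_IDENTITY,
                  ) -> tuple[list[ReadOutcome], int]:
    """Align and classify a batch of reads; returns (outcomes, n_discarded)."""
    if read_ids is None:
        read_ids = [f"read{i}" for i in range(len(reads))]
    outcomes: list[ReadOutcome] = []
    n_discarded = 0
    for read, rid in zip(reads, read_ids):
        aln = align_read(read, site, read_id=rid, min_identity=min_identity)
        if aln is None:
            n_discarded += 1
            continue
        outcomes.append(classify_read(aln, site))
    return outcomes, n_discarded


@dataclass
class PositionProfile:
    """Per-protospacer-position conversion efficiencies for one site.

    ``table`` has one row per (position, conversion) where the reference
    base admits the conversion, with edited counts, the informative-read
    denominator, and the efficiency.
    """

    site_id: str
    reference: str  # the 20-nt protospacer
    table: pd.DataFrame  # columns: position, ref_base, conversion, edited, informative, efficiency

    def efficiency(self, position: int, conversion: str) -> float:
        rows = self.table[(self.table.position == position)
                          & (self.table.conversion == conversion)]
        if rows.empty:
            raise KeyError(f"position {position} does not admit {conversion}")
        return float(rows.efficiency.iloc[0])


@dataclass
class AlleleTable:
    """Ranked read-level genotypes (protospacer-region alleles) for one site."""

    site_id: str
    reference: str
    counts: dict[str, int]
    total: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{"allele": a, "count": c, "ratio": c / self.total,
                 "is_reference": a == self.reference}
                for a, c in self.counts.items()]
        frame = pd.DataFrame(rows)
        return frame.sort_values(["count", "allele"],
                                 ascending=[False, True]).reset_index(drop=True)


@dataclass
class SiteQuantification:
    """Full quantification of one target site."""

    site_id: str
    position_profile: PositionProfile
    allele_table: AlleleTable
    summary: dict


class EmptyResultError(ValueError):
    """No retained reads to quantify."""


def quantify_site(outcomes: Sequence[ReadOutcome], site: TargetSite,
                  n_discarded: int = 0) -> SiteQuantification:
    """Summarize classified reads for one site.

    Per-position efficiency = edited / informative reads; site-level
    C-to-T (A-to-G, C-to-G) efficiency = fraction of informative reads
    carrying at least one such conversion anywhere in the protospacer;
    indel frequency = INDEL reads / all retained reads.  Both the
    read-fraction site efficiency (the headline number) and the maximum
    per-position efficiency are reported.
    """
    if not outcomes:
        raise EmptyResultError(f"site {site.site_id}: no retained reads")
    informative = [o for o in outcomes if o.outcome != "INDEL"]
    n_indel = len(outcomes) - len(informative)
    n_info = len(informative)

    rows = []
    for pos in range(1, PROTOSPACER_LEN + 1):
        ref = site.protospacer[pos - 1]
        for conv in TRACKED_CONVERSIONS:
            if conv[0] != ref:
                continue
            edited = sum(1 for o in informative if (pos, conv) in o.edited_positions)
            rows.append({
                "position": pos, "ref_base": ref, "conversion": conv,
                "edited": edited, "informative": n_info,
                "efficiency": edited / n_info if n_info else float("nan"),
            })
    profile = PositionProfile(site_id=site.site_id, reference=site.protospacer,
                              table=pd.DataFrame(rows))

    counts: dict[str, int] = {}
    for o in informative:
        assert o.allele is not None
        counts[o.allele] = counts.get(o.allele, 0) + 1
    table = AlleleTable(site_id=site.site_id, reference=site.protospacer,
                        counts=counts, total=n_info)

    class_counts = {cls: 0 for cls in OUTCOME_CLASSES}
    for o in outcomes:
        class_counts[o.outcome] += 1

    def site_eff(conv: str) -> float:
        if n_info == 0:
            return float("nan")
        return sum(1 for o in informative
                   if any(c == conv for _, c in o.edited_positions)) / n_info

    max_eff = {conv: (profile.table[profile.table.conversion == conv].efficiency.max()
                      if (profile.table.conversion == conv).any() else 0.0)
               for conv in TRACKED_CONVERSIONS}
    summary = {
        "site_id": site.site_id,
        "n_reads": len(outcomes) + n_discarded,
        "n_discarded": n_discarded,
        "n_retained": len(outcomes),
        "n_informative": n_info,
        "n_indel": n_indel,
        "class_counts": class_counts,
        "c_to_t_efficiency": site_eff("C>T"),
        "a_to_g_efficiency": site_eff("A>G"),
        "c_to_g_efficiency": site_eff("C>G"),
        "simultaneous_fraction": class_counts["SIMULTANEOUS"] / n_info if n_info else float("nan"),
        "max_position_efficiency": {k: float(v) for k, v in max_eff.items()},
        "indel_frequency": n_indel / len(outcomes),
    }
    return SiteQuantification(site_id=site.site_id, position_profile=profile,
                              allele_table=table, summary=summary)


def top_alleles(table: AlleleTable, k: int) -> list[tuple[str, int, float, bool]]:
    """Top-k alleles by read count (ties broken lexicographically).

    Returns (allele, count, ratio, is_reference) tuples.  The reference
    allele is flagged, and appended after the top k if it did not rank.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    out = [(a, c, c / table.total, a == table.reference) for a, c in ranked[:k]]
    if table.reference in table.counts and not any(row[3] for row in out):
        c = table.counts[table.reference]
        out.append((table.reference, c, c / table.total, True))
    return out
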