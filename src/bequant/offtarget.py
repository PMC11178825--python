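"""gRNA-dependent off-target candidate enumeration and SNV attribution.

Enumerates every genomic locus, on both strands, whose 20-nt window lies
within a Hamming-distance budget of a gRNA protospacer and is followed by
a matching PAM (SpCas9 geometry: PAM immediately 3' of the protospacer on
the protospacer strand).  Observed SNVs are then attributed to candidate
intervals, with conversions resolved onto the protospacer strand, so that
e.g. a genomic G>A under a minus-strand candidate is reported as a C>T
editing event at the complementary protospacer position.

Bulge-tolerant (gapped) search is out of scope: the screen is mismatch-only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .sites import IUPAC_CODES, PAM_LEN, PROTOSPACER_LEN, TargetSite, complement, revcomp

if TYPE_CHECKING:  # pragma: no cover
    from .variants import SNVRecord

_ACGT = frozenset("ACGT")

# conversions a C-to-T / A-to-G / dual deaminase can produce on the
# protospacer strand (C>G is the documented by-product channel)
CONSISTENT_CONVERSIONS = frozenset({"C>T", "A>G", "C>G"})


def count_mismatches(a: str, b: str) -> int:
    """Hamming distance between equal-length sequences, case-insensitive.

    Any non-ACGT base (in either sequence) counts as a mismatch, even when
    the two characters are equal.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    a = a.upper()
    b = b.upper()
    return sum(1 for x, y in zip(a, b) if x != y or x not in _ACGT or y not in _ACGT)


def pam_match(seq: str, pattern: str) -> bool:
    """True iff each base of ``seq`` is in the IUPAC class of ``pattern``.

    The relaxed "NG" PAM of Cas9-NG is expressed as the 3-nt pattern "NGN".
    """
    if len(seq) != PAM_LEN or len(pattern) != PAM_LEN:
        raise ValueError("PAM sequence and pattern must both be 3 nt")
    pattern = pattern.upper()
    seq = seq.upper()
    for sym in pattern:
        if sym not in IUPAC_CODES:
            raise ValueError(f"non-IUPAC symbol {sym!r} in PAM pattern")
    return all(base in IUPAC_CODES[sym] for base, sym in zip(seq, pattern))


@dataclass(frozen=True, order=True)
class CandidateSite:
    """A genomic protospacer match under the mismatch budget.

    ``start``/``end`` are 0-based half-open protospacer coordinates;
    ``sequence`` and ``pam`` are reported in protospacer-strand orientation.
    ``is_on_target`` flags perfect (0-mismatch) matches, which include the
    gRNA's own locus.
    """

    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    mismatch_count: int
    pam: str
    source_grna: str

    @property
    def is_on_target(self) -> bool:
        return self.mismatch_count == 0

    def protospacer_position(self, pos_1based: int) -> int:
        """Protospacer position (1..20) of a genomic 1-based coordinate."""
        idx = pos_1based - 1
        if not self.start <= idx < self.end:
            raise ValueError("coordinate outside candidate interval")
        if self.strand == "+":
            return idx - self.start + 1
        return self.end - idx


def _pam_ok_vector(arr: np.ndarray, pattern: str, n_windows: int) -> np.ndarray:
    """Boolean vector: PAM at arr[i+20 : i+23] matches pattern, for i < n_windows."""
    ok = np.ones(n_windows, dtype=bool)
    for j, sym in enumerate(pattern):
        allowed = np.frombuffer("".join(sorted(IUPAC_CODES[sym])).encode(), dtype=np.uint8)
        col = arr[PROTOSPACER_LEN + j : PROTOSPACER_LEN + j + n_windows]
        ok &= np.isin(col, allowed)
    return ok


def _scan_strand(seq: str, proto: str, max_mm: int, pattern: str) -> list[tuple[int, int]]:
    """(start, n_mismatches) for every window of ``seq`` within budget + PAM."""
    n_windows = len(seq) - PROTOSPACER_LEN - PAM_LEN + 1
    if n_windows <= 0:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    proto_arr = np.frombuffer(proto.encode(), dtype=np.uint8)
    windows = sliding_window_view(arr, PROTOSPACER_LEN)[:n_windows]
    mm = (windows != proto_arr).sum(axis=1)
    hit = (mm <= max_mm) & _pam_ok_vector(arr, pattern, n_windows)
    return [(int(i), int(mm[i])) for i in np.nonzero(hit)[0]]


def enumerate_sites(
    genome: Mapping[str, str],
    grnas: Sequence[TargetSite | tuple[str, str]],
    max_mm: int = 3,
    pam_pattern: str = "NGG",
) -> list[CandidateSite]:
    """Enumerate candidate protospacer matches on both strands of a genome.

    Parameters
    ----------
    genome
        Mapping of chromosome name to sequence.
    grnas
        Target sites, or plain ``(site_id, protospacer)`` pairs.
    max_mm
        Mismatch budget (0..6); the study screened at <= 3.
    pam_pattern
        3-nt IUPAC PAM constraint applied at candidate loci (default NGG;
        relaxed NG search uses "NGN").

    Candidates are deduplicated and sorted by (chrom, start, strand).
    """
    if not 0 <= max_mm <= 6:
        raise ValueError("mismatch budget must be within 0..6")
    pairs = []
    for g in grnas:
        if isinstance(g, TargetSite):
            pairs.append((g.site_id, g.protospacer))
        else:
            site_id, proto = g
            pairs.append((site_id, proto.upper()))
    for _, proto in pairs:
        if len(proto) != PROTOSPACER_LEN or set(proto) - _ACGT:
            raise ValueError("gRNA protospacers must be 20 nt of ACGT")
    chroms = {name: str(seq).upper() for name, seq in genome.items()}
    if all(len(seq) < PROTOSPACER_LEN + PAM_LEN for seq in chroms.values()):
        raise ValueError("no chromosome long enough to hold protospacer + PAM")

    found: set[CandidateSite] = set()
    for chrom, seq in chroms.items():
        length = len(seq)
        rc = revcomp(seq)
        for site_id, proto in pairs:
            for start, mm in _scan_strand(seq, proto, max_mm, pam_pattern):
                found.add(CandidateSite(
                    chrom=chrom, start=start, end=start + PROTOSPACER_LEN, strand="+",
                    sequence=seq[start : start + PROTOSPACER_LEN],
                    mismatch_count=mm,
                    pam=seq[start + PROTOSPACER_LEN : start + PROTOSPACER_LEN + PAM_LEN],
                    source_grna=site_id,
                ))
            for i, mm in _scan_strand(rc, proto, max_mm, pam_pattern):
                start = length - (i + PROTOSPACER_LEN)
                found.add(CandidateSite(
                    chrom=chrom, start=start, end=start + PROTOSPACER_LEN, strand="-",
                    sequence=rc[i : i + PROTOSPACER_LEN],
                    mismatch_count=mm,
                    pam=rc[i + PROTOSPACER_LEN : i + PROTOSPACER_LEN + PAM_LEN],
                    source_grna=site_id,
                ))
    return sorted(found, key=lambda c: (c.chrom, c.start, c.strand, c.source_grna))


@dataclass(frozen=True)
class AttributionResult:
    """An SNV placed inside a candidate site, strand-resolved.

    ``conversion`` is the ref>alt pair as seen on the protospacer strand;
    ``consistent`` is True when the conversion is one a base editor produces
    (C>T, A>G, or the C>G by-product).
    """

    snv: "SNVRecord"
    candidate: CandidateSite
    position: int
    conversion: str
    consistent: bool


def attribute_snvs(
    snvs: Iterable["SNVRecord"],
    candidates: Sequence[CandidateSite],
) -> list[AttributionResult]:
    """Attribute SNVs overlapping candidate intervals to those candidates.

    Each SNV that falls inside a candidate's protospacer interval yields one
    result per overlapped candidate.  SNVs outside every interval yield none.
    """
    by_chrom: dict[str, list[CandidateSite]] = {}
    for cand in candidates:
        by_chrom.setdefault(cand.chrom, []).append(cand)
    results: list[AttributionResult] = []
    for snv in snvs:
        for cand in by_chrom.get(snv.chrom, ()):
            idx = snv.pos - 1
            if not cand.start <= idx < cand.end:
                continue
            position = cand.protospacer_position(snv.pos)
            if cand.strand == "+":
                conversion = f"{snv.ref}>{snv.alt}"
            else:
                conversion = f"{complement(snv.ref)}>{complement(snv.alt)}"
            results.append(AttributionResult(
                snv=snv, candidate=cand, position=position,
                conversion=conversion,
                consistent=conversion in CONSISTENT_CONVERSIONS,
            ))
    return results
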