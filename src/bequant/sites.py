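"""Target-site model and protospacer geometry.

A target site is one PCR amplicon carrying a single 20-nt protospacer
followed by a PAM (NGG for SpCas9, NGN for the relaxed Cas9-NG variant).
Protospacer positions are numbered 1 (PAM-distal, 5') to 20 (PAM-proximal);
the PAM occupies positions 21-23.  Editing windows are intervals in that
coordinate system (e.g. positions 4-8 for TadA-8e derived deaminases).
"""

from __future__ import annotations

from dataclasses import dataclass, field

PROTOSPACER_LEN = 20
PAM_LEN = 3

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# IUPAC ambiguity codes, used for PAM patterns.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N passed through)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


class ProtospacerNotFoundError(ValueError):
    """The protospacer does not occur on either strand of the amplicon."""


class AmbiguousProtospacerError(ValueError):
    """The protospacer occurs more than once across the two strands."""


def locate_protospacer(amplicon: str, protospacer: str) -> tuple[int, str]:
    """Find the unique occurrence of a protospacer on either strand.

    Returns ``(offset, strand)`` where ``offset`` is the 0-based start of
    the protospacer-matching block on the amplicon.  For the minus strand
    the block contains the reverse complement of the protospacer.

    Raises
    ------
    ProtospacerNotFoundError
        if the protospacer occurs on neither strand.
    AmbiguousProtospacerError
        if it occurs more than once in total.
    """
    if len(amplicon) < PROTOSPACER_LEN + PAM_LEN:
        raise ValueError("amplicon shorter than protospacer + PAM")
    amplicon = amplicon.upper()
    protospacer = protospacer.upper()
    hits: list[tuple[int, str]] = []
    queries = [("+", protospacer)]
    rc = revcomp(protospacer)
    if rc != protospacer:
        queries.append(("-", rc))
    for strand, query in queries:
        start = amplicon.find(query)
        while start != -1:
            hits.append((start, strand))
            start = amplicon.find(query, start + 1)
    if not hits:
        raise ProtospacerNotFoundError(
            f"protospacer {protospacer!r} not found on either strand of amplicon"
        )
    if len(hits) > 1:
        raise AmbiguousProtospacerError(
            f"protospacer {protospacer!r} occurs {len(hits)} times on the amplicon"
        )
    return hits[0]


@dataclass(frozen=True)
class TargetSite:
    """One amplicon / protospacer / PAM locus with its editing window.

    ``offset`` is the 0-based start of the protospacer-matching block on
    the amplicon.  On the minus strand that block holds revcomp(protospacer)
    and the (revcomp'ed) PAM sits immediately 5' of it on the amplicon.
    """

    site_id: str
    amplicon: str
    protospacer: str
    pam_pattern: str = "NGG"
    strand: str = "+"
    offset: int = 0
    window: tuple[int, int] = (1, 20)

    def __post_init__(self) -> None:
        object.__setattr__(self, "amplicon", self.amplicon.upper())
        object.__setattr__(self, "protospacer", self.protospacer.upper())
        object.__setattr__(self, "pam_pattern", self.pam_pattern.upper())
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError("protospacer must be 20 nt")
        if len(self.pam_pattern) != PAM_LEN:
            raise ValueError("PAM pattern must be 3 nt")
        if any(sym not in IUPAC_CODES for sym in self.pam_pattern):
            raise ValueError(f"non-IUPAC symbol in PAM pattern {self.pam_pattern!r}")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        lo, hi = self.window
        if not (1 <= lo <= hi <= 20):
            raise ValueError("window must be an interval within 1..20")
        block = self.amplicon[self.offset : self.offset + PROTOSPACER_LEN]
        expected = self.protospacer if self.strand == "+" else revcomp(self.protospacer)
        if block != expected:
            raise ValueError(
                f"protospacer does not occur at offset {self.offset} "
                f"on strand {self.strand} of the amplicon"
            )

    # ---- protospacer coordinate arithmetic -------------------------------

    def amplicon_index(self, position: int) -> int:
        """0-based amplicon index of protospacer position ``position`` (1..20)."""
        if not 1 <= position <= PROTOSPACER_LEN:
            raise ValueError("protospacer positions run 1..20")
        if self.strand == "+":
            return self.offset + position - 1
        return self.offset + PROTOSPACER_LEN - position

    @property
    def pam_interval(self) -> tuple[int, int]:
        """0-based half-open amplicon interval of the PAM."""
        if self.strand == "+":
            return (self.offset + PROTOSPACER_LEN, self.offset + PROTOSPACER_LEN + PAM_LEN)
        return (self.offset - PAM_LEN, self.offset)

    @property
    def pam(self) -> str:
        """Observed PAM, reported on the protospacer strand."""
        lo, hi = self.pam_interval
        seq = self.amplicon[max(lo, 0) : hi]
        return seq if self.strand == "+" else revcomp(seq)

    @property
    def footprint(self) -> tuple[int, int]:
        """0-based half-open amplicon interval covering protospacer + PAM."""
        if self.strand == "+":
            return (self.offset, self.offset + PROTOSPACER_LEN + PAM_LEN)
        return (self.offset - PAM_LEN, self.offset + PROTOSPACER_LEN)
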