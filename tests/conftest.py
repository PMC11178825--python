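import pytest

from bequant.sites import TargetSite, revcomp

# hand-built protospacer: C at positions 4,5,10,14,18; A at 2,6,8,13,17
HAND_PROTO = "GATCCATAGCTGACGTACGT"
PREFIX = "TTGAGCTAGCTAGGATTTCAGGACTCTTGG"
SUFFIX = "CCTTGAGATTCACCTGGTGAACGATT"


@pytest.fixture(scope="session")
def hand_site() -> TargetSite:
    """A fixed plus-strand site with known base layout, PAM AGG."""
    amplicon = PREFIX + HAND_PROTO + "AGG" + SUFFIX
    return TargetSite(site_id="hand", amplicon=amplicon, protospacer=HAND_PROTO,
                      pam_pattern="NGG", strand="+", offset=len(PREFIX),
                      window=(4, 8))


@pytest.fixture(scope="session")
def hand_site_minus() -> TargetSite:
    """The same locus with the protospacer on the minus strand."""
    amplicon = PREFIX + revcomp(HAND_PROTO + "AGG") + SUFFIX
    return TargetSite(site_id="hand-minus", amplicon=amplicon,
                      protospacer=HAND_PROTO, pam_pattern="NGG", strand="-",
                      offset=len(PREFIX) + 3, window=(4, 8))


def mutate(seq: str, index0: int, base: str) -> str:
    return seq[:index0] + base + seq[index0 + 1:]
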