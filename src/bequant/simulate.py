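"""Synthetic data with known truth, emulating base-editing study designs.

Generates (i) targeted amplicon read sets for protoplast-style editing
experiments, (ii) toy genomes with planted off-target protospacer matches,
and (iii) regenerated-plant variant cohorts with planted on/off-target
edits plus Poisson background somaclonal SNVs drawn from a six-type
spectrum and a subclonal/heterozygous/homozygous allele-frequency mixture.

Every generator takes one explicit seed and is byte-deterministic for a
given (parameters, seed) pair; every planted record is returned in a truth
registry that round-trips through JSON.

Default magnitudes mirror the emulated study design: ~250-bp amplicons, an
editing window at protospacer positions 4-8, indel rates at the sequencing
error floor, and ~200 background SNVs / ~60 indels per plant.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .amplicon import outcome_class
from .offtarget import CandidateSite, count_mismatches, enumerate_sites, pam_match
from .sites import IUPAC_CODES, PAM_LEN, PROTOSPACER_LEN, TargetSite, complement, revcomp
from .variants import (SNV_CLASSES, ZYGOSITY_CLASSES, IndelRecord, PlantVariantSet,
                       SNVRecord, call_zygosity)

_BASES = "ACGT"
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
# byte -> 0..3 code lookup
_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

DEFAULT_AMPLICON_LENGTH = 250  # the study amplified ~250 bp around each target
DEFAULT_WINDOW = (4, 8)  # TadA-8e style editing window


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASE_BYTES[rng.integers(0, 4, size=n)].tobytes().decode()


def _concrete_pam(rng: np.random.Generator, pattern: str) -> str:
    return "".join(sorted(IUPAC_CODES[sym])[rng.integers(0, len(IUPAC_CODES[sym]))]
                   for sym in pattern.upper())


# ---------------------------------------------------------------------------
# editing profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EditingProfile:
    """Generative per-position conversion probabilities for one editor.

    Keys of the conversion maps are protospacer positions 1..20.  Under
    ``cooccurrence='linked'`` a single uniform draw per read gates all
    conversions jointly (comonotone coupling: position i converts iff
    u < p_i), which preserves every marginal rate while making window
    edits co-occur on the same reads, as a dual deaminase does.
    """

    c_to_t: Mapping[int, float] = field(default_factory=dict)
    a_to_g: Mapping[int, float] = field(default_factory=dict)
    c_to_g: Mapping[int, float] = field(default_factory=dict)
    cooccurrence: str = "independent"
    indel_rate: float = 0.0
    seq_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.cooccurrence not in ("independent", "linked"):
            raise ValueError("cooccurrence must be 'independent' or 'linked'")
        for name, rate in (("indel_rate", self.indel_rate),
                           ("seq_error_rate", self.seq_error_rate)):
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for conv, probs in self.conversions().items():
            for pos, p in probs.items():
                if not 1 <= pos <= PROTOSPACER_LEN:
                    raise ValueError(f"{conv}: position {pos} outside 1..20")
                if not 0 <= p <= 1:
                    raise ValueError(f"{conv}[{pos}]={p} outside [0, 1]")
        # per position, conversion probabilities of the same source base sum <= 1
        for pos in range(1, PROTOSPACER_LEN + 1):
            total = self.c_to_t.get(pos, 0) + self.c_to_g.get(pos, 0)
            if total > 1 + 1e-12:
                raise ValueError(f"position {pos}: C>T + C>G probability exceeds 1")

    def conversions(self) -> dict[str, Mapping[int, float]]:
        return {"C>T": self.c_to_t, "A>G": self.a_to_g, "C>G": self.c_to_g}

    def validate_for(self, site: TargetSite) -> None:
        """Reject probabilities assigned to positions lacking the source base."""
        for conv, probs in self.conversions().items():
            for pos, p in probs.items():
                if p > 0 and site.protospacer[pos - 1] != conv[0]:
                    raise ValueError(
                        f"{conv} probability at position {pos}, but site "
                        f"{site.site_id} carries {site.protospacer[pos - 1]} there"
                    )

    @classmethod
    def window_profile(cls, site: TargetSite, c_to_t: float = 0.0,
                       a_to_g: float = 0.0, c_to_g: float = 0.0,
                       window: tuple[int, int] | None = None,
                       **kwargs) -> "EditingProfile":
        """Uniform conversion rates at eligible bases within a window."""
        lo, hi = window if window is not None else site.window
        maps: dict[str, dict[int, float]] = {"C>T": {}, "A>G": {}, "C>G": {}}
        for conv, rate in (("C>T", c_to_t), ("A>G", a_to_g), ("C>G", c_to_g)):
            if rate == 0:
                continue
            for pos in range(lo, hi + 1):
                if site.protospacer[pos - 1] == conv[0]:
                    maps[conv][pos] = rate
        return cls(c_to_t=maps["C>T"], a_to_g=maps["A>G"], c_to_g=maps["C>G"], **kwargs)


@dataclass
class ReadTruth:
    read_id: str
    outcome: str
    conversions: list[tuple[int, str]]
    has_indel: bool


@dataclass
class SimTruth:
    """Ground truth for one simulated amplicon read set."""

    site_id: str
    rates: dict[str, dict[int, float]]
    reads: list[ReadTruth]

    def to_json(self) -> str:
        return json.dumps({
            "site_id": self.site_id,
            "rates": {conv: {str(k): v for k, v in probs.items()}
                      for conv, probs in self.rates.items()},
            "reads": [{"read_id": r.read_id, "outcome": r.outcome,
                       "conversions": [list(c) for c in r.conversions],
                       "has_indel": r.has_indel} for r in self.reads],
        }, indent=0, sort_keys=True)


# ---------------------------------------------------------------------------
# amplicon-level simulation
# ---------------------------------------------------------------------------

def make_target_site(seed: int, amplicon_length: int = DEFAULT_AMPLICON_LENGTH,
                     pam_pattern: str = "NGG", protospacer: str | None = None,
                     strand: str = "+", window: tuple[int, int] = DEFAULT_WINDOW,
                     site_id: str | None = None) -> TargetSite:
    """Random amplicon containing exactly one protospacer + PAM.

    Deterministic in (arguments, seed).  The protospacer may be supplied
    (e.g. to control base composition at window positions) or drawn at
    random; uniqueness of the protospacer across both strands of the
    amplicon is verified, redrawing the background on the rare collision.
    """
    if amplicon_length < PROTOSPACER_LEN + PAM_LEN + 17:  # >= 40 per contract
        raise ValueError("amplicon_length must be >= 40")
    if len(pam_pattern) != PAM_LEN:
        raise ValueError("PAM pattern must be 3 nt")
    rng = np.random.default_rng(seed)
    proto = (protospacer or _random_dna(rng, PROTOSPACER_LEN)).upper()
    footprint = PROTOSPACER_LEN + PAM_LEN
    for _ in range(100):
        pam = _concrete_pam(rng, pam_pattern)
        insert = proto + pam
        if strand == "-":
            insert = revcomp(insert)
        start = int(rng.integers(0, amplicon_length - footprint + 1))
        background = _random_dna(rng, amplicon_length)
        amplicon = background[:start] + insert + background[start + footprint:]
        offset = start if strand == "+" else start + PAM_LEN
        try:
            found_offset, found_strand = _locate_unique(amplicon, proto)
        except ValueError:
            continue
        if (found_offset, found_strand) == (offset, strand):
            return TargetSite(
                site_id=site_id or f"site_{seed}",
                amplicon=amplicon, protospacer=proto, pam_pattern=pam_pattern,
                strand=strand, offset=offset, window=window,
            )
    raise RuntimeError("could not place a unique protospacer (pathological input)")


def _locate_unique(amplicon: str, protospacer: str) -> tuple[int, str]:
    from .sites import locate_protospacer
    return locate_protospacer(amplicon, protospacer)


def simulate_amplicon_reads(site: TargetSite, profile: EditingProfile,
                            n_reads: int, seed: int,
                            ) -> tuple[list[str], list[str], SimTruth]:
    """Simulate pre-merged single-end amplicon reads.

    Conversions are applied only at protospacer positions carrying the
    required reference base (validated up front), then per-read indels
    (1-5 bp, uniform, anchored inside the protospacer), then uniform
    substitution sequencing errors.  Returns (reads, read_ids, truth);
    truth labels reflect the applied conversions and indels, not
    subsequent sequencing errors.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    profile.validate_for(site)
    rng = np.random.default_rng(seed)
    amp = site.amplicon
    length = len(amp)

    # flatten conversion specs into amplicon-coordinate substitutions
    specs: list[tuple[int, str, int, int]] = []  # (pos, conv, amp_idx, new_byte)
    for conv, probs in profile.conversions().items():
        for pos in sorted(probs):
            p = probs[pos]
            if p == 0:
                continue
            idx = site.amplicon_index(pos)
            new_base = conv[2] if site.strand == "+" else complement(conv[2])
            specs.append((pos, conv, idx, ord(new_base)))
    probs_vec = np.array([profile.conversions()[conv][pos]
                          for pos, conv, _, _ in specs], dtype=float)

    mat = np.tile(np.frombuffer(amp.encode(), dtype=np.uint8), (n_reads, 1)).copy()

    if specs:
        if profile.cooccurrence == "linked":
            u = rng.random(n_reads)
            applied = u[:, None] < probs_vec[None, :]
        else:
            applied = rng.random((n_reads, len(specs))) < probs_vec[None, :]
        for j, (_, _, idx, new_byte) in enumerate(specs):
            mat[applied[:, j], idx] = new_byte
    else:
        applied = np.zeros((n_reads, 0), dtype=bool)

    # plan indels (applied after error substitution, on strings)
    indel_reads = np.nonzero(rng.random(n_reads) < profile.indel_rate)[0]
    indel_plans: dict[int, tuple[bool, int, int, str]] = {}
    proto_lo = min(site.amplicon_index(1), site.amplicon_index(PROTOSPACER_LEN))
    for i in indel_reads:
        is_ins = bool(rng.integers(0, 2))
        ilen = int(rng.integers(1, 6))
        anchor = proto_lo + int(rng.integers(0, PROTOSPACER_LEN))
        inserted = _random_dna(rng, ilen) if is_ins else ""
        indel_plans[int(i)] = (is_ins, ilen, anchor, inserted)

    # uniform substitution errors
    if profile.seq_error_rate > 0:
        err = rng.random((n_reads, length)) < profile.seq_error_rate
        idx = np.nonzero(err)
        if idx[0].size:
            shift = rng.integers(1, 4, size=idx[0].size).astype(np.uint8)
            mat[idx] = _BASE_BYTES[(_CODE[mat[idx]] + shift) % 4]

    reads: list[str] = []
    read_ids: list[str] = []
    truths: list[ReadTruth] = []
    for i in range(n_reads):
        s = mat[i].tobytes().decode()
        convs = [(specs[j][0], specs[j][1]) for j in range(len(specs)) if applied[i, j]]
        has_indel = i in indel_plans
        if has_indel:
            is_ins, ilen, anchor, inserted = indel_plans[i]
            s = s[:anchor] + inserted + s[anchor:] if is_ins else s[:anchor] + s[anchor + ilen:]
        rid = f"{site.site_id}:read{i:06d}"
        reads.append(s)
        read_ids.append(rid)
        truths.append(ReadTruth(read_id=rid, outcome=outcome_class(convs, has_indel),
                                conversions=sorted(convs), has_indel=has_indel))
    rates = {conv: dict(probs) for conv, probs in profile.conversions().items() if probs}
    return reads, read_ids, SimTruth(site_id=site.site_id, rates=rates, reads=truths)


# ---------------------------------------------------------------------------
# toy genomes and planted off-target sites
# ---------------------------------------------------------------------------

def make_toy_genome(n_chrom: int, chrom_length: int, seed: int) -> dict[str, str]:
    """Deterministic random genome with uniform base composition."""
    if chrom_length < 1000:
        raise ValueError("chrom_length must be >= 1000")
    rng = np.random.default_rng(seed)
    return {f"chr{i + 1}": _random_dna(rng, chrom_length) for i in range(n_chrom)}


def _footprint(offset: int, strand: str) -> tuple[int, int]:
    if strand == "+":
        return (offset, offset + PROTOSPACER_LEN + PAM_LEN)
    return (offset - PAM_LEN, offset + PROTOSPACER_LEN)


def plant_candidate_sites(
    genome: Mapping[str, str],
    protospacer: str,
    placements: Sequence[tuple[str, int, str, int]],
    pam_pattern: str = "NGG",
    seed: int = 0,
    source_grna: str = "planted",
) -> tuple[dict[str, str], list[CandidateSite]]:
    """Write protospacer-like sequences into a genome at known loci.

    Each placement is ``(chrom, offset, strand, n_mismatches)`` with
    ``offset`` the 0-based protospacer start; the planted sequence sits at
    Hamming distance exactly ``n_mismatches`` from the protospacer
    (mismatch positions drawn from the seed) and is followed by a concrete
    PAM matching ``pam_pattern``; minus-strand placements are written as
    the reverse complement, PAM 5' of the block in genome coordinates.

    Post-hoc verification re-reads every planted locus at its stated
    mismatch count and re-scans the mutated genome to confirm no extra
    exact matches were created.
    """
    protospacer = protospacer.upper()
    if len(protospacer) != PROTOSPACER_LEN:
        raise ValueError("protospacer must be 20 nt")
    rng = np.random.default_rng(seed)
    chroms = {name: str(seq).upper() for name, seq in genome.items()}
    occupied: dict[str, list[tuple[int, int]]] = {}
    registry: list[CandidateSite] = []
    for chrom, offset, strand, n_mm in placements:
        if not 0 <= n_mm <= 6:
            raise ValueError("n_mismatches must lie in 0..6")
        if chrom not in chroms:
            raise ValueError(f"unknown chromosome {chrom!r}")
        lo, hi = _footprint(offset, strand)
        if lo < 0 or hi > len(chroms[chrom]):
            raise ValueError(f"placement {chrom}:{offset}{strand} exceeds chromosome bounds")
        for plo, phi in occupied.get(chrom, ()):
            if lo < phi and hi > plo:
                raise ValueError(f"placement {chrom}:{offset}{strand} overlaps a previous one")
        occupied.setdefault(chrom, []).append((lo, hi))

        seq = list(protospacer)
        mm_positions = sorted(rng.choice(PROTOSPACER_LEN, size=n_mm, replace=False))
        for p in mm_positions:
            alternatives = [b for b in _BASES if b != seq[p]]
            seq[p] = alternatives[rng.integers(0, 3)]
        mutated = "".join(seq)
        pam = _concrete_pam(rng, pam_pattern)
        block = mutated + pam if strand == "+" else revcomp(mutated + pam)
        chroms[chrom] = chroms[chrom][:lo] + block + chroms[chrom][hi:]
        registry.append(CandidateSite(
            chrom=chrom, start=offset, end=offset + PROTOSPACER_LEN, strand=strand,
            sequence=mutated, mismatch_count=n_mm, pam=pam, source_grna=source_grna,
        ))

    # post-hoc verification
    for cand in registry:
        seq = chroms[cand.chrom][cand.start : cand.end]
        observed = seq if cand.strand == "+" else revcomp(seq)
        if count_mismatches(observed, protospacer) != cand.mismatch_count:
            raise RuntimeError("planted site failed mismatch verification")
        if not pam_match(cand.pam, pam_pattern):
            raise RuntimeError("planted PAM failed pattern verification")
    n_exact_expected = sum(1 for c in registry if c.mismatch_count == 0)
    exact = enumerate_sites(chroms, [(source_grna, protospacer)], max_mm=0,
                            pam_pattern=pam_pattern)
    if len(exact) != n_exact_expected:
        raise RuntimeError(
            f"planting created {len(exact)} exact matches, expected {n_exact_expected}"
        )
    return chroms, registry


# ---------------------------------------------------------------------------
# plant cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BackgroundModel:
    """Somaclonal background-variation model for regenerated plants.

    Defaults mirror the emulated study scale: ~200 SNVs and ~60 small
    indels per plant, a six-type spectrum, and an allele-frequency mixture
    in which the heterozygous + homozygous (germline-transmittable) share
    exceeds one half.
    """

    mean_snvs: float = 200.0
    mean_indels: float = 60.0
    spectrum: Mapping[str, float] = field(default_factory=lambda: {
        "C>T": 0.30, "T>C": 0.20, "C>A": 0.12, "C>G": 0.08, "T>A": 0.15, "T>G": 0.15,
    })
    af_mixture: Mapping[str, float] = field(default_factory=lambda: {
        "subclonal": 0.40, "heterozygous": 0.35, "homozygous": 0.25,
    })

    def __post_init__(self) -> None:
        if self.mean_snvs < 0 or self.mean_indels < 0:
            raise ValueError("means must be non-negative")
        if set(self.spectrum) - set(SNV_CLASSES):
            raise ValueError("spectrum keys must be the six pyrimidine-anchored classes")
        if self.spectrum and abs(sum(self.spectrum.values()) - 1) > 1e-9:
            raise ValueError("spectrum must sum to 1")
        if set(self.af_mixture) - set(ZYGOSITY_CLASSES):
            raise ValueError("af_mixture keys must be zygosity classes")
        if self.af_mixture and abs(sum(self.af_mixture.values()) - 1) > 1e-9:
            raise ValueError("af_mixture must sum to 1")


_AF_BANDS = {"subclonal": (0.05, 0.30), "heterozygous": (0.30, 0.70),
             "homozygous": (0.70, 1.00)}


@dataclass
class TruthVariant:
    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    allele_frequency: float
    zygosity: str
    origin: str  # "planted" or "background"
    snv_class: str
    site: str | None = None  # source site_id for planted edits
    position: int | None = None  # protospacer position for planted edits
    conversion: str | None = None  # protospacer-strand conversion for planted edits


@dataclass
class CohortTruth:
    samples: list[str]
    variants: list[TruthVariant]

    def for_sample(self, sample_id: str) -> list[TruthVariant]:
        return [v for v in self.variants if v.sample_id == sample_id]

    def to_json(self) -> str:
        return json.dumps({
            "samples": self.samples,
            "variants": [dataclasses.asdict(v) for v in self.variants],
        }, indent=0, sort_keys=True)


def _edit_coordinates(site: CandidateSite, conversion: str,
                      window: tuple[int, int]) -> tuple[int, int, str, str]:
    """(protospacer position, genomic 0-based index, genome ref, genome alt)."""
    source = conversion[0]
    candidates = [p for p in range(window[0], window[1] + 1)
                  if site.sequence[p - 1] == source]
    if not candidates:
        candidates = [p for p in range(1, PROTOSPACER_LEN + 1)
                      if site.sequence[p - 1] == source]
    if not candidates:
        raise ValueError(
            f"site {site.chrom}:{site.start}{site.strand} has no editable "
            f"{source} for a {conversion} edit"
        )
    pos = candidates[0]
    if site.strand == "+":
        idx = site.start + pos - 1
        ref, alt = conversion[0], conversion[2]
    else:
        idx = site.end - pos
        ref, alt = complement(conversion[0]), complement(conversion[2])
    return pos, idx, ref, alt


def simulate_plant_cohort(
    genome: Mapping[str, str],
    sites: Sequence[CandidateSite],
    edit_spec: Sequence[tuple[str, float] | None],
    background: BackgroundModel,
    n_plants: int,
    seed: int,
    window: tuple[int, int] = DEFAULT_WINDOW,
    exclude_candidate_intervals: bool = True,
    depth: int = 50,
) -> tuple[list[PlantVariantSet], CohortTruth]:
    """Simulate per-plant variant tables with known truth.

    Each plant receives (i) the planted edits given by ``edit_spec`` — one
    ``(conversion, allele_frequency)`` pair or None per site, written with
    strand-resolved genomic ref/alt at the first eligible window position —
    and (ii) Poisson background SNVs from the spectrum with allele
    frequencies from the zygosity mixture, plus background indels at their
    own rate.  Background variants avoid candidate protospacer intervals
    when ``exclude_candidate_intervals`` is set, so attribution truth stays
    clean.
    """
    if len(edit_spec) != len(sites):
        raise ValueError("edit_spec must parallel sites")
    chroms = {name: str(seq).upper() for name, seq in genome.items()}
    names = sorted(chroms)
    lengths = np.array([len(chroms[c]) for c in names], dtype=float)
    chrom_p = lengths / lengths.sum()
    blocked: dict[str, set[int]] = {c: set() for c in names}
    if exclude_candidate_intervals:
        for s in sites:
            blocked.setdefault(s.chrom, set()).update(range(s.start, s.end))
    rng = np.random.default_rng(seed)

    spectrum_classes = list(background.spectrum)
    spectrum_p = np.array([background.spectrum[c] for c in spectrum_classes])
    mix_classes = list(background.af_mixture)
    mix_p = np.array([background.af_mixture[c] for c in mix_classes])

    plants: list[PlantVariantSet] = []
    truth_rows: list[TruthVariant] = []
    samples = [f"plant{i + 1:03d}" for i in range(n_plants)]
    for sample_id in samples:
        snvs: list[SNVRecord] = []
        indels: list[IndelRecord] = []
        used: set[tuple[str, int]] = set()

        for site, spec in zip(sites, edit_spec):
            if spec is None:
                continue
            conversion, af = spec
            if not 0 < af <= 1:
                raise ValueError("planted allele frequencies must lie in (0, 1]")
            pos, idx, ref, alt = _edit_coordinates(site, conversion, window)
            if chroms[site.chrom][idx] != ref:
                raise ValueError(
                    f"planted edit inconsistent with genome reference base at "
                    f"{site.chrom}:{idx + 1} (expected {ref}, "
                    f"found {chroms[site.chrom][idx]})"
                )
            snvs.append(SNVRecord(chrom=site.chrom, pos=idx + 1, ref=ref, alt=alt,
                                  allele_frequency=af, depth=depth,
                                  sample_id=sample_id))
            used.add((site.chrom, idx))
            truth_rows.append(TruthVariant(
                sample_id=sample_id, chrom=site.chrom, pos=idx + 1, ref=ref, alt=alt,
                allele_frequency=af, zygosity=call_zygosity(af), origin="planted",
                snv_class=conversion if conversion[0] in "CT"
                else f"{complement(conversion[0])}>{complement(conversion[2])}",
                site=site.source_grna, position=pos, conversion=conversion,
            ))

        n_bg = int(rng.poisson(background.mean_snvs))
        for _ in range(n_bg):
            cls = spectrum_classes[rng.choice(len(spectrum_classes), p=spectrum_p)]
            zyg = mix_classes[rng.choice(len(mix_classes), p=mix_p)]
            lo, hi = _AF_BANDS[zyg]
            af = float(lo + (hi - lo) * rng.random())
            ref_options = {cls[0]: cls[2],
                           complement(cls[0]): complement(cls[2])}
            for _try in range(1000):
                chrom = names[rng.choice(len(names), p=chrom_p)]
                idx = int(rng.integers(1, len(chroms[chrom]) - 1))
                base = chroms[chrom][idx]
                if base not in ref_options or idx in blocked.get(chrom, ()) \
                        or (chrom, idx) in used:
                    continue
                alt = ref_options[base]
                snvs.append(SNVRecord(chrom=chrom, pos=idx + 1, ref=base, alt=alt,
                                      allele_frequency=af, depth=depth,
                                      sample_id=sample_id))
                used.add((chrom, idx))
                truth_rows.append(TruthVariant(
                    sample_id=sample_id, chrom=chrom, pos=idx + 1, ref=base, alt=alt,
                    allele_frequency=af, zygosity=zyg, origin="background",
                    snv_class=cls,
                ))
                break
            else:  # pragma: no cover - pathological genomes only
                raise RuntimeError("could not place a background SNV")

        n_ind = int(rng.poisson(background.mean_indels))
        for _ in range(n_ind):
            zyg = mix_classes[rng.choice(len(mix_classes), p=mix_p)]
            lo, hi = _AF_BANDS[zyg]
            af = float(lo + (hi - lo) * rng.random())
            chrom = names[rng.choice(len(names), p=chrom_p)]
            idx = int(rng.integers(1, len(chroms[chrom]) - 2))
            anchor = chroms[chrom][idx]
            if rng.integers(0, 2):  # 1-bp deletion
                ref, alt = anchor + chroms[chrom][idx + 1], anchor
            else:  # 1-bp insertion
                ref, alt = anchor, anchor + _BASES[rng.integers(0, 4)]
            indels.append(IndelRecord(chrom=chrom, pos=idx + 1, ref=ref, alt=alt,
                                      allele_frequency=af, depth=depth,
                                      sample_id=sample_id))

        snvs.sort(key=lambda r: (r.chrom, r.pos))
        indels.sort(key=lambda r: (r.chrom, r.pos))
        plants.append(PlantVariantSet(sample_id=sample_id, snvs=snvs, indels=indels))
    return plants, CohortTruth(samples=samples, variants=truth_rows)
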