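"""File-format interfaces: FASTA/FASTQ via Biopython, VCF, TSV, BED, JSON.

Cohort variant tables are VCF v4.2 with the allele frequency in the AF
INFO field and the read depth in DP; reading goes through cyvcf2 and
splits multi-allelic records into one SNV per ALT.  Target sites travel
as a TSV (site_id, amplicon_seq, protospacer, pam_pattern, strand,
offset, window_start, window_end; offset 0-based).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .offtarget import CandidateSite
from .sites import TargetSite
from .variants import IndelRecord, PlantVariantSet, SNVRecord

FASTQ_QUALITY = 37  # constant Phred quality written for simulated reads


# ---- FASTA / FASTQ --------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Sequence[str], read_ids: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in zip(read_ids, reads):
            fh.write(f"@{rid}\n{seq}\n+\n{chr(FASTQ_QUALITY + 33) * len(seq)}\n")


def read_fastq(path: str | Path) -> tuple[list[str], list[str]]:
    reads, ids = [], []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(str(rec.seq).upper())
        ids.append(rec.id)
    return reads, ids


# ---- target-site TSV ------------------------------------------------------

def write_target_sites(sites: Sequence[TargetSite], path: str | Path) -> None:
    rows = [{"site_id": s.site_id, "amplicon_seq": s.amplicon,
             "protospacer": s.protospacer, "pam_pattern": s.pam_pattern,
             "strand": s.strand, "offset": s.offset,
             "window_start": s.window[0], "window_end": s.window[1]}
            for s in sites]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_target_sites(path: str | Path) -> list[TargetSite]:
    frame = pd.read_csv(path, sep="\t")
    return [TargetSite(site_id=str(r.site_id), amplicon=r.amplicon_seq,
                       protospacer=r.protospacer, pam_pattern=r.pam_pattern,
                       strand=r.strand, offset=int(r.offset),
                       window=(int(r.window_start), int(r.window_end)))
            for r in frame.itertuples()]


# ---- VCF ------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_vcf(plant: PlantVariantSet, path: str | Path,
              contigs: Mapping[str, int] | None = None) -> None:
    """Write one plant's SNVs and indels as a sites-only VCF v4.2."""
    records = sorted([*plant.snvs, *plant.indels], key=lambda r: (r.chrom, r.pos))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(f"##SAMPLE=<ID={plant.sample_id},Molecule={plant.molecule}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in records:
            info = f"AF={rec.allele_frequency:.6g};DP={rec.depth}"
            fh.write(f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t{info}\n")


def read_vcf(path: str | Path, sample_id: str | None = None,
             molecule: str = "DNA") -> PlantVariantSet:
    """Read one plant's variant table from VCF.

    AF comes from the AF INFO field; when absent it is computed from
    AD-style allele depths; records with neither are rejected and counted
    in ``n_rejected``.  Multi-allelic records split into one record per ALT.
    """
    sample_id = sample_id or Path(path).stem
    plant = PlantVariantSet(sample_id=sample_id, molecule=molecule)
    vcf = VCF(str(path))
    for rec in vcf:
        afs = rec.INFO.get("AF")
        if afs is None:
            ad = rec.INFO.get("AD")
            dp = rec.INFO.get("DP")
            if ad is not None and dp:
                ad = (ad,) if isinstance(ad, (int, float)) else tuple(ad)
                afs = tuple(a / dp for a in ad)
            else:
                plant.n_rejected += 1
                continue
        if isinstance(afs, (int, float)):
            afs = (afs,)
        depth = int(rec.INFO.get("DP") or 0)
        for alt, af in zip(rec.ALT, afs):
            if len(rec.REF) == 1 and len(alt) == 1:
                plant.snvs.append(SNVRecord(
                    chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=alt,
                    allele_frequency=float(af), depth=depth,
                    sample_id=sample_id, molecule=molecule))
            else:
                plant.indels.append(IndelRecord(
                    chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=alt,
                    allele_frequency=float(af), depth=depth, sample_id=sample_id))
    vcf.close()
    return plant


# ---- BED / JSON -----------------------------------------------------------

def write_candidates_bed(candidates: Iterable[CandidateSite], path: str | Path) -> None:
    """BED6 of candidate sites; name = source_gRNA:mismatch_count."""
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t"
                     f"{c.source_grna}:{c.mismatch_count}\t0\t{c.strand}\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
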