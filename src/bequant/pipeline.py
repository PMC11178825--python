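"""End-to-end orchestration of the synthetic base-editing pipeline.

A single declarative :class:`RunConfig` drives every stage — simulation,
amplicon quantification, window profiling, off-target search and cohort
profiling — in dependency order, writing machine-readable outputs plus a
manifest with parameter values and SHA-256 checksums of every output.
Identical config + seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as bio
from .amplicon import process_reads, quantify_site, top_alleles
from .offtarget import attribute_snvs, enumerate_sites
from .simulate import (BackgroundModel, EditingProfile, make_target_site,
                       make_toy_genome, plant_candidate_sites,
                       simulate_amplicon_reads, simulate_plant_cohort)
from .variants import (germline_fraction, motif_context,
                       on_target_genotype_matrix, per_plant_counts)
from .window import aggregate_positions, infer_all_windows

ALL_STAGES = ("simulate", "quantify", "window", "offtarget", "profile")


class ConfigError(ValueError):
    """The run configuration failed pre-flight validation."""


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run.

    Seeds are explicit — there is no wall-clock default — and every
    threshold is validated against its documented range before any
    computation starts.
    """

    seed: int
    outdir: str = "bequant_run"
    stages: tuple[str, ...] = ALL_STAGES
    # amplicon simulation
    n_sites: int = 4
    n_reads: int = 2000
    amplicon_length: int = 250
    pam_pattern: str = "NGG"
    c_to_t_rate: float = 0.30
    a_to_g_rate: float = 0.15
    cooccurrence: str = "linked"
    indel_rate: float = 0.005
    seq_error_rate: float = 0.003
    window: tuple[int, int] = (4, 8)
    # toy genome / off-target
    n_chrom: int = 2
    chrom_length: int = 20000
    max_mm: int = 3
    # cohort
    n_plants: int = 6
    mean_background_snvs: float = 200.0
    mean_background_indels: float = 60.0
    planted_edit_af: float = 0.9
    # thresholds
    zygosity_cutoffs: tuple[float, float] = (0.3, 0.7)
    window_threshold: float = 0.5
    min_identity: float = 0.6
    top_k_alleles: int = 10

    def validate(self) -> None:
        if self.seed is None or not isinstance(self.seed, int):
            raise ConfigError("seed must be an explicit integer")
        lo, hi = self.zygosity_cutoffs
        if not 0 < lo < hi < 1:
            raise ConfigError(
                f"zygosity cutoffs must satisfy 0 < lower < upper < 1, got ({lo}, {hi})")
        if not 0 < self.window_threshold <= 1:
            raise ConfigError("window_threshold must lie in (0, 1]")
        if not 0 <= self.min_identity <= 1:
            raise ConfigError("min_identity must lie in [0, 1]")
        if not 0 <= self.max_mm <= 6:
            raise ConfigError("max_mm must lie in 0..6")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        wl, wh = self.window
        if not 1 <= wl <= wh <= 20:
            raise ConfigError("window must be an interval within 1..20")
        for name in ("n_sites", "n_reads", "n_plants", "n_chrom"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("stages", "window", "zygosity_cutoffs"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["stages"] = list(self.stages)
        out["window"] = list(self.window)
        out["zygosity_cutoffs"] = list(self.zygosity_cutoffs)
        return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the requested stages and return the manifest.

    Stage outputs land under ``config.outdir``; the manifest (also written
    as ``manifest.json``) records inputs, parameters, seeds and a SHA-256
    checksum per output file.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def emit(name: str, path: Path) -> None:
        outputs[name] = str(path.relative_to(out))

    stages = [s for s in ALL_STAGES if s in config.stages]
    wanted = set(stages)
    # downstream stages need the simulated inputs present on disk
    if wanted - {"simulate"} and not (out / "target_sites.tsv").exists():
        wanted.add("simulate")

    if "simulate" in wanted:
        sites = [make_target_site(seed=config.seed + i,
                                  amplicon_length=config.amplicon_length,
                                  pam_pattern=config.pam_pattern,
                                  window=config.window,
                                  site_id=f"site{i + 1:02d}")
                 for i in range(config.n_sites)]
        bio.write_target_sites(sites, out / "target_sites.tsv")
        emit("target_sites", out / "target_sites.tsv")
        for i, site in enumerate(sites):
            profile = EditingProfile.window_profile(
                site, c_to_t=config.c_to_t_rate, a_to_g=config.a_to_g_rate,
                cooccurrence=config.cooccurrence, indel_rate=config.indel_rate,
                seq_error_rate=config.seq_error_rate)
            reads, ids, truth = simulate_amplicon_reads(
                site, profile, config.n_reads, seed=config.seed + 1000 + i)
            bio.write_fastq(reads, ids, out / f"{site.site_id}.fastq")
            emit(f"reads_{site.site_id}", out / f"{site.site_id}.fastq")
            (out / f"{site.site_id}.truth.json").write_text(truth.to_json() + "\n")
            emit(f"truth_{site.site_id}", out / f"{site.site_id}.truth.json")

        genome = make_toy_genome(config.n_chrom, config.chrom_length,
                                 seed=config.seed + 2000)
        proto = sites[0].protospacer
        margin = 100
        placements = [
            ("chr1", margin, "+", 0),
            ("chr1", margin + 200, "-", 1),
            ("chr1", margin + 400, "+", 2),
            ("chr2", margin, "-", 3),
        ][: max(1, config.n_chrom * 2)]
        genome, registry = plant_candidate_sites(
            genome, proto, placements, pam_pattern=config.pam_pattern,
            seed=config.seed + 3000, source_grna=sites[0].site_id)
        bio.write_fasta(genome, out / "genome.fasta")
        emit("genome", out / "genome.fasta")
        bio.write_candidates_bed(registry, out / "planted_sites.bed")
        emit("planted_sites", out / "planted_sites.bed")

        background = BackgroundModel(mean_snvs=config.mean_background_snvs,
                                     mean_indels=config.mean_background_indels)
        on_target = [c for c in registry if c.mismatch_count == 0]
        edit_spec = [("C>T", config.planted_edit_af)] * len(on_target)
        plants, cohort_truth = simulate_plant_cohort(
            genome, on_target, edit_spec, background, config.n_plants,
            seed=config.seed + 4000, window=config.window)
        contigs = {name: len(seq) for name, seq in genome.items()}
        for plant in plants:
            bio.write_vcf(plant, out / f"{plant.sample_id}.vcf", contigs=contigs)
            emit(f"vcf_{plant.sample_id}", out / f"{plant.sample_id}.vcf")
        (out / "cohort_truth.json").write_text(cohort_truth.to_json() + "\n")
        emit("cohort_truth", out / "cohort_truth.json")

    sites = bio.read_target_sites(out / "target_sites.tsv")

    quantifications = []
    if wanted & {"quantify", "window"}:
        for site in sites:
            reads, ids = bio.read_fastq(out / f"{site.site_id}.fastq")
            outcomes, n_discarded = process_reads(reads, site, ids,
                                                  min_identity=config.min_identity)
            quantifications.append(quantify_site(outcomes, site, n_discarded))

    if "quantify" in wanted:
        for q in quantifications:
            q.position_profile.table.to_csv(
                out / f"{q.site_id}.positions.tsv", sep="\t", index=False)
            emit(f"positions_{q.site_id}", out / f"{q.site_id}.positions.tsv")
            ranked = top_alleles(q.allele_table, config.top_k_alleles)
            with open(out / f"{q.site_id}.alleles.tsv", "w") as fh:
                fh.write("allele\tcount\tratio\tis_reference\n")
                for allele, count, ratio, is_ref in ranked:
                    fh.write(f"{allele}\t{count}\t{ratio:.6g}\t{is_ref}\n")
            emit(f"alleles_{q.site_id}", out / f"{q.site_id}.alleles.tsv")
        bio.write_json({q.site_id: q.summary for q in quantifications},
                       out / "site_summaries.json")
        emit("site_summaries", out / "site_summaries.json")

    if "window" in wanted:
        summary = aggregate_positions([q.position_profile for q in quantifications])
        summary.table.to_csv(out / "window_summary.tsv", sep="\t", index=False)
        emit("window_summary", out / "window_summary.tsv")
        windows = infer_all_windows(summary, config.window_threshold)
        bio.write_json({conv: (list(w) if w else None) for conv, w in windows.items()},
                       out / "windows.json")
        emit("windows", out / "windows.json")

    candidates = []
    if wanted & {"offtarget", "profile"}:
        genome = bio.read_fasta(out / "genome.fasta")
        candidates = enumerate_sites(genome, [sites[0]], max_mm=config.max_mm,
                                     pam_pattern=config.pam_pattern)

    if "offtarget" in wanted:
        bio.write_candidates_bed(candidates, out / "candidates.bed")
        emit("candidates", out / "candidates.bed")

    if "profile" in wanted:
        plants = [bio.read_vcf(out / f"plant{i + 1:03d}.vcf")
                  for i in range(config.n_plants)]
        class_table, chrom_table = per_plant_counts(plants)
        class_table.to_csv(out / "per_plant_counts.tsv", sep="\t")
        emit("per_plant_counts", out / "per_plant_counts.tsv")
        chrom_table.to_csv(out / "per_chrom_counts.tsv", sep="\t")
        emit("per_chrom_counts", out / "per_chrom_counts.tsv")
        germline = {p.sample_id: germline_fraction(p, config.zygosity_cutoffs)
                    for p in plants if p.snvs}
        bio.write_json(germline, out / "germline_fractions.json")
        emit("germline_fractions", out / "germline_fractions.json")

        on_target = [c for c in candidates if c.mismatch_count == 0]
        if on_target:
            matrix = on_target_genotype_matrix(plants, on_target, "C>T",
                                               config.zygosity_cutoffs)
            matrix.to_csv(out / "genotype_matrix.tsv", sep="\t")
            emit("genotype_matrix", out / "genotype_matrix.tsv")

        attributions = attribute_snvs(
            [s for p in plants for s in p.snvs], candidates)
        with open(out / "attributions.tsv", "w") as fh:
            fh.write("sample_id\tchrom\tpos\tref\talt\tsite\tmismatches\t"
                     "position\tconversion\tconsistent\n")
            for a in attributions:
                fh.write(f"{a.snv.sample_id}\t{a.snv.chrom}\t{a.snv.pos}\t"
                         f"{a.snv.ref}\t{a.snv.alt}\t{a.candidate.source_grna}\t"
                         f"{a.candidate.mismatch_count}\t{a.position}\t"
                         f"{a.conversion}\t{a.consistent}\n")
        emit("attributions", out / "attributions.tsv")

        ct_snvs = [s for p in plants for s in p.snvs
                   if {s.ref, s.alt} == {"C", "T"} or {s.ref, s.alt} == {"G", "A"}]
        ct_snvs = [s for s in ct_snvs
                   if (s.ref, s.alt) in (("C", "T"), ("G", "A"))]
        if ct_snvs:
            genome = bio.read_fasta(out / "genome.fasta")
            motif = motif_context(ct_snvs, genome)
            motif.frequencies.assign(information=motif.information).to_csv(
                out / "motif_ct.tsv", sep="\t")
            emit("motif_ct", out / "motif_ct.tsv")

    manifest = {
        "config": config.to_dict(),
        "stages_run": sorted(wanted),
        "outputs": {name: {"path": rel, "sha256": _sha256(out / rel)}
                    for name, rel in sorted(outputs.items())},
    }
    bio.write_json(manifest, out / "manifest.json")
    return manifest
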