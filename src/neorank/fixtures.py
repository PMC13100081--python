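"""Seeded synthetic toy cohort so every pipeline stage is testable offline.

The generator plants, with known ground truth: missense/synonymous/stop-gain
variants, frameshift and in-frame indels, non-PASS and low-depth decoys,
in-frame and reject fusions, an amplified gene (tumor depth and TPM jointly
elevated), a tumor+normal shared capture spike, an expression-only gene, and
a below-gate low-TPM gene. A manifest of expected downstream counts and
labels is emitted alongside the standard-format files.

All randomness derives from one cohort seed through per-section child
streams, so partial regeneration is stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import epitope_generation as epi
from .epitope_generation import GENETIC_CODE, STOP_CODONS, translate_cds
from .io_formats import (
    EffectAnnotation,
    FusionRecord,
    Interval,
    SomaticVariant,
    write_abundance,
    write_bed,
    write_depth_table,
    write_effect_table,
    write_fasta,
    write_fusion_table,
    write_hla_list,
    write_somatic_vcf,
    AbundanceTable,
    DepthTrack,
)

_CODONS = sorted(set(GENETIC_CODE) - STOP_CODONS)
_BASES = "ACGT"


@dataclass(frozen=True)
class ToyCohortSpec:
    seed: int = 0
    n_genes: int = 20
    gene_length: int = 600  # nt, divisible by 3
    n_samples: int = 3
    contig: str = "chr1"
    intergenic_gap: int = 100
    # planted somatic events per sample
    n_missense: int = 4
    n_synonymous: int = 2
    n_stop_gain: int = 1
    n_frameshift: int = 2
    n_inframe: int = 1
    n_failed: int = 1  # non-PASS decoys
    n_low_depth: int = 1  # PASS but < 10x decoys
    n_good_fusions: int = 2
    n_reject_fusions: int = 3
    # depth model
    min_callable_fraction: float = 0.6
    max_callable_fraction: float = 0.9
    low_depth_range: tuple[int, int] = (4, 8)
    high_depth_range: tuple[int, int] = (20, 40)
    # concordance plants (gene indices into the toy gene list)
    amplified_gene_index: int = 2
    spike_gene_index: int = 3
    expression_only_gene_index: int = 4
    low_tpm_gene_index: int = 5
    amplification_depth_multiplier: int = 12
    spike_depth_multiplier: int = 15
    amplified_tpm: float = 2000.0
    expression_only_tpm: float = 800.0
    low_tpm: float = 0.4
    hla_alleles: tuple[str, ...] = ("A*02:01", "B*07:02")
    min_depth: int = 10

    def __post_init__(self) -> None:
        if self.gene_length % 3 != 0:
            raise ValueError("gene_length must be divisible by 3")
        n_variant_genes = (
            self.n_missense
            + self.n_synonymous
            + self.n_stop_gain
            + self.n_frameshift
            + self.n_inframe
            + self.n_failed
            + self.n_low_depth
        )
        if self.n_genes < 6 + n_variant_genes - 1:
            raise ValueError("n_genes too small for the planted variant load")

    def gene_name(self, i: int) -> str:
        return f"GENE{i:02d}"

    def transcript_name(self, i: int) -> str:
        return f"TX{i:02d}"

    def sample_name(self, s: int) -> str:
        return f"sample_{s + 1:02d}"

    @property
    def amplified_sample(self) -> int:
        return self.n_samples - 1

    @property
    def spike_sample(self) -> int:
        return 0

    @property
    def expression_only_sample(self) -> int:
        return 1 if self.n_samples > 1 else 0


@dataclass
class ToyReference:
    cds: dict[str, str]  # transcript -> CDS
    proteins: dict[str, str]  # transcript -> protein
    bed: list[Interval]
    gene_of_tx: dict[str, str]
    tx_of_gene: dict[str, str]
    gene_start0: dict[str, int]  # genomic 0-based start of each gene's CDS


@dataclass
class ToyCohort:
    spec: ToyCohortSpec
    reference: ToyReference
    variants: dict[str, list[SomaticVariant]] = field(default_factory=dict)
    fusions: dict[str, list[FusionRecord]] = field(default_factory=dict)
    tumor_depth: dict[str, DepthTrack] = field(default_factory=dict)
    normal_depth: dict[str, DepthTrack] = field(default_factory=dict)
    abundance: dict[str, AbundanceTable] = field(default_factory=dict)
    library_size: dict[str, int] = field(default_factory=dict)
    callable_fraction: dict[str, float] = field(default_factory=dict)  # per gene
    ground_truth: list[tuple[str, str, str]] = field(default_factory=list)


def _rng(spec: ToyCohortSpec, *section) -> np.random.Generator:
    return np.random.default_rng([spec.seed, *section])


def make_toy_reference(spec: ToyCohortSpec) -> ToyReference:
    """Random non-stop-codon CDS per gene with tiling BED coordinates."""
    rng = _rng(spec, 0)
    cds: dict[str, str] = {}
    proteins: dict[str, str] = {}
    bed: list[Interval] = []
    gene_of_tx: dict[str, str] = {}
    tx_of_gene: dict[str, str] = {}
    gene_start0: dict[str, int] = {}
    for i in range(spec.n_genes):
        gene, tx = spec.gene_name(i), spec.transcript_name(i)
        n_codons = spec.gene_length // 3
        codons = rng.choice(_CODONS, size=n_codons)
        seq = "".join(codons)
        cds[tx] = seq
        proteins[tx] = translate_cds(seq)
        assert len(proteins[tx]) == n_codons  # no stop codons by construction
        start0 = spec.intergenic_gap + i * (spec.gene_length + spec.intergenic_gap)
        bed.append(Interval(spec.contig, start0, start0 + spec.gene_length, gene))
        gene_of_tx[tx] = gene
        tx_of_gene[gene] = tx
        gene_start0[gene] = start0
    return ToyReference(
        cds=cds,
        proteins=proteins,
        bed=bed,
        gene_of_tx=gene_of_tx,
        tx_of_gene=tx_of_gene,
        gene_start0=gene_start0,
    )


def _callable_prefix(spec: ToyCohortSpec, fraction: float) -> int:
    return int(math.ceil(fraction * spec.gene_length))


def _genome_pos(ref: ToyReference, gene: str, cds_pos: int) -> int:
    return ref.gene_start0[gene] + cds_pos  # 1-based


def _snv_variant(
    spec: ToyCohortSpec,
    ref: ToyReference,
    rng: np.random.Generator,
    gene_index: int,
    kind: str,
    callable_fraction: float,
    in_callable: bool = True,
    filters: frozenset[str] = frozenset({"PASS"}),
    depth_override: int | None = None,
) -> SomaticVariant:
    """Plant a single-nucleotide substitution of the requested consequence."""
    gene = spec.gene_name(gene_index)
    tx = ref.tx_of_gene[gene]
    cds = ref.cds[tx]
    prefix = _callable_prefix(spec, callable_fraction)
    n_codons = len(cds) // 3
    if in_callable:
        codon_lo, codon_hi = 2, max(prefix // 3 - 2, 3)
    else:
        codon_lo, codon_hi = prefix // 3 + 1, n_codons - 2
    for _ in range(500):
        c = int(rng.integers(codon_lo, codon_hi))
        codon = cds[3 * c : 3 * c + 3]
        offset = int(rng.integers(0, 3))
        alt_base = _BASES[int(rng.integers(0, 4))]
        if alt_base == codon[offset]:
            continue
        new_codon = codon[:offset] + alt_base + codon[offset + 1 :]
        old_aa, new_aa = GENETIC_CODE[codon], GENETIC_CODE[new_codon]
        if kind == "missense" and (new_aa == "*" or new_aa == old_aa):
            continue
        if kind == "synonymous" and new_aa != old_aa:
            continue
        if kind == "stop_gain" and new_aa != "*":
            continue
        cds_pos = 3 * c + offset + 1
        vaf = round(float(rng.uniform(0.15, 0.85)), 2)
        depth = depth_override if depth_override is not None else int(rng.integers(15, 60))
        consequence = {"missense": "missense", "synonymous": "synonymous", "stop_gain": "stop_gain"}[kind]
        return SomaticVariant(
            chrom=spec.contig,
            pos=_genome_pos(ref, gene, cds_pos),
            ref_allele=codon[offset],
            alt_allele=alt_base,
            filter_status=filters,
            tumor_depth=depth,
            vaf=vaf,
            effect=EffectAnnotation(
                gene_symbol=gene,
                transcript_id=tx,
                consequence_class=consequence,
                protein_position=c + 1,
                ref_aa=old_aa,
                alt_aa=new_aa if new_aa != "*" else "*",
                cds_position=cds_pos,
                cds_ref=codon[offset],
                cds_alt=alt_base,
            ),
        )
    raise RuntimeError(f"could not plant a {kind} SNV in {gene}")


def _indel_variant(
    spec: ToyCohortSpec,
    ref: ToyReference,
    rng: np.random.Generator,
    gene_index: int,
    frameshift: bool,
    callable_fraction: float,
) -> SomaticVariant:
    """Plant a 1-nt deletion (frameshift) or 3-nt insertion (in-frame)."""
    gene = spec.gene_name(gene_index)
    tx = ref.tx_of_gene[gene]
    cds = ref.cds[tx]
    prefix = _callable_prefix(spec, callable_fraction)
    codon_hi = max(prefix // 3 - 4, 6)
    for _ in range(500):
        c = int(rng.integers(3, codon_hi))
        if frameshift:
            p = 3 * c + 1  # anchor base; delete the base after it
            cds_ref, cds_alt = cds[p - 1 : p + 1], cds[p - 1]
        else:
            p = 3 * c  # anchor at a codon's last base; insert a codon after it
            ins = _CODONS[int(rng.integers(0, len(_CODONS)))]
            cds_ref, cds_alt = cds[p - 1], cds[p - 1] + ins
        effect = EffectAnnotation(
            gene_symbol=gene,
            transcript_id=tx,
            consequence_class="frameshift" if frameshift else "inframe_indel",
            cds_position=p,
            cds_ref=cds_ref,
            cds_alt=cds_alt,
        )
        variant = SomaticVariant(
            chrom=spec.contig,
            pos=_genome_pos(ref, gene, p),
            ref_allele=cds_ref,
            alt_allele=cds_alt,
            filter_status=frozenset({"PASS"}),
            tumor_depth=int(rng.integers(15, 60)),
            vaf=round(float(rng.uniform(0.15, 0.85)), 2),
            effect=effect,
        )
        builder = epi.build_frameshift_context if frameshift else epi.build_inframe_context
        if builder(variant, ref.cds) is not None:
            return variant
    raise RuntimeError(f"could not plant an indel in {gene}")


def _make_fusion(
    spec: ToyCohortSpec,
    ref: ToyReference,
    rng: np.random.Generator,
    gene5_index: int,
    gene3_index: int,
    *,
    junction: int,
    discordant: int,
    confidence: str = "high",
    frame_status: str = "in_frame",
) -> FusionRecord:
    g5, g3 = spec.gene_name(gene5_index), spec.gene_name(gene3_index)
    cds5 = ref.cds[ref.tx_of_gene[g5]]
    cds3 = ref.cds[ref.tx_of_gene[g3]]
    # codon-aligned interior slices: 10 codons of the 5' partner, 11 of the 3'
    c5 = int(rng.integers(10, 30))
    c3 = int(rng.integers(10, 30))
    five = cds5[3 * c5 : 3 * c5 + 30]
    three = cds3[3 * c3 : 3 * c3 + 33]
    return FusionRecord(
        gene5=g5,
        gene3=g3,
        breakpoint5=f"{spec.contig}:{_genome_pos(ref, g5, 3 * c5 + 30)}",
        breakpoint3=f"{spec.contig}:{_genome_pos(ref, g3, 3 * c3 + 1)}",
        junction_reads=junction,
        discordant_pairs=discordant,
        confidence=confidence,
        frame_status=frame_status,
        junction_cds=five + three,
        junction_offset=len(five),
    )


def _depth_tracks(
    spec: ToyCohortSpec,
    ref: ToyReference,
    rng: np.random.Generator,
    sample_index: int,
    callable_fraction: dict[str, float],
) -> tuple[DepthTrack, DepthTrack]:
    tumor, normal = DepthTrack(), DepthTrack()
    for i in range(spec.n_genes):
        gene = spec.gene_name(i)
        prefix = _callable_prefix(spec, callable_fraction[gene])
        hi_t = int(rng.integers(*spec.high_depth_range))
        hi_n = int(rng.integers(*spec.high_depth_range))
        lo_t = int(rng.integers(*spec.low_depth_range))
        lo_n = int(rng.integers(*spec.low_depth_range))
        mult_t = mult_n = 1
        if i == spec.amplified_gene_index and sample_index == spec.amplified_sample:
            mult_t = spec.amplification_depth_multiplier
        if i == spec.spike_gene_index and sample_index == spec.spike_sample:
            mult_t = mult_n = spec.spike_depth_multiplier
        start0 = ref.gene_start0[gene]
        for offset in range(spec.gene_length):
            pos = start0 + offset + 1
            t = hi_t if offset < prefix else lo_t
            n = hi_n if offset < prefix else lo_n
            tumor.set(spec.contig, pos, t * mult_t)
            normal.set(spec.contig, pos, n * mult_n)
    return tumor, normal


def _abundance(
    spec: ToyCohortSpec,
    ref: ToyReference,
    rng: np.random.Generator,
    sample_index: int,
) -> AbundanceTable:
    tpm: dict[str, float] = {}
    gene_of: dict[str, str] = {}
    for i in range(spec.n_genes):
        gene, tx = spec.gene_name(i), spec.transcript_name(i)
        value = round(float(rng.uniform(2.0, 40.0)), 2)
        if i == spec.low_tpm_gene_index:
            value = spec.low_tpm
        elif i == spec.amplified_gene_index:
            value = spec.amplified_tpm if sample_index == spec.amplified_sample else 8.0
        elif i == spec.expression_only_gene_index:
            value = spec.expression_only_tpm if sample_index == spec.expression_only_sample else 6.0
        elif i == spec.spike_gene_index:
            value = 5.0
        tpm[tx] = value
        gene_of[tx] = gene
    return AbundanceTable(tpm=tpm, gene_of=gene_of)


def build_toy_cohort(spec: ToyCohortSpec = ToyCohortSpec()) -> ToyCohort:
    """Build the whole cohort in memory, with a ground-truth manifest."""
    ref = make_toy_reference(spec)
    cohort = ToyCohort(spec=spec, reference=ref)

    frac_rng = _rng(spec, 1)
    for i in range(spec.n_genes):
        cohort.callable_fraction[spec.gene_name(i)] = float(
            frac_rng.uniform(spec.min_callable_fraction, spec.max_callable_fraction)
        )

    special = {
        spec.amplified_gene_index,
        spec.spike_gene_index,
        spec.expression_only_gene_index,
        spec.low_tpm_gene_index,
    }
    pool = [i for i in range(6, spec.n_genes) if i not in special]

    for s in range(spec.n_samples):
        sample = spec.sample_name(s)
        vrng = _rng(spec, 2, s)
        gene_iter = iter(
            [spec.low_tpm_gene_index] + list(vrng.permutation(pool))
        )  # first missense lands in the below-gate gene
        variants: list[SomaticVariant] = []

        def frac(gi: int) -> float:
            return cohort.callable_fraction[spec.gene_name(gi)]

        for k in range(spec.n_missense):
            gi = next(gene_iter)
            variants.append(_snv_variant(spec, ref, vrng, gi, "missense", frac(gi)))
        for _ in range(spec.n_synonymous):
            gi = next(gene_iter)
            variants.append(_snv_variant(spec, ref, vrng, gi, "synonymous", frac(gi)))
        for _ in range(spec.n_stop_gain):
            gi = next(gene_iter)
            variants.append(_snv_variant(spec, ref, vrng, gi, "stop_gain", frac(gi)))
        for _ in range(spec.n_frameshift):
            gi = next(gene_iter)
            variants.append(_indel_variant(spec, ref, vrng, gi, True, frac(gi)))
        for _ in range(spec.n_inframe):
            gi = next(gene_iter)
            variants.append(_indel_variant(spec, ref, vrng, gi, False, frac(gi)))
        for _ in range(spec.n_failed):
            gi = next(gene_iter)
            variants.append(
                _snv_variant(
                    spec, ref, vrng, gi, "missense", frac(gi),
                    filters=frozenset({"germline", "weak_evidence"}),
                )
            )
        for _ in range(spec.n_low_depth):
            gi = next(gene_iter)
            variants.append(
                _snv_variant(
                    spec, ref, vrng, gi, "missense", frac(gi),
                    in_callable=False, depth_override=5,
                )
            )
        cohort.variants[sample] = variants

        frng = _rng(spec, 3, s)
        fusion_pool = list(frng.permutation(pool))
        fusions: list[FusionRecord] = []
        for k in range(spec.n_good_fusions):
            fusions.append(
                _make_fusion(
                    spec, ref, frng, fusion_pool[2 * k], fusion_pool[2 * k + 1],
                    junction=int(frng.integers(5, 12)), discordant=int(frng.integers(0, 4)),
                )
            )
        reject_kinds = [
            dict(junction=2, discordant=1),  # below support
            dict(junction=9, discordant=2, confidence="medium"),
            dict(junction=9, discordant=2, frame_status="out_of_frame"),
        ]
        for k in range(spec.n_reject_fusions):
            kind = reject_kinds[k % len(reject_kinds)]
            fusions.append(
                _make_fusion(
                    spec, ref, frng,
                    fusion_pool[(2 * spec.n_good_fusions + k) % len(fusion_pool)],
                    fusion_pool[(2 * spec.n_good_fusions + k + 1) % len(fusion_pool)],
                    **kind,
                )
            )
        cohort.fusions[sample] = fusions

        drng = _rng(spec, 4, s)
        tumor, normal = _depth_tracks(spec, ref, drng, s, cohort.callable_fraction)
        cohort.tumor_depth[sample] = tumor
        cohort.normal_depth[sample] = normal
        cohort.abundance[sample] = _abundance(spec, ref, _rng(spec, 5, s), s)
        cohort.library_size[sample] = 2_000_000 + 100_000 * s

        _record_ground_truth(cohort, sample, s)
    return cohort


def _record_ground_truth(cohort: ToyCohort, sample: str, s: int) -> None:
    spec, ref = cohort.spec, cohort.reference
    gt = cohort.ground_truth
    variants = cohort.variants[sample]

    eligible = epi.select_epitope_variants(variants, spec.min_depth)
    gt.append((sample, "eligible_epitope_variants", str(len(eligible))))

    n_tmb = spec.n_missense + spec.n_stop_gain + spec.n_frameshift + spec.n_inframe
    gt.append((sample, "tmb_eligible", str(n_tmb)))

    # brute-force per-position count over the generated track (depth
    # multipliers can lift low-coverage segments past the threshold)
    tumor = cohort.tumor_depth[sample]
    callable_bases = sum(
        1
        for iv in ref.bed
        for pos in iv.positions_1based()
        if tumor.get(iv.contig, pos) >= spec.min_depth
    )
    gt.append((sample, "callable_bases", str(callable_bases)))
    gt.append((sample, "tmb", repr(n_tmb / (callable_bases / 1e6))))

    transitions = transversions = 0
    for v in variants:
        if len(v.ref_allele) == 1 == len(v.alt_allele) and v.is_pass and v.tumor_depth >= spec.min_depth:
            if (v.ref_allele, v.alt_allele) in {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}:
                transitions += 1
            else:
                transversions += 1
    gt.append((sample, "titv_transitions", str(transitions)))
    gt.append((sample, "titv_transversions", str(transversions)))

    gt.append((sample, "retained_fusions", str(spec.n_good_fusions)))

    # candidates gated out by the below-threshold TPM gene (the first missense)
    low_gene = spec.gene_name(spec.low_tpm_gene_index)
    n_gated = 0
    n_candidates = 0
    for v in eligible:
        ctx = epi.build_context(v, ref.proteins, ref.cds)
        if ctx is None:
            continue
        n_peps = len(epi.enumerate_peptides(ctx))
        n_candidates += n_peps * len(spec.hla_alleles)
        if v.effect.gene_symbol == low_gene:
            n_gated += n_peps * len(spec.hla_alleles)
    for f in cohort.fusions[sample]:
        if f.confidence == "high" and f.frame_status == "in_frame" and max(
            f.junction_reads, f.discordant_pairs
        ) >= 5:
            n_candidates += len(epi.fusion_peptides(f)) * len(spec.hla_alleles)
    gt.append((sample, "gated_candidates", str(n_gated)))
    gt.append((sample, "scored_candidates", str(n_candidates)))

    if s == spec.amplified_sample:
        gt.append((sample, f"label:{spec.gene_name(spec.amplified_gene_index)}", "concordant_amplification"))
    if s == spec.spike_sample:
        gt.append((sample, f"label:{spec.gene_name(spec.spike_gene_index)}", "capture_artifact"))
    if s == spec.expression_only_sample:
        gt.append((sample, f"label:{spec.gene_name(spec.expression_only_gene_index)}", "transcriptional_only"))


def write_cohort(cohort: ToyCohort, out_dir: str | Path) -> Path:
    """Serialize the cohort to standard formats; returns the manifest path."""
    spec, ref = cohort.spec, cohort.reference
    out = Path(out_dir)
    ref_dir = out / "reference"
    ref_dir.mkdir(parents=True, exist_ok=True)

    write_fasta(ref.cds, ref_dir / "cds.fasta")
    write_fasta(ref.proteins, ref_dir / "proteins.fasta")
    write_fasta(ref.proteins, ref_dir / "proteome.fasta")
    write_bed(ref.bed, ref_dir / "cds.bed")

    manifest: dict = {
        "reference": {
            "cds_fasta": "reference/cds.fasta",
            "protein_fasta": "reference/proteins.fasta",
            "proteome_fasta": "reference/proteome.fasta",
            "cds_bed": "reference/cds.bed",
        },
        "samples": [],
    }
    for s in range(spec.n_samples):
        sample = spec.sample_name(s)
        sdir = out / sample
        sdir.mkdir(parents=True, exist_ok=True)
        write_somatic_vcf(cohort.variants[sample], sdir / "somatic.vcf")
        write_effect_table(cohort.variants[sample], sdir / "effects.tsv")
        write_depth_table(cohort.tumor_depth[sample], sdir / "tumor_depth.tsv")
        write_depth_table(cohort.normal_depth[sample], sdir / "normal_depth.tsv")
        write_abundance(cohort.abundance[sample], sdir / "abundance.tsv")
        write_fusion_table(cohort.fusions[sample], sdir / "fusions.tsv")
        write_hla_list(spec.hla_alleles, sdir / "hla.txt")
        manifest["samples"].append(
            {
                "name": sample,
                "vcf": f"{sample}/somatic.vcf",
                "effects": f"{sample}/effects.tsv",
                "tumor_depth": f"{sample}/tumor_depth.tsv",
                "normal_depth": f"{sample}/normal_depth.tsv",
                "abundance": f"{sample}/abundance.tsv",
                "fusions": f"{sample}/fusions.tsv",
                "hla": f"{sample}/hla.txt",
                "total_mapped_reads": cohort.library_size[sample],
            }
        )

    with open(out / "ground_truth.tsv", "w") as fh:
        fh.write("sample\tkey\tvalue\n")
        for sample, key, value in cohort.ground_truth:
            fh.write(f"{sample}\t{key}\t{value}\n")

    manifest_path = out / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path


def make_somatic_inputs(spec: ToyCohortSpec, out_dir: str | Path) -> Path:
    """Build and serialize a cohort in one call; returns the manifest path."""
    return write_cohort(build_toy_cohort(spec), out_dir)


def read_ground_truth(path: str | Path) -> dict[tuple[str, str], str]:
    truth = {}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        sample, key, value = line.split("\t")
        truth[(sample, key)] = value
    return truth
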