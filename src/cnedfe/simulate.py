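"""Synthetic inputs with known ground truth for the whole pipeline.

The generator lays out a single synthetic chromosome carrying CNEs with a
planted invariant/substituted column mosaic, a protein-coding gene for the
coding controls, and non-coding flank space. Polymorphism is placed on top
with derived allele counts drawn from the Poisson-Random-Field model (class-
specific gamma DFEs under a two-epoch expansion), and every record carries
its truth label. A HapMap-style common-allele ascertainment filter emulates
discovery panels that preferentially capture common variants.

Defaults mirror the study conditions: seven vertebrate species with human
focal, an invariant-column fraction of 0.507 (the observed NVR share of CNE
columns), a two-epoch expansion (omega = 0.75, tau = 0.45, Ne = 16000),
gamma DFEs (0.18, 7.8) at NVR-like and (0.1, 6.25) at non-synonymous-like
sites, neutral synonymous/non-coding classes, and n = 120 sampled
chromosomes (the order of a single 1000 Genomes population panel).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .elements import AlignedElement, Anchor
from .prf import DemographyModel, GammaDFE, SelectionSpectrumCache, expected_sfs_two_epoch
from .variants import (
    CAT_NONCODING, CAT_NONSYN, CAT_NVR, CAT_RVR, CAT_SYN,
    PolarizedVariant, build_noncoding_control, degeneracy_classify,
)

_NUCS = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}

SPECIES = ("human", "macaque", "mouse", "chicken", "frog", "zebrafish", "fugu")


@dataclass
class GeneratorConfig:
    """Everything the synthetic-data generator needs; seed fixes all output."""

    seed: int = 0
    n_elements: int = 40
    element_length: tuple[int, int] = (120, 320)
    invariant_fraction: float = 0.507
    substitution_prob: float = 0.3
    focal_substitution_prob: float = 0.0
    gc_content: float = 0.40
    cpg_rate: float = 0.02
    species: tuple[str, ...] = SPECIES
    focal_species: str = "human"
    chromosome: str = "chr1"
    element_spacing: int = 20000
    first_element_at: int = 10000
    n_chromosomes: int = 120
    demography: DemographyModel = field(
        default_factory=lambda: DemographyModel(ne=16000, omega=0.75, tau=0.45)
    )
    theta_per_site: float = 0.001
    dfes: dict[str, GammaDFE | None] = field(default_factory=lambda: {
        CAT_NVR: GammaDFE(0.18, 7.8),
        CAT_RVR: GammaDFE(0.26, 590.0),
        CAT_NONSYN: GammaDFE(0.1, 6.25),
        CAT_SYN: None,
        CAT_NONCODING: None,
    })
    #: per-category multiplier on theta_per_site (lets tests raise SNP yield)
    theta_scale: float = 1.0
    cds_length: int = 900
    min_maf: float = 0.05


def _random_sequence(rng: np.random.Generator, length: int, gc: float,
                     cpg_rate: float = 0.0) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(_NUCS, size=length, p=p)
    if cpg_rate > 0 and length > 1:
        plant = np.where(rng.random(length - 1) < cpg_rate)[0]
        seq[plant] = "C"
        seq[plant + 1] = "G"
    return seq


def generate_alignments(
    config: GeneratorConfig,
) -> tuple[list[AlignedElement], dict[str, np.ndarray]]:
    """Alignments with a planted invariant/substituted mosaic plus truth masks.

    Every column designated variable receives at least one non-focal
    substitution, so the truth mask is exactly recoverable by classification.
    Truth labels are 'NVR'/'RVR' per column.
    """
    elements, truth, _ = _generate_alignments_full(config)
    return elements, truth


def _generate_alignments_full(
    config: GeneratorConfig,
) -> tuple[list[AlignedElement], dict[str, np.ndarray], dict[str, str]]:
    rng = np.random.default_rng(config.seed)
    elements: list[AlignedElement] = []
    truth: dict[str, np.ndarray] = {}
    ancestral_seqs: dict[str, str] = {}
    nonfocal = [sp for sp in config.species if sp != config.focal_species]
    pos = config.first_element_at
    for e in range(config.n_elements):
        length = int(rng.integers(config.element_length[0],
                                  config.element_length[1] + 1))
        ancestral = _random_sequence(rng, length, config.gc_content,
                                     config.cpg_rate)
        invariant = rng.random(length) < config.invariant_fraction
        rows = {sp: ancestral.copy() for sp in config.species}
        for col in np.where(~invariant)[0]:
            hit = rng.random(len(nonfocal)) < config.substitution_prob
            if not hit.any():
                hit[rng.integers(len(nonfocal))] = True
            for sp in np.array(nonfocal)[hit]:
                choices = _NUCS[_NUCS != ancestral[col]]
                rows[sp][col] = rng.choice(choices)
            if hit.all():
                # all species substituted: guarantee the column still varies
                # among the non-focal rows (they could all draw the same base)
                column = {str(rows[sp][col]) for sp in nonfocal}
                if len(column) == 1:
                    sp = nonfocal[int(rng.integers(len(nonfocal)))]
                    base = rows[sp][col]
                    rows[sp][col] = rng.choice(_NUCS[_NUCS != base])
        if config.focal_substitution_prob > 0:
            for col in np.where(invariant)[0]:
                if rng.random() < config.focal_substitution_prob:
                    choices = _NUCS[_NUCS != ancestral[col]]
                    rows[config.focal_species][col] = rng.choice(choices)
        element_id = f"CNE{e:04d}"
        anchor = Anchor(config.chromosome, pos, pos + length, "+")
        elements.append(AlignedElement(
            element_id,
            {sp: "".join(rows[sp]) for sp in config.species},
            anchor,
            config.focal_species,
        ))
        truth[element_id] = np.where(invariant, "NVR", "RVR")
        ancestral_seqs[element_id] = "".join(ancestral)
        pos += config.element_spacing
    return elements, truth, ancestral_seqs


def _random_cds(rng: np.random.Generator, length: int) -> str:
    codons = []
    for _ in range(length // 3):
        while True:
            codon = "".join(rng.choice(_NUCS, size=3))
            if codon not in _STOPS:
                codons.append(codon)
                break
    return "".join(codons)


@dataclass
class SyntheticBundle:
    """All generated inputs plus their ground truth."""

    config: GeneratorConfig
    elements: list[AlignedElement]
    truth_masks: dict[str, np.ndarray]
    ancestral_genome: str
    variants: list[PolarizedVariant]
    truth_categories: pd.DataFrame
    cds_sequence: str
    cds_start: int
    noncoding_intervals: pd.DataFrame

    @property
    def anchors_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"chrom": el.anchor.chromosome, "start": el.anchor.start,
             "end": el.anchor.end, "name": el.element_id, "score": 0,
             "strand": el.anchor.strand}
            for el in self.elements
        ])


def generate_bundle(config: GeneratorConfig) -> SyntheticBundle:
    """Generate the full synthetic input set with truth labels."""
    rng = np.random.default_rng(config.seed + 1)
    elements, truth, ancestral_seqs = _generate_alignments_full(config)

    # --- chromosome layout -------------------------------------------------
    last_end = elements[-1].anchor.end
    cds_start = last_end + 50000
    genome_len = cds_start + config.cds_length + 10000
    genome = _random_sequence(rng, genome_len, config.gc_content,
                              config.cpg_rate)
    # ancestral genome: element regions carry the true ancestral sequence
    # (the focal reference may differ where focal substitutions were planted)
    for el in elements:
        genome[el.anchor.start:el.anchor.end] = list(ancestral_seqs[el.element_id])
    cds_seq = _random_cds(rng, config.cds_length)
    genome[cds_start:cds_start + config.cds_length] = list(cds_seq)
    ancestral_genome = "".join(genome)

    # --- position pools per category ---------------------------------------
    anchors = pd.DataFrame([
        {"chrom": el.anchor.chromosome, "start": el.anchor.start,
         "end": el.anchor.end} for el in elements
    ])
    exons = pd.DataFrame([{"chrom": config.chromosome, "start": cds_start,
                           "end": cds_start + config.cds_length}])
    noncoding = build_noncoding_control(anchors, exons=exons)
    pools: dict[str, np.ndarray] = {}
    nvr_pos, rvr_pos = [], []
    for el in elements:
        labels = truth[el.element_id]
        coords = np.arange(el.anchor.start, el.anchor.end)
        nvr_pos.append(coords[labels == "NVR"])
        rvr_pos.append(coords[labels == "RVR"])
    pools[CAT_NVR] = np.concatenate(nvr_pos)
    pools[CAT_RVR] = np.concatenate(rvr_pos)
    dmap = degeneracy_classify(cds_seq,
                               np.arange(cds_start, cds_start + config.cds_length),
                               "synthetic_tx", config.chromosome)
    folds = np.array([dmap.position_fold[p]
                      for p in range(cds_start, cds_start + config.cds_length)])
    pools[CAT_NONSYN] = np.arange(cds_start, cds_start + config.cds_length)[folds == 0]
    pools[CAT_SYN] = np.arange(cds_start, cds_start + config.cds_length)[folds > 0]
    pools[CAT_NONCODING] = np.concatenate([
        np.arange(s, e) for s, e in noncoding[["start", "end"]].to_numpy()
    ])

    # --- expected spectra and variant placement ----------------------------
    n = config.n_chromosomes
    cache: SelectionSpectrumCache | None = None
    variants: list[PolarizedVariant] = []
    truth_rows = []
    for category, pool in pools.items():
        theta = config.theta_per_site * config.theta_scale * len(pool)
        model = DemographyModel(config.demography.ne, config.demography.omega,
                                config.demography.tau, theta=1.0)
        dfe = config.dfes.get(category)
        if dfe is None:
            unit = expected_sfs_two_epoch(0.0, model, n)
        else:
            if cache is None:
                cache = SelectionSpectrumCache(model, n)
            unit = cache.expected_sfs(dfe)
        expected = theta * unit
        counts = rng.poisson(expected)
        total = int(counts.sum())
        if total > len(pool):
            raise ValueError(
                f"theta too large for category {category}: "
                f"{total} variants for {len(pool)} sites"
            )
        sites = rng.choice(pool, size=total, replace=False)
        k = 0
        for dac_minus_1, c in enumerate(counts):
            for _ in range(int(c)):
                position = int(sites[k]); k += 1
                ancestral = ancestral_genome[position]
                derived = str(rng.choice(_NUCS[_NUCS != ancestral]))
                dac = dac_minus_1 + 1
                if rng.random() < dac / n:  # reference panel carries derived
                    ref, alt, ac = derived, ancestral, n - dac
                else:
                    ref, alt, ac = ancestral, derived, dac
                variants.append(PolarizedVariant(
                    config.chromosome, position, ref, alt, ancestral,
                    dac, n,
                ))
                truth_rows.append({"chrom": config.chromosome,
                                   "pos": position + 1,
                                   "category": category, "ref": ref,
                                   "alt": alt, "ac": ac})
    order = np.argsort([v.position for v in variants], kind="stable")
    variants = [variants[i] for i in order]
    truth_df = pd.DataFrame(truth_rows).iloc[order].reset_index(drop=True)
    return SyntheticBundle(
        config=config, elements=elements, truth_masks=truth,
        ancestral_genome=ancestral_genome, variants=variants,
        truth_categories=truth_df, cds_sequence=cds_seq, cds_start=cds_start,
        noncoding_intervals=noncoding,
    )


def generate_variants(
    config: GeneratorConfig,
) -> tuple[list[PolarizedVariant], pd.DataFrame]:
    """Polarized variants with PRF-drawn DACs plus their truth categories."""
    bundle = generate_bundle(config)
    return bundle.variants, bundle.truth_categories


def ascertain_hapmap_style(
    variants: list[PolarizedVariant], min_maf: float = 0.05
) -> list[PolarizedVariant]:
    """Common-allele ascertainment: keep variants with minor allele frequency
    above ``min_maf`` (discovery panels preferring common SNPs)."""
    return [v for v in variants if v.minor_allele_frequency > min_maf]


# ---------------------------------------------------------------------------
# On-disk bundle
# ---------------------------------------------------------------------------

def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as standard files (FASTA/BED/VCF/TSV); deterministic."""
    outdir = Path(outdir)
    (outdir / "alignments").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for el in bundle.elements:
        p = outdir / "alignments" / f"{el.element_id}.fa"
        with open(p, "w") as fh:
            for sp, seq in el.sequences.items():
                fh.write(f">{sp}\n{seq}\n")
    paths["alignments"] = outdir / "alignments"

    anchors = bundle.anchors_frame
    paths["anchors"] = outdir / "anchors.bed"
    anchors.to_csv(paths["anchors"], sep="\t", header=False, index=False)

    cfg = bundle.config
    exons = pd.DataFrame([{"chrom": cfg.chromosome, "start": bundle.cds_start,
                           "end": bundle.cds_start + cfg.cds_length,
                           "name": "synthetic_tx"}])
    paths["exons"] = outdir / "exons.bed"
    exons.to_csv(paths["exons"], sep="\t", header=False, index=False)

    paths["cds"] = outdir / "cds.fa"
    with open(paths["cds"], "w") as fh:
        fh.write(f">synthetic_tx {cfg.chromosome}:{bundle.cds_start}\n"
                 f"{bundle.cds_sequence}\n")

    paths["ancestral"] = outdir / "ancestral.fa"
    with open(paths["ancestral"], "w") as fh:
        fh.write(f">{cfg.chromosome}\n")
        seq = bundle.ancestral_genome
        for i in range(0, len(seq), 80):
            fh.write(seq[i:i + 80] + "\n")

    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele count">')
    header.add_line('##INFO=<ID=AN,Number=1,Type=Integer,Description="Total allele number">')
    header.add_line('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">')
    header.contigs.add(cfg.chromosome, length=len(bundle.ancestral_genome))
    paths["vcf"] = outdir / "variants.vcf"
    with pysam.VariantFile(str(paths["vcf"]), "w", header=header) as vf:
        for v, t in zip(bundle.variants, bundle.truth_categories.itertuples()):
            rec = vf.new_record(contig=v.chromosome, start=v.position,
                                stop=v.position + 1, alleles=(v.ref, v.alt))
            rec.info["AC"] = (int(t.ac),)
            rec.info["AN"] = v.total_chromosomes
            rec.info["AA"] = v.ancestral
            vf.write(rec)

    paths["truth"] = outdir / "truth_categories.tsv"
    bundle.truth_categories.to_csv(paths["truth"], sep="\t", index=False)
    truth_masks = pd.DataFrame([
        {"element_id": eid, "labels": "".join("N" if l == "NVR" else "R"
                                              for l in labels)}
        for eid, labels in bundle.truth_masks.items()
    ])
    paths["truth_masks"] = outdir / "truth_masks.tsv"
    truth_masks.to_csv(paths["truth_masks"], sep="\t", index=False)
    return paths
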