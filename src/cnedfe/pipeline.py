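"""End-to-end orchestration: classify -> map variants -> spectra/tests -> DFE.

``run_full`` drives the whole analysis from a :class:`RunConfig` (usually
loaded from YAML) and writes the report bundle: a polymorphism table (sites,
SNPs, % polymorphic at each DAC threshold per category), a pairwise-test
table (chi-square on proportions, KS on derived-allele-frequency spectra),
optional demography + DFE fits, and a JSON run log with seed, versions and
exclusion tallies (including the reclassified-column count).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .elements import (
    InputError, classify_columns, read_alignments, read_anchor_bed,
    reclassify_focal_only, summarize_classes, write_class_summary,
    write_mask_bed,
)
from .estimators import GammaDFEEstimator, TwoEpochDemographyEstimator, lethal_fraction
from .spectra import (
    UnfoldedSFS, build_sfs, cumulative_daf_curve, pairwise_tests_table,
    polymorphism_table,
)
from .variants import (
    CAT_NONCODING, CAT_NONSYN, CAT_NVR, CAT_RVR, CAT_SYN,
    CategoryAssigner, build_noncoding_control, degeneracy_classify,
    flag_ancestral_cpg, read_vcf, variants_to_frame,
)

log = logging.getLogger("cnedfe")

CATEGORIES = (CAT_NVR, CAT_RVR, CAT_NONSYN, CAT_SYN, CAT_NONCODING)


@dataclass
class RunConfig:
    """Paths and options for a full run (all paths must exist at validation)."""

    alignments_dir: str
    anchors_bed: str
    vcf: str
    output_dir: str
    exons_bed: str | None = None
    cds_fasta: str | None = None
    ancestral_fasta: str | None = None
    excluded_bed: str | None = None
    focal_species: str = "human"
    n_chromosomes: int = 120
    dac_thresholds: tuple[int, ...] = (1, 6)
    continuity_correction: bool = False
    fit_dfe: bool = False
    dfe_neutral_category: str = CAT_NONCODING
    dfe_selected_categories: tuple[str, ...] = (CAT_NVR,)
    ne: float = 16000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for key in ("alignments_dir", "anchors_bed", "vcf", "exons_bed",
                    "cds_fasta", "ancestral_fasta", "excluded_bed"):
            value = getattr(self, key)
            if value is not None and not Path(value).exists():
                raise InputError(f"{key} does not exist: {value}")
        if any(t < 1 for t in self.dac_thresholds):
            raise InputError("DAC thresholds must be >= 1")


def _read_bed3(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    df["chrom"] = df["chrom"].astype(str)
    return df


def run_full(config: RunConfig) -> dict:
    """Execute every stage; returns the report dict written to the output dir."""
    config.validate()
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed}

    # --- stage 1: classification -------------------------------------------
    stage = "classify"
    try:
        anchors = read_anchor_bed(config.anchors_bed)
        fasta_paths = sorted(Path(config.alignments_dir).glob("*.fa")) + \
            sorted(Path(config.alignments_dir).glob("*.fasta"))
        elements = read_alignments(fasta_paths, anchors, config.focal_species)
        masks = [reclassify_focal_only(classify_columns(el), el)
                 for el in elements]
        class_summary = summarize_classes(masks)
        report["site_classes"] = class_summary
        write_mask_bed(masks, outdir / "site_classes.bed")
        write_class_summary(masks, outdir / "site_classes_summary.tsv")
        log.info("classified %d elements: %s", len(elements), class_summary)

        # --- stage 2: variant mapping ---------------------------------------
        stage = "map-variants"
        variants, excluded = read_vcf(config.vcf)
        report["vcf_exclusions"] = dict(excluded)
        exons = _read_bed3(config.exons_bed) if config.exons_bed else None
        excluded_bed = _read_bed3(config.excluded_bed) if config.excluded_bed else None
        anchors_df = pd.DataFrame([
            {"chrom": a.chromosome, "start": a.start, "end": a.end}
            for a in anchors.values()
        ])
        noncoding = build_noncoding_control(anchors_df, exons, excluded_bed)
        assigner = CategoryAssigner(masks, noncoding_intervals=noncoding)
        if config.cds_fasta:
            for rec in SeqIO.parse(config.cds_fasta, "fasta"):
                # description: ">tx_id chrom:start" (contiguous forward CDS)
                chrom, start = rec.description.split()[-1].split(":")
                coords = np.arange(int(start), int(start) + len(rec.seq))
                dmap = degeneracy_classify(str(rec.seq), coords, rec.id, chrom)
                assigner.add_degeneracy(chrom, dmap)
                report.setdefault("degeneracy_totals", {})[rec.id] = dmap.fold_totals()
        for v in variants:
            assigner.assign(v)
        if config.ancestral_fasta:
            context = {rec.id: str(rec.seq)
                       for rec in SeqIO.parse(config.ancestral_fasta, "fasta")}
            for v in variants:
                flag_ancestral_cpg(v, context)
        retained = [v for v in variants if v.category != "UNASSIGNED"]
        report["variants_total"] = len(variants)
        report["variants_retained"] = len(retained)
        variants_to_frame(retained).to_csv(outdir / "variants_categorized.tsv",
                                           sep="\t", index=False)

        # --- stage 3: spectra and tests --------------------------------------
        stage = "sfs-tests"
        sites = _sites_per_category(class_summary, assigner, noncoding, config)
        spectra: dict[str, dict[int, UnfoldedSFS]] = {}
        for category in CATEGORIES:
            cat_variants = [v for v in retained if v.category == category]
            by_thr = {}
            for thr in config.dac_thresholds:
                by_thr[thr] = build_sfs(cat_variants, category, sites[category],
                                        config.n_chromosomes, thr)
            spectra[category] = by_thr
        table2 = polymorphism_table(spectra)
        table2.to_csv(outdir / "polymorphism_table.tsv", sep="\t", index=False)
        thr_main = max(config.dac_thresholds)
        main = {c: spectra[c][thr_main] for c in CATEGORIES
                if spectra[c][thr_main].n_snps > 0}
        table3 = pairwise_tests_table(main, config.continuity_correction)
        table3.to_csv(outdir / "pairwise_tests.tsv", sep="\t", index=False)
        curves = []
        for category, sfs in main.items():
            curve = cumulative_daf_curve(sfs)
            curve.insert(0, "category", category)
            curves.append(curve)
        pd.concat(curves).to_csv(outdir / "cumulative_daf.tsv", sep="\t",
                                 index=False)
        report["polymorphism_table"] = table2.to_dict(orient="records")

        # --- stage 4: demography + DFE ---------------------------------------
        if config.fit_dfe:
            stage = "fit-demography"
            neutral = spectra[config.dfe_neutral_category][min(config.dac_thresholds)]
            dem_est = TwoEpochDemographyEstimator(ne=config.ne,
                                                  seed=config.seed or 20140725)
            dem_est.fit(neutral)
            report["demography"] = {
                "omega": dem_est.omega_, "tau": dem_est.tau_,
                "theta": dem_est.theta_, "loglik": dem_est.loglik_, "ne": config.ne,
            }
            stage = "fit-dfe"
            report["dfe"] = {}
            for category in config.dfe_selected_categories:
                sel = spectra[category][min(config.dac_thresholds)]
                dfe_est = GammaDFEEstimator(demography=dem_est.model_,
                                            seed=config.seed or 20140725)
                dfe_est.fit(sel)
                report["dfe"][category] = {
                    "shape": dfe_est.shape_, "rate": dfe_est.rate_,
                    "theta": dfe_est.theta_, "loglik": dfe_est.loglik_,
                    "shape_ci": list(dfe_est.shape_ci_),
                    "lethal_fraction": lethal_fraction(dfe_est.dfe_),
                }
    except Exception as err:
        log.error("stage %s failed: %s", stage, err)
        (outdir / "run_log.json").write_text(json.dumps(
            {"failed_stage": stage, "error": str(err), **report}, indent=2,
            default=str))
        raise

    report["runtime_s"] = round(time.time() - t0, 2)
    (outdir / "run_log.json").write_text(json.dumps(report, indent=2,
                                                    default=str))
    return report


def _sites_per_category(class_summary, assigner: CategoryAssigner,
                        noncoding: pd.DataFrame, config: RunConfig) -> dict[str, int]:
    nonsyn = sum(1 for cat in assigner._coding.values() if cat == CAT_NONSYN)
    syn = sum(1 for cat in assigner._coding.values() if cat == CAT_SYN)
    return {
        CAT_NVR: class_summary["NVR"],
        CAT_RVR: class_summary["RVR"],
        CAT_NONSYN: nonsyn,
        CAT_SYN: syn,
        CAT_NONCODING: int((noncoding["end"] - noncoding["start"]).sum())
        if len(noncoding) else 0,
    }
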