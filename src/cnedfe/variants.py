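"""Variant ingestion, polarization and site-category assignment.

Variants come from a sites-level VCF carrying INFO/AC, INFO/AN and an
ancestral-allele annotation (INFO/AA). Each biallelic SNV is polarized to a
derived allele count (DAC) out of AN sampled chromosomes and assigned to one
of the analysis categories: CNE-NVR, CNE-RVR, non-synonymous (0-fold
degenerate coding), synonymous (2- or 4-fold degenerate), or the non-coding
control built from CNE flanks. Category precedence is CNE > coding >
non-coding; anything else is UNASSIGNED and excluded from tables.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pyranges as pr
import pysam
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .elements import SiteClassMask, InputError

# categories
CAT_NVR = "NVR"
CAT_RVR = "RVR"
CAT_NONSYN = "NONSYN"
CAT_SYN = "SYN"
CAT_NONCODING = "NONCODING"
CAT_UNASSIGNED = "UNASSIGNED"

_NUCS = ("A", "C", "G", "T")


@dataclass
class PolarizedVariant:
    """A biallelic SNV polarized by ancestral state.

    ``position`` is 0-based (converted once at the parser boundary; VCF on
    disk is 1-based). ``derived_count`` is the number of sampled chromosomes
    carrying the non-ancestral allele.
    """

    chromosome: str
    position: int
    ref: str
    alt: str
    ancestral: str
    derived_count: int
    total_chromosomes: int
    category: str = CAT_UNASSIGNED
    at_ancestral_cpg: bool | None = None
    element_id: str | None = None

    @property
    def derived_frequency(self) -> float:
        return self.derived_count / self.total_chromosomes

    @property
    def minor_allele_frequency(self) -> float:
        f = self.derived_frequency
        return min(f, 1.0 - f)


def polarize(
    ref: str,
    alt: str,
    ancestral: str | None,
    alt_count: int,
    an: int,
    *,
    chromosome: str = ".",
    position: int = 0,
    accept_lowercase_ancestral: bool = False,
) -> tuple[PolarizedVariant | None, str | None]:
    """Polarize one biallelic SNV; returns (variant, None) or (None, reason).

    DAC = alt_count when the ancestral allele is REF, AN - alt_count when it
    is ALT. Exclusion reasons: ``zero_alt_count``, ``missing_ancestral``,
    ``low_confidence_ancestral`` (lowercase AA, excluded by default),
    ``ancestral_mismatch`` (AA is neither REF nor ALT), ``monomorphic``.
    """
    if an <= 0:
        raise InputError("AN must be positive")
    if alt_count == 0:
        return None, "zero_alt_count"
    if ancestral is None or ancestral in (".", "", "N", "n", "-"):
        return None, "missing_ancestral"
    if ancestral != ancestral.upper() and not accept_lowercase_ancestral:
        return None, "low_confidence_ancestral"
    ancestral = ancestral.upper()
    if ancestral == ref:
        dac = alt_count
    elif ancestral == alt:
        dac = an - alt_count
    else:
        return None, "ancestral_mismatch"
    if dac <= 0 or dac >= an:
        return None, "monomorphic"
    return (
        PolarizedVariant(chromosome, position, ref, alt, ancestral, dac, an),
        None,
    )


def read_vcf(
    path: str | Path,
    *,
    accept_lowercase_ancestral: bool = False,
) -> tuple[list[PolarizedVariant], Counter]:
    """Read a sites VCF and polarize every biallelic SNV.

    Multiallelic records and indels are excluded (SNP-only analysis), as are
    records failing :func:`polarize`. Returns the retained variants and a
    Counter of exclusion reason codes. Positions are converted to 0-based.
    """
    variants: list[PolarizedVariant] = []
    excluded: Counter = Counter()
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                excluded["multiallelic_or_no_alt"] += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in _NUCS or alt not in _NUCS:
                excluded["not_snv"] += 1
                continue
            info = rec.info
            try:
                ac = info["AC"]
                ac = int(ac[0] if isinstance(ac, tuple) else ac)
                an = int(info["AN"])
            except KeyError:
                excluded["missing_ac_an"] += 1
                continue
            aa = info.get("AA")
            aa = str(aa) if aa is not None else None
            variant, reason = polarize(
                ref, alt, aa, ac, an,
                chromosome=rec.chrom, position=rec.start,
                accept_lowercase_ancestral=accept_lowercase_ancestral,
            )
            if variant is None:
                excluded[reason] += 1
            else:
                variants.append(variant)
    return variants, excluded


# ---------------------------------------------------------------------------
# Codon degeneracy
# ---------------------------------------------------------------------------

def _codon_fold(codon: str, pos: int) -> int:
    """Degeneracy (0/2/4) of position ``pos`` in ``codon``: the number of the
    three alternative bases giving a synonymous codon (0 -> 0-fold, 1 or 2 ->
    2-fold, 3 -> 4-fold)."""
    table = standard_dna_table.forward_table
    stops = set(standard_dna_table.stop_codons)

    def product(c: str) -> str:
        return "*" if c in stops else table[c]

    aa = product(codon)
    syn = 0
    for b in _NUCS:
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1:]
        if product(alt) == aa:
            syn += 1
    if syn == 0:
        return 0
    if syn == 3:
        return 4
    return 2


@dataclass
class DegeneracyMap:
    """Per-position degeneracy of one transcript's CDS on genomic coordinates."""

    transcript_id: str
    position_fold: dict[int, int]  # genomic position (0-based) -> 0/2/4
    chromosome: str = "."

    def category_of(self, position: int) -> str | None:
        fold = self.position_fold.get(position)
        if fold is None:
            return None
        return CAT_NONSYN if fold == 0 else CAT_SYN

    def fold_totals(self) -> dict[int, int]:
        c = Counter(self.position_fold.values())
        return {0: c.get(0, 0), 2: c.get(2, 0), 4: c.get(4, 0)}


def degeneracy_classify(
    cds_sequence: str,
    genomic_coords: Sequence[int],
    transcript_id: str = "tx",
    chromosome: str = ".",
) -> DegeneracyMap:
    """Label every CDS position 0-, 2- or 4-fold degenerate.

    ``genomic_coords[k]`` is the genomic coordinate of CDS position k (the
    caller supplies the exon/strand layout). Non-synonymous sites are the
    0-fold positions; synonymous sites are 2-fold plus 4-fold.
    """
    cds = cds_sequence.upper()
    if len(cds) % 3 != 0:
        raise InputError("CDS length not divisible by 3")
    if len(genomic_coords) != len(cds):
        raise InputError("genomic_coords length != CDS length")
    if any(b not in _NUCS for b in cds):
        raise InputError("invalid base in CDS")
    prot = str(Seq(cds).translate())
    if "*" in prot[:-1]:
        raise InputError("internal stop codon in CDS")
    mapping: dict[int, int] = {}
    for k in range(len(cds)):
        codon = cds[3 * (k // 3): 3 * (k // 3) + 3]
        mapping[int(genomic_coords[k])] = _codon_fold(codon, k % 3)
    return DegeneracyMap(transcript_id, mapping, chromosome)


def longest_cds_transcript(transcripts: Mapping[str, str]) -> str:
    """Pick the transcript with the longest CDS; ties broken by id."""
    return min(transcripts, key=lambda t: (-len(transcripts[t]), t))


# ---------------------------------------------------------------------------
# Non-coding control intervals
# ---------------------------------------------------------------------------

def _to_ranges(df: pd.DataFrame) -> pr.PyRanges:
    return pr.PyRanges(
        pd.DataFrame({
            "Chromosome": df["chrom"].astype(str),
            "Start": df["start"].astype(np.int64),
            "End": df["end"].astype(np.int64),
        })
    )


def build_noncoding_control(
    cne_anchors: pd.DataFrame,
    exons: pd.DataFrame | None = None,
    excluded_elements: pd.DataFrame | None = None,
    flank_near: int = 5000,
    flank_far: int = 6000,
) -> pd.DataFrame:
    """Non-coding control intervals: per-CNE flanks minus exclusions.

    For each CNE anchor the bands ``[start-far, start-near)`` and
    ``[end+near, end+far)`` are retained, then known exons, all CNEs and any
    excluded conserved elements are subtracted. Inputs and output are
    BED-style frames with columns chrom/start/end; negative coordinates are
    clipped at 0. The retained total length is ``(out.end - out.start).sum()``.
    """
    if flank_near >= flank_far:
        raise InputError("flank_near must be < flank_far")
    left = cne_anchors.assign(
        start=(cne_anchors["start"] - flank_far).clip(lower=0),
        end=(cne_anchors["start"] - flank_near).clip(lower=0),
    )
    right = cne_anchors.assign(
        start=cne_anchors["end"] + flank_near,
        end=cne_anchors["end"] + flank_far,
    )
    flanks = pd.concat([left, right], ignore_index=True)
    flanks = flanks[flanks["end"] > flanks["start"]]
    ranges = _to_ranges(flanks).merge()
    for excl in (exons, cne_anchors, excluded_elements):
        if excl is not None and len(excl):
            ranges = ranges.subtract(_to_ranges(excl))
    df = ranges.df
    if df.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    out = df.rename(columns={"Chromosome": "chrom", "Start": "start", "End": "end"})
    return out[["chrom", "start", "end"]].sort_values(["chrom", "start"]).reset_index(drop=True)


def _interval_index(intervals: pd.DataFrame) -> dict[str, np.ndarray]:
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, grp in intervals.groupby("chrom", observed=True):
        arr = grp[["start", "end"]].to_numpy(dtype=np.int64)
        by_chrom[str(chrom)] = arr[np.argsort(arr[:, 0])]
    return by_chrom


def _in_intervals(index: dict[str, np.ndarray], chrom: str, pos: int) -> bool:
    arr = index.get(chrom)
    if arr is None or not len(arr):
        return False
    i = np.searchsorted(arr[:, 0], pos, side="right") - 1
    return i >= 0 and pos < arr[i, 1]


# ---------------------------------------------------------------------------
# Category assignment and CpG context
# ---------------------------------------------------------------------------

class CategoryAssigner:
    """Assigns a category to each variant with precedence CNE > coding > non-coding."""

    def __init__(
        self,
        masks: Iterable[SiteClassMask],
        degeneracy_maps: Iterable[DegeneracyMap] = (),
        noncoding_intervals: pd.DataFrame | None = None,
    ) -> None:
        # genomic position -> (label, element_id); focal-gap columns carry no coordinate
        self._cne: dict[tuple[str, int], tuple[str, str]] = {}
        self._cne_span: list[tuple[str, int, int, str]] = []
        for mask in masks:
            chrom = mask.anchor.chromosome
            self._cne_span.append((chrom, mask.anchor.start, mask.anchor.end, mask.element_id))
            for col, g in enumerate(mask.column_to_genome):
                if g >= 0:
                    self._cne[(chrom, int(g))] = (str(mask.labels[col]), mask.element_id)
        self._coding: dict[tuple[str, int], str] = {}
        for dm in degeneracy_maps:
            self.add_degeneracy(dm.chromosome, dm)
        self._noncoding = (
            _interval_index(noncoding_intervals)
            if noncoding_intervals is not None and len(noncoding_intervals)
            else {}
        )

    def add_degeneracy(self, chrom: str, dmap: DegeneracyMap) -> None:
        for pos, fold in dmap.position_fold.items():
            self._coding[(chrom, pos)] = CAT_NONSYN if fold == 0 else CAT_SYN

    def assign(self, variant: PolarizedVariant) -> PolarizedVariant:
        """Return the variant with its category (and element id) set."""
        key = (variant.chromosome, variant.position)
        hit = self._cne.get(key)
        if hit is not None:
            label, element_id = hit
            variant.element_id = element_id
            if label in (CAT_NVR, CAT_RVR):
                variant.category = label
            else:
                variant.category = CAT_UNASSIGNED  # UNASSESSED column
            return variant
        for chrom, start, end, element_id in self._cne_span:
            if variant.chromosome == chrom and start <= variant.position < end:
                # inside a CNE but at a focal-gap column: no coordinate mapping
                variant.category = CAT_UNASSIGNED
                variant.element_id = element_id
                return variant
        cat = self._coding.get(key)
        if cat is not None:
            variant.category = cat
            return variant
        if _in_intervals(self._noncoding, variant.chromosome, variant.position):
            variant.category = CAT_NONCODING
            return variant
        variant.category = CAT_UNASSIGNED
        return variant


def assign_categories(
    variants: Iterable[PolarizedVariant],
    assigner: CategoryAssigner,
) -> list[PolarizedVariant]:
    return [assigner.assign(v) for v in variants]


def flag_ancestral_cpg(
    variant: PolarizedVariant,
    ancestral_context: Mapping[str, str],
) -> bool | None:
    """True iff the variant sits at the C of an ancestral CpG (strand-symmetric:
    also the G preceded by ancestral C). ``ancestral_context`` maps chromosome
    to the ancestral sequence; returns None when context is unavailable, in
    which case the variant is excluded from CpG tables only."""
    seq = ancestral_context.get(variant.chromosome)
    if seq is None or not (0 <= variant.position < len(seq)):
        variant.at_ancestral_cpg = None
        return None
    base = seq[variant.position].upper()
    nxt = seq[variant.position + 1].upper() if variant.position + 1 < len(seq) else ""
    prv = seq[variant.position - 1].upper() if variant.position > 0 else ""
    flag = (base == "C" and nxt == "G") or (base == "G" and prv == "C")
    variant.at_ancestral_cpg = flag
    return flag


def variants_to_frame(variants: Iterable[PolarizedVariant]) -> pd.DataFrame:
    """Categorized variants as a TSV-ready frame (positions back to 1-based)."""
    rows = [{
        "chrom": v.chromosome,
        "pos": v.position + 1,
        "ref": v.ref,
        "alt": v.alt,
        "ancestral": v.ancestral,
        "DAC": v.derived_count,
        "AN": v.total_chromosomes,
        "category": v.category,
        "cpg": v.at_ancestral_cpg,
        "element_id": v.element_id,
    } for v in variants]
    return pd.DataFrame(rows)
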