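"""Cross-species site classification inside conserved non-coding elements (CNEs).

A CNE is represented by a multi-species alignment in which one row is the
focal (human) reference. Classification masks the focal row and labels every
alignment column by what the remaining species show:

* ``NVR`` (non-variable region): all non-focal species carry the identical
  nucleotide.
* ``RVR`` (restricted-variable region): at least one non-focal species
  differs (a gap in a non-focal row counts as a difference).
* ``UNASSESSED``: an ambiguity code (N, R, Y, ...) in a non-focal row makes
  identity unverifiable; the column is excluded from all counts.

A second pass flags columns where the focal reference alone differs from an
otherwise invariant column; these stay NVR and are marked *reclassified*
(an NVR that is polymorphic in the focal lineage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

NVR = "NVR"
RVR = "RVR"
UNASSESSED = "UNASSESSED"

_GAP = "-"
_NUCS = frozenset("ACGT")
_IUPAC = frozenset("ACGTRYSWKMBDHVN-")


class AlignmentError(ValueError):
    """Rows of unequal length or other structural defects in an alignment."""


class InputError(ValueError):
    """Malformed or inconsistent user input."""


@dataclass
class Anchor:
    """Genomic anchor of an element: 0-based, half-open, stranded."""

    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise InputError(f"strand must be + or -, got {self.strand!r}")
        if self.end < self.start:
            raise InputError("anchor end < start")


@dataclass
class AlignedElement:
    """One CNE's multi-species alignment plus its genomic anchor.

    ``sequences`` maps species name to the aligned (gapped) sequence; the
    focal species row is the reference sequence of the anchor genome.
    """

    element_id: str
    sequences: dict[str, str]
    anchor: Anchor
    focal_species: str = "human"

    def __post_init__(self) -> None:
        self.sequences = {sp: seq.upper() for sp, seq in self.sequences.items()}
        if self.focal_species not in self.sequences:
            raise InputError(
                f"focal species {self.focal_species!r} absent from alignment "
                f"{self.element_id!r}"
            )
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise AlignmentError(
                f"unequal sequence lengths in element {self.element_id!r}: {lengths}"
            )
        for sp, seq in self.sequences.items():
            bad = set(seq) - _IUPAC
            if bad:
                raise InputError(
                    f"non-IUPAC characters {bad} in {sp!r} of {self.element_id!r}"
                )
        span = self.anchor.end - self.anchor.start
        ungapped = len(self.focal_sequence.replace(_GAP, ""))
        if span != ungapped:
            raise InputError(
                f"anchor span {span} != focal non-gap length {ungapped} "
                f"in {self.element_id!r}"
            )

    @property
    def length(self) -> int:
        return len(self.focal_sequence)

    @property
    def focal_sequence(self) -> str:
        return self.sequences[self.focal_species]

    @property
    def nonfocal_species(self) -> list[str]:
        return [sp for sp in self.sequences if sp != self.focal_species]


@dataclass
class SiteClassMask:
    """Per-column NVR/RVR labels for one element.

    ``column_to_genome[k]`` is the genomic coordinate of alignment column k,
    or -1 for columns that are gaps in the focal row (no coordinate).
    ``reclassified`` may be true only at NVR columns.
    """

    element_id: str
    labels: np.ndarray  # dtype '<U10'
    reclassified: np.ndarray  # bool
    column_to_genome: np.ndarray  # int64, -1 = no coordinate
    anchor: Anchor = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.reclassified) == len(self.column_to_genome)):
            raise AlignmentError("mask arrays of unequal length")
        if np.any(self.reclassified & (self.labels != NVR)):
            raise AlignmentError("reclassified flag set on a non-NVR column")

    def counts(self) -> dict[str, int]:
        lab = self.labels
        return {
            NVR: int(np.sum(lab == NVR)),
            RVR: int(np.sum(lab == RVR)),
            UNASSESSED: int(np.sum(lab == UNASSESSED)),
        }

    def genome_to_column(self) -> dict[int, int]:
        """Inverse of ``column_to_genome`` on focal non-gap columns."""
        return {int(g): k for k, g in enumerate(self.column_to_genome) if g >= 0}


def _column_coordinates(element: AlignedElement) -> np.ndarray:
    """Genomic coordinate per column; -1 at focal-gap columns.

    On the minus strand the element sequence is the reverse complement of the
    genome, so the first focal base maps to ``end - 1`` and coordinates run
    downward.
    """
    coords = np.full(element.length, -1, dtype=np.int64)
    k = 0
    for col, base in enumerate(element.focal_sequence):
        if base == _GAP:
            continue
        if element.anchor.strand == "+":
            coords[col] = element.anchor.start + k
        else:
            coords[col] = element.anchor.end - 1 - k
        k += 1
    return coords


def classify_columns(element: AlignedElement) -> SiteClassMask:
    """Label every alignment column NVR/RVR/UNASSESSED, ignoring the focal row.

    A column is NVR when all non-focal rows carry the same A/C/G/T base; a
    column where any non-focal row differs (including by a gap) is RVR; a
    column containing an ambiguity code in a non-focal row is UNASSESSED.
    """
    nonfocal = element.nonfocal_species
    if len(nonfocal) < 2:
        raise InputError(
            f"element {element.element_id!r} needs >= 2 non-focal species, "
            f"got {len(nonfocal)}"
        )
    rows = np.array([list(element.sequences[sp]) for sp in nonfocal])
    labels = np.empty(element.length, dtype="<U10")
    for col in range(element.length):
        chars = rows[:, col]
        if any(c not in _NUCS and c != _GAP for c in chars):
            labels[col] = UNASSESSED
        elif _GAP in chars:
            labels[col] = RVR
        elif len(set(chars)) == 1:
            labels[col] = NVR
        else:
            labels[col] = RVR
    return SiteClassMask(
        element_id=element.element_id,
        labels=labels,
        reclassified=np.zeros(element.length, dtype=bool),
        column_to_genome=_column_coordinates(element),
        anchor=element.anchor,
    )


def reclassify_focal_only(mask: SiteClassMask, element: AlignedElement) -> SiteClassMask:
    """Flag NVR columns where the focal reference alone carries a different base.

    Classification already ignores the focal row, so such columns are NVR;
    this pass marks them as NVRs that are polymorphic in the focal lineage
    (``reclassified``). Returns a new mask; ``mask.reclassified.sum()`` of the
    result is the per-run reclassified-column tally.
    """
    focal = element.focal_sequence
    nonfocal = element.nonfocal_species
    reclassified = mask.reclassified.copy()
    for col in range(element.length):
        if mask.labels[col] != NVR:
            continue
        consensus = element.sequences[nonfocal[0]][col]
        fb = focal[col]
        if fb in _NUCS and fb != consensus:
            reclassified[col] = True
    return SiteClassMask(
        element_id=mask.element_id,
        labels=mask.labels.copy(),
        reclassified=reclassified,
        column_to_genome=mask.column_to_genome.copy(),
        anchor=mask.anchor,
    )


def classify_element(element: AlignedElement) -> SiteClassMask:
    """classify_columns followed by the focal-only reclassification pass."""
    return reclassify_focal_only(classify_columns(element), element)


def summarize_classes(masks: Iterable[SiteClassMask]) -> dict[str, int]:
    """Pooled site totals: assessed columns, NVR, RVR, and reclassified count."""
    masks = list(masks)
    if not masks:
        raise InputError("no masks to summarize")
    nvr = sum(m.counts()[NVR] for m in masks)
    rvr = sum(m.counts()[RVR] for m in masks)
    unassessed = sum(m.counts()[UNASSESSED] for m in masks)
    return {
        "assessed": nvr + rvr,
        "NVR": nvr,
        "RVR": rvr,
        "UNASSESSED": unassessed,
        "reclassified": int(sum(m.reclassified.sum() for m in masks)),
    }


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_anchor_bed(path: str | Path) -> dict[str, Anchor]:
    """Read element anchors from BED (name column = element id)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6), dtype={"chrom": str, "name": str},
    )
    out: dict[str, Anchor] = {}
    for row in df.itertuples(index=False):
        out[row.name] = Anchor(row.chrom, int(row.start), int(row.end),
                               row.strand if row.strand in "+-" else "+")
    return out


def read_alignments(
    fasta_paths: Iterable[str | Path],
    anchors: Mapping[str, Anchor],
    focal_species: str = "human",
) -> list[AlignedElement]:
    """Read one aligned multi-FASTA per element (record id = species name).

    The element id is the FASTA file stem and must have an anchor entry.
    """
    elements = []
    for path in fasta_paths:
        path = Path(path)
        element_id = path.stem
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if element_id not in anchors:
            raise InputError(f"no anchor for element {element_id!r}")
        elements.append(
            AlignedElement(element_id, seqs, anchors[element_id], focal_species)
        )
    return elements


def write_mask_bed(masks: Iterable[SiteClassMask], path: str | Path) -> None:
    """Write masks as BED: one interval per maximal same-class run of columns.

    Name = class label, score = 1 when any column of the run is reclassified.
    Focal-gap columns (no genomic coordinate) are skipped.
    """
    rows = []
    for mask in masks:
        coords = mask.column_to_genome
        order = np.argsort(coords)
        run = None  # [start, end, label, reclass]
        for k in order:
            g = coords[k]
            if g < 0:
                continue
            lab = mask.labels[k]
            rec = bool(mask.reclassified[k])
            if run is not None and g == run[1] and lab == run[2]:
                run[1] = g + 1
                run[3] = run[3] or rec
            else:
                if run is not None:
                    rows.append((mask.anchor.chromosome, run[0], run[1], run[2],
                                 int(run[3]), mask.anchor.strand, mask.element_id))
                run = [g, g + 1, lab, rec]
        if run is not None:
            rows.append((mask.anchor.chromosome, run[0], run[1], run[2],
                         int(run[3]), mask.anchor.strand, mask.element_id))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                     "score", "strand", "element_id"])
    df.to_csv(path, sep="\t", header=False, index=False)


def write_class_summary(masks: Sequence[SiteClassMask], path: str | Path) -> None:
    per_elem = []
    for m in masks:
        c = m.counts()
        per_elem.append({"element_id": m.element_id, "NVR": c[NVR], "RVR": c[RVR],
                         "UNASSESSED": c[UNASSESSED],
                         "reclassified": int(m.reclassified.sum())})
    pd.DataFrame(per_elem).to_csv(path, sep="\t", index=False)
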