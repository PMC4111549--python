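"""Unfolded site-frequency spectra and the comparisons built on them.

An unfolded SFS for a site category holds, for each derived allele count
(DAC) i = 1..n-1, the number of segregating sites observed at that count,
together with the total number of sites surveyed in the category. Two site
categories are compared by (i) a Pearson chi-square test on the 2x2 table of
polymorphic vs non-polymorphic sites and (ii) a two-sample Kolmogorov-Smirnov
test on the per-variant derived allele frequencies. CpG-SNP proportions are
made comparable across categories of different base composition by linear
rescaling to a reference G+C content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .elements import InputError
from .variants import PolarizedVariant


@dataclass
class UnfoldedSFS:
    """Counts of variants at each DAC 1..n-1 for one site category."""

    category: str
    n_chromosomes: int
    counts: np.ndarray
    sites_surveyed: int
    dac_threshold: int = 1

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != self.n_chromosomes - 1:
            raise InputError(
                f"counts length {len(self.counts)} != n-1 = {self.n_chromosomes - 1}"
            )
        if np.any(self.counts < 0):
            raise InputError("negative SFS count")
        if self.counts.sum() > self.sites_surveyed:
            raise InputError("more SNPs than sites surveyed")

    @property
    def n_snps(self) -> int:
        return int(self.counts.sum())

    @property
    def dacs(self) -> np.ndarray:
        """DAC values 1..n-1 aligned with ``counts``."""
        return np.arange(1, self.n_chromosomes)

    def frequencies(self) -> np.ndarray:
        """Per-variant derived allele frequencies (DAC/AN), one per SNP."""
        return np.repeat(self.dacs / self.n_chromosomes, self.counts)

    def thresholded(self, dac_threshold: int) -> "UnfoldedSFS":
        counts = self.counts.copy()
        counts[: dac_threshold - 1] = 0
        return UnfoldedSFS(self.category, self.n_chromosomes, counts,
                           self.sites_surveyed, dac_threshold)


def build_sfs(
    variants: Iterable[PolarizedVariant],
    category: str,
    sites_surveyed: int,
    n_chromosomes: int,
    dac_threshold: int = 1,
) -> UnfoldedSFS:
    """Tabulate variants of one category into an unfolded SFS.

    Entries with DAC below ``dac_threshold`` are zeroed; a DAC at or above
    ``n_chromosomes`` is a data error.
    """
    counts = np.zeros(n_chromosomes - 1, dtype=np.int64)
    for v in variants:
        if v.category != category:
            raise InputError(f"variant category {v.category} != {category}")
        if not 1 <= v.derived_count < n_chromosomes:
            raise InputError(
                f"DAC {v.derived_count} out of range for n={n_chromosomes}"
            )
        counts[v.derived_count - 1] += 1
    sfs = UnfoldedSFS(category, n_chromosomes, counts, sites_surveyed)
    return sfs.thresholded(dac_threshold) if dac_threshold > 1 else sfs


def proportion_polymorphic(sfs: UnfoldedSFS) -> float:
    """Percentage of surveyed sites that carry a SNP, to two decimals."""
    if sfs.sites_surveyed <= 0:
        raise InputError("sites_surveyed must be positive")
    return round(100.0 * sfs.n_snps / sfs.sites_surveyed, 2)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: int | None = None


def chi2_2x2(
    k1: int, n1: int, k2: int, n2: int, continuity_correction: bool = False
) -> TestResult:
    """Pearson chi-square (df=1) on {polymorphic, non-polymorphic} x {cat1, cat2}.

    Continuity correction is off by default; a warning (not a failure) is
    emitted when any expected cell is below 5.
    """
    if n1 <= 0 or n2 <= 0 or k1 > n1 or k2 > n2:
        raise InputError("invalid 2x2 inputs")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if k1 == 0 and k2 == 0:
        return TestResult(0.0, 1.0, "chi2", df=1)
    res = stats.chi2_contingency(table, correction=continuity_correction)
    expected = res.expected_freq
    if np.any(expected < 5):
        import warnings

        warnings.warn("chi-square expected cell below 5", stacklevel=2)
    return TestResult(float(res.statistic), float(res.pvalue), "chi2", df=1)


def ks_two_sample(
    freqs1: Sequence[float], freqs2: Sequence[float], method: str = "asymp"
) -> TestResult:
    """Two-sample KS test on per-variant derived allele frequencies."""
    f1 = np.asarray(freqs1, dtype=float)
    f2 = np.asarray(freqs2, dtype=float)
    if f1.size == 0 or f2.size == 0:
        raise InputError("empty sample in KS test")
    res = stats.ks_2samp(f1, f2, method=method)
    return TestResult(float(res.statistic), float(res.pvalue), "KS")


def cumulative_daf_curve(sfs: UnfoldedSFS) -> pd.DataFrame:
    """Cumulative proportion of SNPs at or below each derived allele frequency.

    Nondecreasing, ends at 1.0; rows only at frequencies with observed SNPs.
    """
    if sfs.n_snps == 0:
        raise InputError("empty SFS has no cumulative curve")
    mask = sfs.counts > 0
    freqs = sfs.dacs[mask] / sfs.n_chromosomes
    cum = np.cumsum(sfs.counts[mask]) / sfs.n_snps
    return pd.DataFrame({"frequency": freqs, "cumulative_proportion": cum})


def cpg_gc_normalize(
    observed_cpg_pct: float, gc_pct: float, reference_gc: float = 50.0
) -> float:
    """Rescale an observed CpG-SNP percentage to a reference G+C content.

    Linear scaling: observed x reference_gc / gc_pct, to one decimal place.
    """
    if not 0 < gc_pct < 100:
        raise InputError("gc_pct must be in (0, 100)")
    return round(observed_cpg_pct * reference_gc / gc_pct, 1)


def bin_sfs(sfs: UnfoldedSFS, bin_width: int = 3) -> pd.DataFrame:
    """Sum consecutive DAC classes in groups of ``bin_width`` (count-conserving)."""
    if bin_width < 1:
        raise InputError("bin_width must be >= 1")
    counts = sfs.counts
    nbins = int(np.ceil(len(counts) / bin_width))
    padded = np.zeros(nbins * bin_width, dtype=np.int64)
    padded[: len(counts)] = counts
    binned = padded.reshape(nbins, bin_width).sum(axis=1)
    lo = np.arange(nbins) * bin_width + 1
    hi = np.minimum(lo + bin_width - 1, len(counts))
    return pd.DataFrame({"dac_lo": lo, "dac_hi": hi, "count": binned})


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def polymorphism_table(
    spectra: dict[str, dict[int, UnfoldedSFS]]
) -> pd.DataFrame:
    """Per-category site totals, SNP counts and percent polymorphic at each
    DAC threshold (the shape of the study's summary table)."""
    rows = []
    for category, by_thr in spectra.items():
        row: dict[str, object] = {"category": category}
        for thr, sfs in sorted(by_thr.items()):
            row["sites_surveyed"] = sfs.sites_surveyed
            row[f"snps_dac_ge_{thr}"] = sfs.n_snps
            row[f"pct_polymorphic_dac_ge_{thr}"] = proportion_polymorphic(sfs)
        rows.append(row)
    return pd.DataFrame(rows)


def pairwise_tests_table(
    spectra: dict[str, UnfoldedSFS], continuity_correction: bool = False
) -> pd.DataFrame:
    """All pairwise chi-square (proportion polymorphic) and KS (DAF spectra)
    comparisons between categories."""
    cats = list(spectra)
    rows = []
    for i, a in enumerate(cats):
        for b in cats[i + 1:]:
            sa, sb = spectra[a], spectra[b]
            chi = chi2_2x2(sa.n_snps, sa.sites_surveyed, sb.n_snps,
                           sb.sites_surveyed, continuity_correction)
            if sa.n_snps and sb.n_snps:
                ks = ks_two_sample(sa.frequencies(), sb.frequencies())
                ks_stat, ks_p = ks.statistic, ks.p_value
            else:
                ks_stat, ks_p = np.nan, np.nan
            rows.append({
                "category_1": a, "category_2": b,
                "chi2_statistic": chi.statistic, "chi2_p": chi.p_value,
                "ks_statistic": ks_stat, "ks_p": ks_p,
            })
    return pd.DataFrame(rows)
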