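"""Polarization, degeneracy, control intervals, CpG context, categories."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from cnedfe.elements import InputError
from cnedfe.variants import (
    CategoryAssigner, PolarizedVariant, build_noncoding_control,
    degeneracy_classify, flag_ancestral_cpg, longest_cds_transcript,
    polarize, read_vcf,
)


class TestPolarize:
    def test_ancestral_is_ref(self):
        v, reason = polarize("A", "G", "A", 5, 120)
        assert reason is None and v.derived_count == 5

    def test_ancestral_is_alt_flips(self):
        v, reason = polarize("A", "G", "G", 5, 120)
        assert reason is None and v.derived_count == 115

    @pytest.mark.parametrize("ancestral,alt_count,reason", [
        ("C", 5, "ancestral_mismatch"),
        ("A", 0, "zero_alt_count"),
        (".", 5, "missing_ancestral"),
        (None, 5, "missing_ancestral"),
        ("a", 5, "low_confidence_ancestral"),
        ("G", 120, "monomorphic"),  # all chromosomes derived? AN - 120 = 0
    ])
    def test_exclusions(self, ancestral, alt_count, reason):
        v, r = polarize("A", "G", ancestral, alt_count, 120)
        assert v is None and r == reason

    def test_lowercase_accepted_when_configured(self):
        v, r = polarize("A", "G", "a", 5, 120, accept_lowercase_ancestral=True)
        assert r is None and v.derived_count == 5

    @given(st.integers(1, 119), st.booleans())
    @settings(max_examples=40, deadline=None)
    def test_polarization_involution(self, alt_count, anc_is_ref):
        """Flipping the ancestral label maps DAC -> AN - DAC."""
        an = 120
        v1, _ = polarize("A", "G", "A" if anc_is_ref else "G", alt_count, an)
        v2, _ = polarize("A", "G", "G" if anc_is_ref else "A", alt_count, an)
        assert v1.derived_count + v2.derived_count == an


class TestDegeneracy:
    def test_met_codon_all_zero_fold(self):
        dm = degeneracy_classify("ATG", [0, 1, 2])
        assert [dm.position_fold[i] for i in range(3)] == [0, 0, 0]

    def test_ala_third_position_four_fold(self):
        dm = degeneracy_classify("GCT", [0, 1, 2])
        assert dm.position_fold[2] == 4

    def test_brute_force_oracle_random_cds(self):
        """Fold labels agree with mutating every position to all 3 bases."""
        rng = np.random.default_rng(0)
        stops = {"TAA", "TAG", "TGA"}
        codons = []
        while len(codons) < 60:
            c = "".join(rng.choice(list("ACGT"), 3))
            if c not in stops:
                codons.append(c)
        cds = "".join(codons)
        dm = degeneracy_classify(cds, range(len(cds)))
        for k in range(len(cds)):
            aa = str(Seq(cds[3 * (k // 3):3 * (k // 3) + 3]).translate())
            syn = 0
            for b in "ACGT":
                if b == cds[k]:
                    continue
                mutant = cds[:k] + b + cds[k + 1:]
                codon = mutant[3 * (k // 3):3 * (k // 3) + 3]
                if str(Seq(codon).translate()) == aa:
                    syn += 1
            expected = 0 if syn == 0 else (4 if syn == 3 else 2)
            assert dm.position_fold[k] == expected

    def test_fold_totals_partition_cds(self):
        dm = degeneracy_classify("ATGGCTAAACGT", range(12))
        assert sum(dm.fold_totals().values()) == 12

    def test_invalid_cds_rejected(self):
        with pytest.raises(InputError):
            degeneracy_classify("ATGA", [0, 1, 2, 3])
        with pytest.raises(InputError):
            degeneracy_classify("ATGTAAATG", range(9))  # internal stop

    def test_longest_cds_transcript_tie_break(self):
        assert longest_cds_transcript({"t2": "ATGGCT", "t1": "ATGGCT",
                                       "t3": "ATG"}) == "t1"


class TestNoncodingControl:
    def _anchors(self, *spans):
        return pd.DataFrame([{"chrom": "chr1", "start": s, "end": e}
                             for s, e in spans])

    def test_two_flanks_no_exclusions(self):
        out = build_noncoding_control(self._anchors((100000, 100200)))
        assert (out["end"] - out["start"]).sum() == 2000
        assert out.values.tolist() == [["chr1", 94000, 95000],
                                       ["chr1", 105200, 106200]]

    def test_exon_covering_one_flank(self):
        exons = self._anchors((94000, 95000))
        out = build_noncoding_control(self._anchors((100000, 100200)), exons)
        assert (out["end"] - out["start"]).sum() == 1000

    def test_negative_coordinates_clipped(self):
        out = build_noncoding_control(self._anchors((2000, 2200)))
        # left band [-4000, -3000) clipped away entirely
        assert (out["start"] >= 0).all()

    def test_per_base_oracle_random_layout(self):
        """Retained length equals brute-force per-base membership."""
        rng = np.random.default_rng(1)
        cnes = sorted(rng.choice(200000, 4, replace=False))
        anchors = self._anchors(*[(int(s), int(s) + 150) for s in cnes])
        exons = self._anchors(*[(int(s), int(s) + int(l)) for s, l in
                                zip(rng.choice(220000, 6), rng.integers(50, 3000, 6))])
        excluded = self._anchors(*[(int(s), int(s) + int(l)) for s, l in
                                   zip(rng.choice(220000, 5), rng.integers(20, 800, 5))])
        out = build_noncoding_control(anchors, exons, excluded)
        genome = np.zeros(300000, bool)
        for s, e in anchors[["start", "end"]].values:
            for lo, hi in ((s - 6000, s - 5000), (e + 5000, e + 6000)):
                genome[max(lo, 0):max(hi, 0)] = True
        for df in (exons, anchors, excluded):
            for s, e in df[["start", "end"]].values:
                genome[max(s, 0):e] = False
        assert (out["end"] - out["start"]).sum() == genome.sum()
        for s, e in out[["start", "end"]].values:
            assert genome[s:e].all()

    def test_bad_flanks_rejected(self):
        with pytest.raises(InputError):
            build_noncoding_control(self._anchors((0, 100)), flank_near=6000,
                                    flank_far=5000)


class TestCpGFlag:
    def _variant(self, pos):
        return PolarizedVariant("chr1", pos, "C", "T", "C", 3, 120)

    def test_c_of_cpg_true(self):
        assert flag_ancestral_cpg(self._variant(1), {"chr1": "ACGT"}) is True

    def test_g_of_cpg_true(self):
        assert flag_ancestral_cpg(self._variant(2), {"chr1": "ACGT"}) is True

    def test_non_cpg_false(self):
        assert flag_ancestral_cpg(self._variant(1), {"chr1": "ACAT"}) is False

    def test_missing_context_returns_none(self):
        v = self._variant(1)
        assert flag_ancestral_cpg(v, {}) is None
        assert v.at_ancestral_cpg is None

    def test_planted_cpgs_recovered(self, small_bundle):
        genome = small_bundle.ancestral_genome
        context = {"chr1": genome}
        for v in small_bundle.variants[:200]:
            expected = (
                (genome[v.position] == "C" and genome[v.position + 1] == "G")
                or (genome[v.position] == "G" and genome[v.position - 1] == "C")
            )
            assert flag_ancestral_cpg(v, context) == expected


class TestCategoryAssignment:
    def test_precedence_and_partition(self, small_bundle):
        from cnedfe.elements import classify_element

        masks = [classify_element(el) for el in small_bundle.elements]
        cfg = small_bundle.config
        dmap = degeneracy_classify(
            small_bundle.cds_sequence,
            np.arange(small_bundle.cds_start,
                      small_bundle.cds_start + cfg.cds_length),
            "tx", cfg.chromosome)
        assigner = CategoryAssigner(masks, [dmap],
                                    small_bundle.noncoding_intervals)
        truth = small_bundle.truth_categories
        for v, expected in zip(small_bundle.variants, truth["category"]):
            assert assigner.assign(v).category == expected

    def test_unmatched_position_unassigned(self):
        assigner = CategoryAssigner([], [], None)
        v = PolarizedVariant("chr9", 12345, "A", "G", "A", 2, 120)
        assert assigner.assign(v).category == "UNASSIGNED"


def test_read_vcf_round_trip(small_bundle, tmp_path):
    """Writing the bundle VCF and re-reading reproduces DAC/AN exactly."""
    from cnedfe.simulate import write_bundle

    paths = write_bundle(small_bundle, tmp_path)
    variants, excluded = read_vcf(paths["vcf"])
    assert sum(excluded.values()) == 0
    assert len(variants) == len(small_bundle.variants)
    for got, want in zip(variants, small_bundle.variants):
        assert (got.chromosome, got.position) == (want.chromosome, want.position)
        assert got.derived_count == want.derived_count
        assert got.total_chromosomes == want.total_chromosomes
        assert got.ancestral == want.ancestral
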