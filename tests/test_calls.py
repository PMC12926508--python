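"""Ancestral consensus, de novo call acceptance rules, MNM grouping, and
impact annotation."""

import numpy as np
import pytest

from malines.calls import (MutationCall, annotate_impact, call_mutations,
                           count_mnm, group_mnms, infer_ancestral)
from malines.variants import HET, HOM_ALT, HOM_REF, MISSING, SiteTable


def _site(gt, ad_alt=None, pos=100, ref="A", alts=("G",), chrom="c1", dp=80):
    n = len(gt)
    ad_alt = ad_alt if ad_alt is not None else \
        [dp // 2 if g == HET else (dp if g == HOM_ALT else 0) for g in gt]
    ad_ref = [dp - a for a in ad_alt]
    return (chrom, pos, ref, alts, gt, ad_ref, ad_alt, [dp] * n)


def _table(sites):
    n_lines = len(sites[0][4])
    n = len(sites)
    return SiteTable(
        chrom=np.array([s[0] for s in sites], dtype=object),
        pos=np.array([s[1] for s in sites], dtype=np.int64),
        ref=np.array([s[2] for s in sites], dtype=object),
        alts=[tuple(s[3]) for s in sites],
        gt=np.array([s[4] for s in sites], dtype=np.int8),
        ad_ref=np.array([s[5] for s in sites], dtype=np.int32),
        ad_alt=np.array([s[6] for s in sites], dtype=np.int32),
        dp=np.array([s[7] for s in sites], dtype=np.int32),
        fs=np.full(n, 1.0), mq_rank_sum=np.zeros(n),
        read_pos_rank_sum=np.zeros(n),
        samples=[f"L{i+1}" for i in range(n_lines)])


class TestInferAncestral:
    def test_seven_of_eight_consensus_gives_hom_ref(self):
        table = _table([_site([HOM_REF] * 7 + [HET])])
        anc = infer_ancestral(table)
        assert anc.genotype[0] == HOM_REF
        assert anc.support[0] == 7

    def test_six_of_eight_is_uncallable_at_consensus_seven(self):
        table = _table([_site([HOM_REF] * 6 + [HET, HET])])
        anc = infer_ancestral(table, min_consensus=7)
        assert anc.genotype[0] == MISSING

    def test_all_het_gives_ancestral_het(self):
        table = _table([_site([HET] * 8)])
        assert infer_ancestral(table).genotype[0] == HET

    def test_missing_genotype_excludes_site(self):
        table = _table([_site([HOM_REF] * 7 + [MISSING])])
        assert infer_ancestral(table).genotype[0] == MISSING

    def test_fewer_than_three_lines_is_an_error(self):
        table = _table([_site([HOM_REF, HET])])
        with pytest.raises(ValueError):
            infer_ancestral(table)


class TestCallMutations:
    def test_unique_hom_to_het_is_called(self):
        table = _table([_site([HOM_REF] * 7 + [HET])])
        calls = call_mutations(table, infer_ancestral(table))
        assert len(calls) == 1
        c = calls[0]
        assert (c.line, c.event_class, c.ref_allele, c.alt_allele) == \
            ("L8", "SNM", "A", "G")

    def test_variant_reads_in_another_line_reject_the_call(self):
        ad_alt = [0, 0, 2, 0, 0, 0, 0, 40]  # L3 has 2 reads of the G allele
        table = _table([_site([HOM_REF] * 7 + [HET], ad_alt=ad_alt)])
        assert call_mutations(table, infer_ancestral(table)) == []

    def test_shared_mutation_in_two_lines_rejected(self):
        table = _table([_site([HOM_REF] * 6 + [HET, HET])])
        assert call_mutations(table, infer_ancestral(table)) == []

    def test_het_to_hom_is_not_a_mutation(self):
        # feeds LOH instead: ancestral het, one line homozygous
        table = _table([_site([HET] * 7 + [HOM_REF], ad_alt=[40] * 7 + [0])])
        assert call_mutations(table, infer_ancestral(table)) == []

    def test_call_near_indel_rejected(self):
        sites = [_site([HOM_REF] * 7 + [HET], pos=100),
                 _site([HET] * 8, pos=110, ref="AT", alts=("A",))]
        table = _table(sites)
        calls = call_mutations(table, infer_ancestral(table), indel_window=20)
        assert calls == []

    def test_indel_called_with_class_and_length(self):
        table = _table([_site([HOM_REF] * 7 + [HET], ref="A", alts=("ATTT",))])
        calls = call_mutations(table, infer_ancestral(table))
        assert len(calls) == 1
        assert calls[0].event_class == "insertion"
        assert calls[0].indel_length == 3

    def test_indels_longer_than_five_are_dropped(self):
        table = _table([_site([HOM_REF] * 7 + [HET], ref="A",
                              alts=("ATTTTTTT",))])
        assert call_mutations(table, infer_ancestral(table)) == []


class TestMnmGrouping:
    def _calls(self, specs):
        return [MutationCall(line=l, chrom=c, position=p, ref_allele="A",
                             alt_allele="G", event_class="SNM")
                for l, c, p in specs]

    def test_two_snms_30bp_apart_same_line_group(self):
        calls = group_mnms(self._calls([("L1", "c1", 100), ("L1", "c1", 130)]))
        groups, members = count_mnm(calls)
        assert (groups, members) == (1, 2)

    def test_two_snms_60bp_apart_ungrouped(self):
        calls = group_mnms(self._calls([("L1", "c1", 100), ("L1", "c1", 160)]))
        assert count_mnm(calls) == (0, 0)

    def test_different_lines_never_group(self):
        calls = group_mnms(self._calls([("L1", "c1", 100), ("L2", "c1", 130)]))
        assert count_mnm(calls) == (0, 0)

    def test_chained_gaps_form_one_group(self):
        calls = group_mnms(self._calls(
            [("L1", "c1", 100), ("L1", "c1", 140), ("L1", "c1", 185)]))
        assert count_mnm(calls) == (1, 3)


class TestAnnotateImpact:
    # toy CDS (31..60, + strand): ATG CAA CTT GGG TGC TCA GAT CCC TGG TAA
    def _call(self, pos, alt, ref="N"):
        return MutationCall(line="L1", chrom="t1", position=pos,
                            ref_allele=ref, alt_allele=alt, event_class="SNM")

    def test_stop_gained_is_high(self, toy_bundle):
        # CAA (Gln, codon 2) -> TAA (stop): position 34 C>T
        assert annotate_impact(self._call(34, "T", "C"), toy_bundle) == "HIGH"

    def test_silent_third_position_is_low(self, toy_bundle):
        # CTT (Leu, codon 3) -> CTC (Leu): position 39 T>C
        assert annotate_impact(self._call(39, "C", "T"), toy_bundle) == "LOW"

    def test_missense_is_moderate(self, toy_bundle):
        # GGG (Gly, codon 4) -> GAG (Glu): position 41 G>A
        assert annotate_impact(self._call(41, "A", "G"), toy_bundle) == "MODERATE"

    def test_start_lost_is_high(self, toy_bundle):
        # ATG -> CTG at position 31
        assert annotate_impact(self._call(31, "C", "A"), toy_bundle) == "HIGH"

    def test_stop_lost_is_high(self, toy_bundle):
        # TAA (codon 10) -> CAA at position 58
        assert annotate_impact(self._call(58, "C", "T"), toy_bundle) == "HIGH"

    def test_intergenic_is_modifier(self, toy_bundle):
        assert annotate_impact(self._call(5, "T", "A"), toy_bundle) == "MODIFIER"

    def test_out_of_bounds_is_an_error(self, toy_bundle):
        with pytest.raises(ValueError):
            annotate_impact(self._call(9999, "T"), toy_bundle)

    def test_minus_strand_codon_reconstruction(self):
        from malines.reference import (COMPLEMENT_CODE, GeneModel,
                                       ReferenceBundle, encode_seq)
        # reverse-complement the toy gene onto the minus strand
        cds_seq = "ATGCAACTTGGGTGCTCAGATCCCTGGTAA"
        fwd = "A" * 30 + cds_seq + "A" * 60
        rc = COMPLEMENT_CODE[encode_seq(fwd)][::-1].copy()
        L = len(fwd)
        s, e = L - 60 + 1, L - 31 + 1
        bundle = ReferenceBundle(sequences={"t1": rc},
                                 genes=[GeneModel("g1", "t1", "-",
                                                  cds=[(s, e)])])
        # the plus-strand stop-gained at 34 maps to position L-34+1, alt A
        call = MutationCall(line="L1", chrom="t1", position=L - 34 + 1,
                            ref_allele="G", alt_allele="A", event_class="SNM")
        assert annotate_impact(call, bundle) == "HIGH"


class TestRecoveryOnSimulation:
    def test_snm_and_indel_recovery(self, experiment, analyzed):
        calls = analyzed.calls
        called_snm = {(c.line, c.chrom, c.position)
                      for c in calls if c.event_class == "SNM"}
        truth_snm = experiment.truth.snm_set()
        tp = len(called_snm & truth_snm)
        assert len(truth_snm) >= 100
        assert tp / len(called_snm) >= 0.95
        assert tp / len(truth_snm) >= 0.95
        called_ind = {(c.line, c.chrom, c.position) for c in calls
                      if c.event_class in ("insertion", "deletion")}
        truth_ind = experiment.truth.indel_set()
        # allow 1 bp of representation slack at boundaries
        def near(s, pool):
            return any(s[0] == t[0] and s[1] == t[1] and abs(s[2] - t[2]) <= 1
                       for t in pool)
        tp_i = sum(1 for s in called_ind if near(s, truth_ind))
        rec_i = sum(1 for t in truth_ind if near(t, called_ind))
        assert tp_i / max(len(called_ind), 1) >= 0.9
        assert rec_i / max(len(truth_ind), 1) >= 0.9

    def test_no_call_sits_near_surviving_indel(self, analyzed):
        indels = [(c.chrom, c.position) for c in analyzed.calls
                  if c.event_class in ("insertion", "deletion")]
        for c in analyzed.calls:
            for ic, ip in indels:
                if c.chrom == ic and c.position != ip:
                    assert abs(c.position - ip) > 20

    def test_per_line_counts_sum_to_total(self, analyzed):
        per_line = analyzed.snm_rates.per_line
        n_snm = sum(1 for c in analyzed.calls if c.event_class == "SNM")
        assert int(per_line["x"].sum()) == n_snm
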