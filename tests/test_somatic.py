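import numpy as np
import pytest

from varcall.genotypes import GENOTYPES, GENOTYPE_INDEX
from varcall.germline import log_genotype_priors, site_log_likelihoods
from varcall.params import ModelParams
from varcall.pileup_io import AlleleObservation, IndelObservation, SiteColumn
from varcall.somatic import (
    SOMATIC_TYPES,
    _postprocess_genotype,
    call_somatic_pairs,
    call_somatic_snv,
    call_to_record,
    classify_somatic,
    estimate_or_accept_purity,
    joint_argmax,
    joint_posterior,
    joint_prior,
    pair_columns,
    relaxed_threshold,
    somatic_indel,
    subtraction_call,
)

from .oracles import naive_joint_posterior


def column(bases, ref="A", pos=1, bq=30, mq=60, indels=()):
    return SiteColumn(
        "c",
        pos,
        ref,
        [AlleleObservation(b, bq, mq, "+") for b in bases],
        list(indels),
    )


def ins(seq, n):
    return tuple(IndelObservation("insertion", seq, "+") for _ in range(n))


class TestJointPrior:
    def test_rows_sum_to_one(self):
        for s in (1e-6, 1e-4, 1e-2):
            p = joint_prior("A", ModelParams(somatic_rate=s))
            rows = np.exp(p.log_dependency).sum(axis=1)
            assert np.allclose(rows, 1.0)

    def test_small_rate_approaches_identity(self):
        p = joint_prior("A", ModelParams(somatic_rate=1e-12))
        dep = np.exp(p.log_dependency)
        assert np.allclose(dep, np.eye(len(GENOTYPES)), atol=1e-10)

    def test_transition_change_more_plausible(self):
        p = joint_prior("A", ModelParams(somatic_rate=1e-4))
        dep = np.exp(p.log_dependency)
        i = GENOTYPE_INDEX["AA"]
        assert dep[i, GENOTYPE_INDEX["AG"]] > dep[i, GENOTYPE_INDEX["AC"]]

    def test_joint_sums_to_one(self):
        p = joint_prior("C", ModelParams())
        assert np.exp(p.log_joint).sum() == pytest.approx(1.0, abs=1e-9)


class TestJointPosterior:
    def test_clean_somatic_site_argmax(self):
        post = joint_posterior(column("A" * 30), column("A" * 15 + "G" * 15))
        assert post.sum() == pytest.approx(1.0, abs=1e-9)
        assert joint_argmax(post) == ("AA", "AG")

    def test_no_variant_site(self):
        post = joint_posterior(column("A" * 30), column("A" * 30))
        assert joint_argmax(post) == ("AA", "AA")
        assert classify_somatic("AA", "AA", "A") == "Wild"

    def test_empty_column_returns_none(self):
        assert joint_posterior(column(""), column("A" * 5)) is None

    def test_matches_naive_hundred_cell_oracle(self, rng):
        params = ModelParams()
        for ref in "ACGT":
            for _ in range(15):
                nn = int(rng.integers(1, 5))
                nt = int(rng.integers(1, 5))
                nb = [str(b) for b in rng.choice(list("ACGT"), size=nn)]
                tb = [str(b) for b in rng.choice(list("ACGT"), size=nt)]
                nq = [int(q) for q in rng.choice([10, 20, 30], size=nn)]
                tq = [int(q) for q in rng.choice([10, 20, 30], size=nt)]
                ncol = SiteColumn(
                    "c", 1, ref,
                    [AlleleObservation(b, q, 60, "+") for b, q in zip(nb, nq)],
                )
                tcol = SiteColumn(
                    "c", 1, ref,
                    [AlleleObservation(b, q, 60, "+") for b, q in zip(tb, tq)],
                )
                post = joint_posterior(ncol, tcol, ref, params)
                oracle = naive_joint_posterior(
                    list(zip(nb, nq, [60] * nn)),
                    list(zip(tb, tq, [60] * nt)),
                    ref,
                )
                for gn in GENOTYPES:
                    for gt in GENOTYPES:
                        got = post[GENOTYPE_INDEX[gn], GENOTYPE_INDEX[gt]]
                        assert got == pytest.approx(
                            oracle[(gn, gt)], abs=1e-9
                        )

    def test_independence_oracle_outer_product(self):
        """Replacing the dependency rows by the marginal prior makes the
        joint posterior the outer product of per-sample posteriors."""
        params = ModelParams()
        ncol = column("A" * 4 + "C" * 2)
        tcol = column("A" * 3 + "G" * 3)
        logp = log_genotype_priors("A", params)
        lln = site_log_likelihoods(ncol, params)
        llt = site_log_likelihoods(tcol, params)
        joint = (lln + logp)[:, None] + (llt + logp)[None, :]
        joint = np.exp(joint - joint.max())
        joint /= joint.sum()
        pn = np.exp(lln + logp - (lln + logp).max())
        pn /= pn.sum()
        pt = np.exp(llt + logp - (llt + logp).max())
        pt /= pt.sum()
        assert np.allclose(joint, np.outer(pn, pt), atol=1e-12)


class TestClassifySomatic:
    @pytest.mark.parametrize(
        "gn,gt,expected",
        [
            ("AA", "AA", "Wild"),
            ("AA", "AG", "Somatic"),
            ("AA", "GG", "Somatic"),
            ("AC", "AA", "LOH"),
            ("AC", "AC", "Germline"),
            ("AC", "CC", "LOH"),
            ("GG", "AA", "Unknown"),
            ("GG", "AG", "Unknown"),
            ("GG", "GG", "Germline"),
        ],
    )
    def test_table_examples(self, gn, gt, expected):
        assert classify_somatic(gn, gt, "A") == expected

    def test_het_var_normal_routing(self):
        # shares an allele with the tumor genotype -> AB row
        assert classify_somatic("CG", "CC", "A") == "LOH"
        # no shared allele -> BB row
        assert classify_somatic("CG", "TT", "A") == "Germline"

    def test_total_over_all_pairs(self):
        for gn in GENOTYPES:
            for gt in GENOTYPES:
                for ref in "ACGT":
                    assert classify_somatic(gn, gt, ref) in SOMATIC_TYPES


class TestSubtraction:
    def test_clean_somatic_site(self):
        call = subtraction_call(column("A" * 30), column("A" * 15 + "G" * 15))
        assert call is not None
        assert call.somatic_type == "Somatic"
        assert call.provenance == "subtraction"
        assert (call.g_normal, call.g_tumor) == ("AA", "AG")

    def test_non_hom_ref_normal_defers(self):
        assert (
            subtraction_call(
                column("A" * 15 + "C" * 15), column("A" * 15 + "C" * 15)
            )
            is None
        )

    def test_weak_tumor_variant_defers(self):
        # two supporting reads out of 30 keep the VCOS below high confidence
        assert (
            subtraction_call(column("A" * 30), column("A" * 28 + "G" * 2))
            is None
        )


class TestPostprocess:
    def test_relaxed_threshold_values(self):
        p = ModelParams(purity=0.9)
        # normal sample ignores purity: ceil(0.25 * 30) = 8
        assert relaxed_threshold(30, p, is_tumor=False) == 8
        # tumor sample: ceil(0.25 * 0.9 * 30) = 7
        assert relaxed_threshold(30, p, is_tumor=True) == 7
        # absolute floor
        assert relaxed_threshold(2, p, is_tumor=True) == 2

    def test_disagreement_with_low_confidence_demotes(self):
        col = column("A" * 29 + "C")
        g, conf = _postprocess_genotype(
            "AC", "AA", col, "A", ModelParams(), is_tumor=False
        )
        assert g == "AA" and conf is None

    def test_agreement_with_enough_support_retained(self):
        col = column("A" * 15 + "G" * 15)
        g, conf = _postprocess_genotype(
            "AG", "AG", col, "A", ModelParams(purity=0.9), is_tumor=True
        )
        assert g == "AG" and conf is not None and conf.label == "high"

    def test_agreement_below_threshold_demoted(self):
        col = column("A" * 26 + "G" * 4)
        g, _ = _postprocess_genotype(
            "AG", "AG", col, "A", ModelParams(purity=0.9), is_tumor=True
        )
        assert g == "AA"


class TestCallSomaticSnv:
    def test_clean_somatic_site(self):
        call = call_somatic_snv(column("A" * 30), column("A" * 15 + "G" * 15))
        assert call is not None and call.somatic_type == "Somatic"

    def test_wild_site_is_none(self):
        assert call_somatic_snv(column("A" * 30), column("A" * 30)) is None

    def test_germline_het_in_both(self):
        het = "A" * 15 + "C" * 15
        call = call_somatic_snv(column(het), column(het))
        assert call is not None and call.somatic_type == "Germline"

    def test_loh_site(self):
        call = call_somatic_snv(column("A" * 15 + "C" * 15), column("A" * 30))
        assert call is not None and call.somatic_type == "LOH"

    def test_one_sided_site_is_unknown(self):
        call = call_somatic_snv(column(""), column("C" * 20))
        assert call is not None
        assert call.somatic_type == "Unknown"
        assert call.g_tumor == "CC" and call.g_normal == "AA"

    def test_self_vs_self_clean_emits_no_somatic(self):
        """Identical clean columns as both samples never yield Somatic."""
        from varcall.simulate import iter_germline

        for col, _ in iter_germline(2000, 30, 0.0, seed=11):
            call = call_somatic_snv(col, col)
            if call is not None:
                assert call.somatic_type != "Somatic"

    def test_record_rendering(self):
        call = call_somatic_snv(column("A" * 30), column("A" * 15 + "G" * 15))
        rec = call_to_record(call)
        assert rec.ref == "A" and rec.alts == ("G",)
        assert rec.genotypes == ("0/0", "0/1")
        assert rec.somatic_type == "Somatic"
        assert rec.depths == (30, 30)


class TestSomaticIndel:
    def test_tumor_only_candidate_is_somatic(self):
        normal = column("A" * 30)
        tumor = column("A" * 30, indels=ins("TG", 12))
        rec = somatic_indel(normal, tumor)
        assert rec is not None and rec.somatic_type == "Somatic"
        assert rec.ref == "A" and rec.alts == ("ATG",)
        assert rec.genotypes == ("0/0", "0/1")

    def test_both_candidates_is_none(self):
        col = column("A" * 30, indels=ins("TG", 12))
        assert somatic_indel(col, col) is None

    def test_neither_candidate_is_none(self):
        assert somatic_indel(column("A" * 30), column("A" * 30)) is None

    def test_normal_only_candidate_is_loh(self):
        normal = column("A" * 30, indels=ins("TG", 12))
        rec = somatic_indel(normal, column("A" * 30))
        assert rec is not None and rec.somatic_type == "LOH"
        assert rec.genotypes == ("0/1", "0/0")


class TestPairing:
    def test_merges_by_position_with_gaps(self):
        normal = [column("A", pos=1), column("A", pos=3)]
        tumor = [column("A", pos=1), column("A", pos=2)]
        pairs = list(pair_columns(normal, tumor))
        assert [(n.pos if n else None, t.pos if t else None) for n, t in pairs] == [
            (1, 1),
            (None, 2),
            (3, None),
        ]

    def test_pipeline_over_pairs(self):
        normal = [column("A" * 30, pos=1), column("A" * 30, pos=2)]
        tumor = [
            column("A" * 30, pos=1),
            column("A" * 15 + "G" * 15, pos=2),
        ]
        recs = list(
            call_somatic_pairs(pair_columns(normal, tumor), ModelParams(purity=0.9))
        )
        assert len(recs) == 1 and recs[0].pos == 2
        assert recs[0].somatic_type == "Somatic"


class TestPurity:
    def test_passthrough(self):
        assert estimate_or_accept_purity(ModelParams(purity=0.9)) == 0.9

    def test_default_without_data(self):
        assert estimate_or_accept_purity(ModelParams()) == 1.0

    def test_estimate_from_simulation(self):
        from varcall.simulate import iter_tumor_normal

        pairs = (
            (n, t)
            for n, t, _ in iter_tumor_normal(
                10000,
                coverage=30,
                error_rate=0.01,
                purity=0.8,
                somatic_fraction=0.05,
                indel_fraction=0.0,
                seed=21,
            )
        )
        est = estimate_or_accept_purity(ModelParams(), pairs)
        assert est == pytest.approx(0.8, abs=0.1)

    def test_no_somatic_sites_defaults_to_one(self):
        pairs = [(column("A" * 10, pos=i + 1), column("A" * 10, pos=i + 1)) for i in range(5)]
        assert estimate_or_accept_purity(ModelParams(), pairs) == 1.0
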