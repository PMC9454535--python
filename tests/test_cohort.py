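import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from llskit.acmg import AcmgClass, EvidenceSet, Tier
from llskit.acmg import ClassifiedVariant
from llskit.cohort import (
    BrafStatus,
    ContingencyTable2x2,
    Methylation,
    MsiStatus,
    Patient,
    Sex,
    TriageDecision,
    chi2_2x2,
    class_shares,
    compare_2x2,
    fisher_exact_2x2,
    kruskal_wallis,
    one_way_anova,
    read_phenotypes,
    select_2x2_test,
    summarize_cohort,
    triage,
    write_phenotypes,
    write_report,
)
from llskit.io import LlskitError, ValidationError
from llskit.prioritization import Route
from test_prioritization import mkvar


def make_patient(**kwargs) -> Patient:
    base = dict(
        id="P1", sex=Sex.FEMALE, tumors=(("colorectal", 45.0),),
        ihc_loss=frozenset({"MSH6"}), msi=MsiStatus.MSI,
    )
    base.update(kwargs)
    return Patient(**base)


def classified(pid: str, tier: Tier) -> ClassifiedVariant:
    return ClassifiedVariant(
        variant=mkvar(patient_id=pid), route=Route.LOF,
        evidence=EvidenceSet(), acmg=AcmgClass(tier),
    )


class TestTriage:
    def test_mlh1_loss_braf_wildtype_tested_regardless_of_methylation(self):
        p = make_patient(ihc_loss=frozenset({"MLH1", "PMS2"}),
                         braf_v600e=BrafStatus.WILDTYPE,
                         mlh1_methylated=Methylation.YES)
        assert triage(p) is TriageDecision.GERMLINE_TEST

    def test_isolated_msh6_loss_has_no_braf_gate(self):
        p = make_patient(ihc_loss=frozenset({"MSH6"}),
                         braf_v600e=BrafStatus.UNTESTED)
        assert triage(p) is TriageDecision.GERMLINE_TEST

    def test_mlh1_loss_braf_mutant_not_tested(self):
        p = make_patient(ihc_loss=frozenset({"MLH1"}),
                         braf_v600e=BrafStatus.MUTANT)
        assert triage(p) is TriageDecision.NO_TEST

    def test_mlh1_loss_braf_untested_is_explicit(self):
        p = make_patient(ihc_loss=frozenset({"MLH1", "PMS2"}),
                         braf_v600e=BrafStatus.UNTESTED)
        assert triage(p) is TriageDecision.NEEDS_BRAF

    def test_msi_without_ihc_loss_is_tested(self):
        p = make_patient(ihc_loss=frozenset(), msi=MsiStatus.MSI)
        assert triage(p) is TriageDecision.GERMLINE_TEST

    def test_no_loss_mss_excluded(self):
        p = make_patient(ihc_loss=frozenset(), msi=MsiStatus.MSS)
        assert triage(p) is TriageDecision.EXCLUDED

    def test_total_over_all_combinations(self):
        """triage returns a decision for every IHC x BRAF x methylation x MSI
        combination (exhaustive enumeration)."""
        proteins = ["MLH1", "PMS2", "MSH2", "MSH6"]
        for r in range(len(proteins) + 1):
            for loss in itertools.combinations(proteins, r):
                for braf in BrafStatus:
                    for meth in Methylation:
                        for msi in (MsiStatus.MSI, MsiStatus.MSS):
                            p = make_patient(
                                ihc_loss=frozenset(loss), braf_v600e=braf,
                                mlh1_methylated=meth, msi=msi,
                            )
                            assert triage(p) in TriageDecision


class TestSummaries:
    def test_published_class_shares(self):
        """107/204/8 of 319 -> 33.5% / 63.9% / 2.5% with half-up rounding."""
        shares = class_shares({"benign_lb": 107, "vus": 204, "path_lp": 8})
        assert shares == {"benign_lb": 33.5, "vus": 63.9, "path_lp": 2.5}

    def test_shares_sum_to_100_within_rounding(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            counts = {str(i): int(c) for i, c in enumerate(rng.integers(0, 50, 4))}
            if sum(counts.values()) == 0:
                continue
            assert sum(class_shares(counts).values()) == pytest.approx(100, abs=0.2)

    def test_carrier_rate_seven_of_twenty(self):
        patients = [make_patient(id=f"P{i}") for i in range(20)]
        cls = [classified(f"P{i}", Tier.PATHOGENIC) for i in range(4)]
        cls += [classified(f"P{i}", Tier.LIKELY_PATHOGENIC) for i in range(4, 7)]
        cls += [classified("P3", Tier.VUS)]  # VUS does not make a carrier
        result = summarize_cohort(patients, cls)
        assert result.n_carriers == 7
        assert result.carrier_rate_pct == 35.0

    def test_empty_cohort_no_division_by_zero(self):
        result = summarize_cohort([], [])
        assert result.carrier_rate_pct == 0.0
        assert math.isnan(result.age_mean)

    def test_orphan_variant_names_patient(self):
        with pytest.raises(LlskitError, match="GHOST"):
            summarize_cohort([make_patient()], [classified("GHOST", Tier.VUS)])

    def test_site_distribution_and_age_stats(self):
        patients = [
            make_patient(id="A", tumors=(("colorectal", 40.0),)),
            make_patient(id="B", tumors=(("ovary", 50.0), ("breast", 60.0))),
        ]
        result = summarize_cohort(patients, [])
        assert result.first_tumor_sites == {"colorectal": 1, "ovary": 1}
        assert result.age_mean == 45.0


class TestFisherExact:
    def test_methylation_by_carrier_table(self):
        """3/6 vs 1/4 potentially pathogenic -> two-sided p = 0.571."""
        assert fisher_exact_2x2(ContingencyTable2x2(3, 3, 1, 3)) == pytest.approx(
            0.571, abs=5e-4)

    def test_degenerate_column_p_one(self):
        with pytest.warns(UserWarning):
            assert fisher_exact_2x2(ContingencyTable2x2(0, 5, 0, 7)) == 1.0

    @staticmethod
    def enumeration_oracle(a, b, c, d):
        """Sum hypergeometric P over all same-margin tables with
        P <= P_obs (relative tie tolerance 1e-7)."""
        r1, c1, n = a + b, a + c, a + b + c + d
        denom = math.comb(n, c1)

        def prob(x):
            if x < 0 or x > r1 or c1 - x < 0 or c1 - x > n - r1:
                return 0.0
            return math.comb(r1, x) * math.comb(n - r1, c1 - x) / denom

        p_obs = prob(a)
        return sum(
            p for x in range(0, c1 + 1)
            if (p := prob(x)) <= p_obs * (1 + 1e-7)
        )

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(123)
        checked = 0
        while checked < 500:
            cells = rng.multinomial(int(rng.integers(1, 41)), [0.25] * 4)
            t = ContingencyTable2x2(*map(int, cells))
            arr = t.to_array()
            if 0 in arr.sum(axis=0) or 0 in arr.sum(axis=1):
                continue
            expected = self.enumeration_oracle(t.a, t.b, t.c, t.d)
            assert fisher_exact_2x2(t) == pytest.approx(expected, abs=1e-12)
            checked += 1

    def test_invariance_under_transposition_and_swaps(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a, b, c, d = map(int, rng.integers(1, 15, 4))
            p = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
            assert fisher_exact_2x2(ContingencyTable2x2(a, c, b, d)) == pytest.approx(p, rel=1e-9)
            assert fisher_exact_2x2(ContingencyTable2x2(c, d, a, b)) == pytest.approx(p, rel=1e-9)
            assert fisher_exact_2x2(ContingencyTable2x2(b, a, d, c)) == pytest.approx(p, rel=1e-9)


class TestChi2:
    def test_null_table(self):
        statistic, p = chi2_2x2(ContingencyTable2x2(10, 10, 10, 10))
        assert statistic == 0.0 and p == 1.0

    def test_matches_hand_computed_statistic(self):
        t = ContingencyTable2x2(20, 5, 5, 20)
        observed = t.to_array()
        expected = t.expected()
        hand = float(((observed - expected) ** 2 / expected).sum())
        statistic, _ = chi2_2x2(t)
        assert statistic == pytest.approx(hand, rel=1e-12)

    def test_zero_expected_count_is_error(self):
        with pytest.raises(ValidationError, match="[Ff]isher"):
            chi2_2x2(ContingencyTable2x2(0, 0, 5, 7))

    def test_pipeline_selects_fisher_on_small_expected_counts(self):
        t = ContingencyTable2x2(3, 3, 1, 3)
        assert select_2x2_test(t) == "fisher"
        assert compare_2x2(t)["test"] == "fisher"
        assert select_2x2_test(ContingencyTable2x2(20, 20, 20, 20)) == "chi2"

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestAnova:
    def test_identical_groups(self):
        f, p = one_way_anova([1, 2, 3], [1, 2, 3])
        assert f == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_two_group_f(self):
        """Groups {1,2} and {5,6}: SSB=16, SSW=1, F = 16/(1/2) = 32."""
        f, p = one_way_anova([1, 2], [5, 6])
        assert f == pytest.approx(32.0, rel=1e-12)
        assert p == pytest.approx(1 - sps.f.cdf(32.0, 1, 2), rel=1e-9)

    def test_constant_data_degenerate(self):
        f, p = one_way_anova([2, 2], [2, 2])
        assert f == 0.0 and p == 1.0

    def test_two_group_p_equals_pooled_t_test(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            g1, g2 = rng.normal(0, 1, 12), rng.normal(0.4, 1, 9)
            _, p_anova = one_way_anova(g1, g2)
            p_t = sps.ttest_ind(g1, g2, equal_var=True).pvalue
            assert p_anova == pytest.approx(p_t, abs=1e-10)

    def test_rejects_degenerate_group_layout(self):
        with pytest.raises(ValidationError):
            one_way_anova([1, 2, 3])
        with pytest.raises(ValidationError):
            one_way_anova([1], [2])


class TestKruskalWallis:
    def test_identical_values(self):
        h, p = kruskal_wallis([3, 3], [3, 3])
        assert h == 0.0 and p == 1.0

    def test_hand_ranked_two_groups(self):
        """Groups {1,2,3} and {4,5,6}: ranks 1..6, H = 12/42*(36/3+225/3)-21."""
        h, _ = kruskal_wallis([1, 2, 3], [4, 5, 6])
        hand = 12 / (6 * 7) * (6 ** 2 / 3 + 15 ** 2 / 3) - 3 * 7
        assert h == pytest.approx(hand, rel=1e-12)

    @staticmethod
    def rank_formula_oracle(groups):
        flat = np.concatenate(groups)
        n = len(flat)
        ranks = sps.rankdata(flat)
        start, h = 0, 0.0
        for g in groups:
            r = ranks[start:start + len(g)]
            h += r.sum() ** 2 / len(g)
            start += len(g)
        h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
        _, counts = np.unique(flat, return_counts=True)
        tie = 1 - ((counts ** 3 - counts).sum() / (n ** 3 - n))
        return h / tie

    def test_tie_corrected_h_matches_direct_formula(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            groups = [rng.integers(0, 5, size=int(rng.integers(3, 10))).astype(float)
                      for _ in range(3)]
            if np.ptp(np.concatenate(groups)) == 0:
                continue
            h, _ = kruskal_wallis(*groups)
            assert h == pytest.approx(self.rank_formula_oracle(groups), rel=1e-10)


class TestPhenotypeAndReportIO:
    def test_phenotype_round_trip(self, tmp_path, default_cohort):
        path = tmp_path / "pheno.tsv"
        write_phenotypes(default_cohort.patients, path)
        back = read_phenotypes(path)
        assert sorted(back, key=lambda p: p.id) == sorted(
            default_cohort.patients, key=lambda p: p.id)

    def test_report_written_deterministically(self, tmp_path, fixture_t2):
        from llskit.acmg import classify_selected
        from llskit.prioritization import prioritize

        dispositions = prioritize(fixture_t2.variants, fixture_t2.panel)
        cls = classify_selected(
            dispositions, fixture_t2.lof_mechanism_genes, fixture_t2.manual_codes)
        result = summarize_cohort(fixture_t2.patients, cls)
        p1, p2 = tmp_path / "r1.tsv", tmp_path / "r2.tsv"
        write_report(result, p1)
        write_report(result, p2)
        assert p1.read_bytes() == p2.read_bytes()
        variant_block = p1.read_text().split("\n\n")[0].splitlines()
        assert len(variant_block) == 1 + 8  # header + eight retained variants

    def test_empty_report_is_header_only_table(self, tmp_path):
        result = summarize_cohort([], [])
        path = tmp_path / "empty.tsv"
        write_report(result, path)
        first_block = path.read_text().split("\n\n")[0].splitlines()
        assert len(first_block) == 1 and first_block[0].startswith("patient\t")
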