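import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cgprofiler.cohort import NO_CALL, CohortGenotypes
from cgprofiler.popstats import (
    FREQ_GROUPS,
    classify_rarity,
    detect_flip,
    group_allele_counts,
    group_specific_common,
    reconstruct_allele_counts,
    reference_minor_positions,
    select_test,
)
from cgprofiler.popstats import test_freq_difference as freq_difference_test
from cgprofiler.refdata import reconstructed_flip_counts, subpopulation_sizes

import oracles


def two_group_cohort(dosages_by_group, chrom="chr1", sex=None):
    """Subjects from several labelled groups, one site."""
    subs, dos, labels = [], [], []
    for g, values in dosages_by_group.items():
        for v in values:
            subs.append(f"{g}_{len(subs)}")
            dos.append([v])
            labels.append(g)
    dos = np.array(dos, dtype=np.int8)
    cohort = CohortGenotypes(
        subjects=subs,
        sites=pd.DataFrame(
            {"chrom": [chrom], "pos": [100], "id": ".", "ref": ["A"], "alt": ["G"]}
        ),
        dosage=dos,
        ref_depth=np.full_like(dos, 30, dtype=np.int32),
        alt_depth=np.full_like(dos, 30, dtype=np.int32),
        sex=np.array(sex) if sex is not None else None,
    )
    subpop = pd.DataFrame({"subject": subs, "subpopulation": labels})
    return cohort, subpop


class TestGroupAlleleCounts:
    def test_all_hom_ref_zero_frequency(self):
        cohort, subpop = two_group_cohort({"African": [0] * 43, "European": [0] * 10})
        t = group_allele_counts(cohort, subpop, groups=("African", "European"))
        assert (t.frequency == 0).all()
        assert t.loc[t.group == "African", "total_alleles"].iloc[0] == 86

    def test_het_and_hom_counting(self):
        vals = [1] * 10 + [2] * 1 + [0] * 39
        cohort, subpop = two_group_cohort({"European": vals})
        t = group_allele_counts(cohort, subpop, groups=("European",))
        row = t.iloc[0]
        assert row.alt_count == 12 and row.total_alleles == 100
        assert row.frequency == pytest.approx(0.12)

    def test_x_hemizygote_ploidy(self):
        # 20 females (2 het) + 20 males (3 carrying the alt) at an X site
        female_dos = [1, 1] + [0] * 18
        male_dos = [1, 1, 1] + [0] * 17
        cohort, subpop = two_group_cohort(
            {"EastAsian": female_dos + male_dos},
            chrom="chrX",
            sex=["F"] * 20 + ["M"] * 20,
        )
        t = group_allele_counts(cohort, subpop, groups=("EastAsian",))
        row = t.iloc[0]
        assert row.alt_count == 5 and row.total_alleles == 60

    def test_masked_genotypes_leave_denominator(self):
        vals = [1] * 5 + [NO_CALL] * 5 + [0] * 10
        cohort, subpop = two_group_cohort({"African": vals})
        t = group_allele_counts(cohort, subpop, groups=("African",))
        assert t.iloc[0].total_alleles == 30

    def test_other_group_excluded(self):
        cohort, subpop = two_group_cohort({"African": [1] * 25, "Other": [2] * 10})
        t = group_allele_counts(cohort, subpop)
        assert "Other" not in set(t.group)

    def test_allele_conservation(self, default_metrics):
        """Alt + ref counts equal total unmasked alleles at every site."""
        filtered = default_metrics["filtered"]
        subpop = pd.DataFrame(
            {
                "subject": filtered.subjects,
                "subpopulation": ["African"] * 341 + ["European"] * 340,
            }
        )
        t = group_allele_counts(filtered, subpop, groups=("African", "European"))
        tot = t.groupby(["chrom", "pos", "ref", "alt"], sort=False).total_alleles.sum()
        called = 2 * (filtered.dosage != NO_CALL).sum(axis=0)
        assert (tot.to_numpy() == called).all()


class TestRarity:
    @pytest.mark.parametrize(
        "maf,expect",
        [(3 / 1362, "rare"), (0.06, "common"), (0.03, "intermediate"), (0.0099, "rare")],
    )
    def test_cutoffs(self, maf, expect):
        assert classify_rarity(maf) == expect

    def test_not_minor_raises(self):
        with pytest.raises(ValueError):
            classify_rarity(0.7)


class TestSelectTest:
    def test_large_counts_chi_squared(self):
        table = np.array([[50, 50]] * 6)
        assert select_test(table) == "chi_squared"

    def test_singleton_forces_fisher(self):
        table = np.array([[1, 99], [0, 100], [0, 100]])
        assert select_test(table) == "fisher_simulated"

    def test_expected_exactly_one_is_fisher(self):
        # margins give an expected cell of exactly 1.0; ">1" is strict
        table = np.array([[1, 9], [1, 9]])
        assert select_test(table) == "fisher_simulated"

    def test_degenerate_column_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert select_test(np.array([[0, 10], [0, 10]])) == "fisher_simulated"


class TestFreqDifference:
    def test_identical_frequencies_not_significant(self):
        table = np.array([[100, 100]] * 6)
        res = freq_difference_test(table)
        assert res.test_used == "chi_squared"
        assert res.p_value > 0.99

    def test_simulated_p_matches_enumeration(self, rng):
        """Simulated Fisher p within 3 Monte-Carlo SE of full enumeration."""
        tables = [
            [[10, 0], [0, 10]],
            [[3, 7], [5, 5]],
            [[2, 4], [3, 3], [1, 5]],
            [[1, 5], [2, 2], [3, 1]],
            [[6, 0], [2, 4], [0, 6]],
            [[4, 2], [1, 5], [2, 4]],
        ]
        n_sim = 20000
        for t in tables:
            t = np.array(t)
            exact = oracles.exact_prob_based_p(t)
            res = freq_difference_test(
                t, n_sim=n_sim, seed=int(rng.integers(2**31)), force_test="fisher_simulated"
            )
            se = np.sqrt(exact * (1 - exact) / n_sim)
            assert abs(res.p_value - exact) <= 3 * se + 2 / (n_sim + 1), (t, exact, res)

    def test_chi_squared_matches_permutation_oracle(self, rng):
        """Pearson chi-squared p agrees with an allele-label permutation null."""
        table = np.array([[30, 50], [45, 35], [25, 55]])
        res = freq_difference_test(table, force_test="chi_squared")
        obs_stat = stats.chi2_contingency(table, correction=False)[0]
        labels = np.repeat([0, 1, 2], table.sum(axis=1))
        alleles = np.concatenate([np.r_[np.ones(a), np.zeros(b)] for a, b in table])
        n_perm, hits = 20000, 0
        for _ in range(n_perm):
            rng.shuffle(alleles)
            perm = np.array(
                [
                    [alleles[labels == g].sum(), (1 - alleles[labels == g]).sum()]
                    for g in range(3)
                ]
            )
            if stats.chi2_contingency(perm, correction=False)[0] >= obs_stat - 1e-9:
                hits += 1
        p_perm = hits / n_perm
        se = np.sqrt(max(p_perm * (1 - p_perm), 1e-6) / n_perm)
        assert abs(res.p_value - p_perm) <= 3 * se + 1e-3

    def test_small_n_sim_warns(self):
        with pytest.warns(UserWarning, match="n_sim"):
            freq_difference_test(
                np.array([[1, 9], [1, 9]]), n_sim=500, seed=0, force_test="fisher_simulated"
            )


class TestDetectFlip:
    def test_reported_ptch1_row_is_flip(self):
        rec = next(r for r in reconstructed_flip_counts() if r["gene"] == "PTCH1")
        res = detect_flip(rec["alt"], rec["total"])
        assert res.is_flip
        assert res.max_group == "EastAsian"

    def test_all_below_half_is_not_flip(self):
        alt = np.array([10, 12, 9, 14, 11, 13])
        total = np.full(6, 100)
        assert not detect_flip(alt, total).is_flip

    def test_insufficient_evidence_fails(self):
        # 0.49 vs 0.51 with 10 alleles per group cannot reach significance
        res = detect_flip(np.array([5, 5]), np.array([10, 10]), groups=("a", "b"))
        assert not res.is_flip

    def test_zero_total_group_excluded(self):
        alt = np.array([0, 10, 90])
        total = np.array([0, 100, 100])
        res = detect_flip(alt, total, groups=("a", "b", "c"))
        assert res.min_group == "b" and res.max_group == "c"

    def test_type_one_rate_under_null(self, rng):
        """Under equal true frequencies of 0.5 the composite criterion fires at
        most alpha + 3 SE of the time."""
        sizes = subpopulation_sizes()
        totals = 2 * sizes[sizes.subpopulation != "Other"].n_individuals.to_numpy()
        n_rep, fires = 1000, 0
        for _ in range(n_rep):
            alt = rng.binomial(totals, 0.5)
            fires += detect_flip(alt, totals).is_flip
        rate = fires / n_rep
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_reported_sites_pass_frequency_and_mostly_significance(self):
        recs = reconstructed_flip_counts()
        assert len(recs) == 21
        candidates = sum(
            detect_flip(r["alt"], r["total"]).min_freq < 0.5 < detect_flip(r["alt"], r["total"]).max_freq
            for r in recs
        )
        full = sum(detect_flip(r["alt"], r["total"]).is_flip for r in recs)
        assert candidates == 21
        assert full >= 19  # rounding of printed frequencies can cost borderline rows


class TestGroupSpecificAndReferenceMinor:
    def _table(self, freq_rows):
        rows = []
        for i, freqs in enumerate(freq_rows):
            for g, f in zip(FREQ_GROUPS, freqs):
                total = 100
                rows.append(
                    {
                        "chrom": "chr1",
                        "pos": 100 + i,
                        "ref": "A",
                        "alt": "G",
                        "group": g,
                        "alt_count": int(round(f * total)),
                        "total_alleles": total,
                        "frequency": f,
                    }
                )
        return pd.DataFrame(rows)

    def test_african_specific_common(self):
        t = self._table([[0.07, 0, 0, 0, 0, 0]])
        out = group_specific_common(t)
        assert len(out) == 1 and out.iloc[0].group == "African"
        assert out.iloc[0].low_admixture_group

    def test_two_group_variant_excluded(self):
        t = self._table([[0.07, 0.01, 0, 0, 0, 0]])
        assert group_specific_common(t).empty

    def test_admixed_specific_flagged(self):
        t = self._table([[0, 0.07, 0, 0, 0, 0]])  # African-European only
        out = group_specific_common(t)
        assert len(out) == 1 and not out.iloc[0].low_admixture_group

    def test_reference_minor_all_above_half(self):
        t = self._table([[0.9, 0.8, 0.95, 0.9, 0.85, 0.9], [0.9, 0.8, 0.45, 0.9, 0.85, 0.9]])
        out = reference_minor_positions(t)
        assert len(out) == 1 and out.iloc[0].pos == 100

    def test_planted_reference_minor_recovered(self, default_syn, default_metrics):
        filtered = default_metrics["filtered"]
        subpop = default_syn.truth.subjects.rename(columns={"group": "subpopulation"})
        t = group_allele_counts(filtered, subpop[["subject", "subpopulation"]])
        rm = reference_minor_positions(t)
        truth = default_syn.truth.sites
        planted = truth[truth.reference_minor][["chrom", "pos", "ref", "alt"]]
        found = rm.merge(planted, on=["chrom", "pos", "ref", "alt"])
        assert len(found) == len(planted)  # 100% of planted sites recovered


class TestReconstruction:
    def test_autosomal_counts(self):
        alt, total = reconstruct_allele_counts([0.5, 0.25], [50, 100], chrom="chr2")
        assert list(total) == [100, 200]
        assert list(alt) == [50, 50]

    def test_x_counts_use_hemizygote_rule(self):
        alt, total = reconstruct_allele_counts([0.5], [62], chrom="chrX", male_fraction=0.5)
        assert total[0] == 2 * 62 - 31
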