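import numpy as np
import pandas as pd
import pytest

from cgprofiler.cohort import CohortGenotypes
from cgprofiler.profiles import (
    ancova_gene_type,
    anova_by_group,
    gene_profiles,
    individual_profiles,
    variability_rate,
)

import oracles


def build(dosage, genes, **flags):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, s = dosage.shape
    sites = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(s) + 1, "id": ".", "ref": "A", "alt": "G"}
    )
    cohort = CohortGenotypes(
        subjects=[f"S{i}" for i in range(n)],
        sites=sites,
        dosage=dosage,
        ref_depth=np.full((n, s), 30, dtype=np.int32),
        alt_depth=np.full((n, s), 30, dtype=np.int32),
    )
    classes = pd.DataFrame({"gene": genes})
    defaults = dict(
        nonsynonymous=True, deleterious=False, hgmd=False, vus=True, novel=False, rare=False
    )
    for k, v in defaults.items():
        classes[k] = flags.get(k, v)
    return cohort, classes


class TestIndividualProfiles:
    def test_hom_alt_counts_once_per_site(self):
        cohort, classes = build([[1, 2, 1]], ["A", "A", "B"])
        prof = individual_profiles(cohort, classes)
        assert prof.n_total.iloc[0] == 3

    def test_genes_with_variant_deduplicated(self):
        cohort, classes = build([[1, 1, 1]], ["A", "A", "B"])
        prof = individual_profiles(cohort, classes)
        assert prof.n_genes_with_variant.iloc[0] == 2

    def test_synonymous_sites_excluded(self):
        cohort, classes = build(
            [[1, 1]], ["A", "A"], nonsynonymous=[True, False], vus=[True, False]
        )
        prof = individual_profiles(cohort, classes)
        assert prof.n_total.iloc[0] == 1

    def test_class_partition_identity(self, default_metrics):
        """n_vus + carried sites in (deleterious or HGMD) = n_total, per subject."""
        filtered = default_metrics["filtered"]
        classes = default_metrics["classes"]
        prof = default_metrics["profiles"]
        nonsyn = classes.nonsynonymous.to_numpy()
        del_or_hgmd = (classes.deleterious | classes.hgmd).to_numpy() & nonsyn
        carried = filtered.dosage > 0
        union_counts = (carried & del_or_hgmd).sum(axis=1)
        assert (prof.n_vus.to_numpy() + union_counts == prof.n_total.to_numpy()).all()

    def test_profiles_consistent_with_direct_tabulation(self, default_metrics):
        """Rebuilding counts straight from the genotype matrix agrees exactly."""
        filtered = default_metrics["filtered"]
        classes = default_metrics["classes"]
        prof = default_metrics["profiles"]
        carried = (filtered.dosage > 0) & classes.nonsynonymous.to_numpy()
        assert (prof.n_total.to_numpy() == carried.sum(axis=1)).all()
        assert (
            prof.n_hgmd.to_numpy() == (carried & classes.hgmd.to_numpy()).sum(axis=1)
        ).all()


class TestGeneProfiles:
    def test_zero_variant_gene_present(self):
        cohort, classes = build([[1]], ["A"])
        gp = gene_profiles(cohort, classes, {"A": 1000, "B": 2000})
        b = gp[gp.gene == "B"].iloc[0]
        assert b.n_variants == 0 and b.prevalence == 0.0

    def test_prevalence_fraction_of_cohort(self):
        dosage = np.zeros((10, 1), dtype=np.int8)
        dosage[:4, 0] = 1
        cohort, classes = build(dosage, ["A"], rare=[True])
        gp = gene_profiles(cohort, classes, {"A": 500})
        assert gp.iloc[0].prevalence_rare == pytest.approx(0.4)

    def test_identical_inputs_identical_profiles(self):
        cohort, classes = build([[1, 1], [0, 1]], ["A", "B"])
        g1 = gene_profiles(cohort, classes, {"A": 900, "B": 900})
        g2 = gene_profiles(cohort, classes, {"A": 900, "B": 900})
        pd.testing.assert_frame_equal(g1.drop(columns="gene"), g2.drop(columns="gene"))

    def test_variants_per_kb(self):
        cohort, classes = build([[1, 1, 1]], ["A", "A", "A"])
        gp = gene_profiles(cohort, classes, {"A": 1500})
        assert gp.iloc[0].variants_per_kb == pytest.approx(2.0)


class TestVariabilityRate:
    def test_exact_line(self):
        prof = pd.DataFrame(
            {"coding_length": [1000, 2000, 3000], "n_variants": [6, 12, 18]}
        )
        rate = variability_rate(prof)
        assert rate.slope_per_kb == pytest.approx(6.0)
        assert rate.r_squared == pytest.approx(1.0)

    def test_flat_counts_zero_slope(self):
        prof = pd.DataFrame({"coding_length": [1000, 2000, 3000], "n_variants": [5, 5, 5]})
        assert variability_rate(prof).slope_per_kb == pytest.approx(0.0)

    def test_zero_length_variance_raises(self):
        prof = pd.DataFrame({"coding_length": [1000] * 4, "n_variants": [1, 2, 3, 4]})
        with pytest.raises(ValueError, match="variance"):
            variability_rate(prof)

    def test_matches_normal_equations(self, rng):
        x = rng.uniform(300, 11000, size=80)
        y = rng.poisson(0.006 * x)
        slope, intercept = oracles.normal_equation_slope(x, y)
        rate = variability_rate(pd.DataFrame({"coding_length": x, "n_variants": y}))
        assert rate.slope_per_kb == pytest.approx(slope * 1000, rel=1e-9)
        assert rate.intercept == pytest.approx(intercept, rel=1e-6, abs=1e-9)

    def test_generator_defaults_near_six_per_kb(self, default_metrics, default_syn):
        from cgprofiler.genes import coding_length, gene_models_from_frames

        models, _ = gene_models_from_frames(default_syn.transcripts, default_syn.gene_list)
        lengths = {m.gene_symbol: coding_length(m) for m in models}
        gp = gene_profiles(
            default_metrics["filtered"], default_metrics["classes"], lengths
        )
        rate = variability_rate(gp)
        assert rate.slope_per_kb == pytest.approx(6.0, rel=0.25)
        assert 0 <= rate.r_squared <= 1


def _group_data(rng, means, sds, ns):
    profs, labels = [], []
    for g, (m, s, n) in enumerate(zip(means, sds, ns)):
        x = rng.normal(size=n)
        x = (x - x.mean()) / x.std(ddof=0) * s + m  # exact sample mean and sd
        profs.extend(x)
        labels.extend([f"g{g}"] * n)
    prof = pd.DataFrame({"subject": [f"S{i}" for i in range(len(profs))], "n_total": profs})
    sub = pd.DataFrame({"subject": prof.subject, "subpopulation": labels})
    return prof, sub


class TestAnova:
    def test_two_group_difference_like_reported_means(self, rng):
        """African vs European per-person totals (84 vs 64.5, sd 8) are
        overwhelmingly separated."""
        prof, sub = _group_data(rng, [64.5, 84.0], [8, 8], [331, 43])
        f, p = anova_by_group(prof, sub)
        assert p < 1e-10

    def test_constant_values_give_zero_f(self):
        prof = pd.DataFrame({"subject": [f"S{i}" for i in range(8)], "n_total": [5] * 8})
        sub = pd.DataFrame(
            {"subject": prof.subject, "subpopulation": ["a"] * 4 + ["b"] * 4}
        )
        f, p = anova_by_group(prof, sub)
        assert f == 0.0 and p == 1.0

    def test_type_one_calibration(self, rng):
        """Under a common distribution the rejection rate stays near alpha."""
        n_rep, hits = 500, 0
        for _ in range(n_rep):
            vals = rng.normal(50, 8, size=60)
            prof = pd.DataFrame(
                {"subject": [f"S{i}" for i in range(60)], "n_total": vals}
            )
            sub = pd.DataFrame(
                {
                    "subject": prof.subject,
                    "subpopulation": np.repeat(["a", "b", "c"], 20),
                }
            )
            _, p = anova_by_group(prof, sub)
            hits += p < 0.05
        rate = hits / n_rep
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_small_group_raises(self):
        prof = pd.DataFrame({"subject": ["S0", "S1", "S2"], "n_total": [1, 2, 3]})
        sub = pd.DataFrame(
            {"subject": prof.subject, "subpopulation": ["a", "a", "b"]}
        )
        with pytest.raises(ValueError, match=">= 2 subjects"):
            anova_by_group(prof, sub)


class TestAncova:
    def _profiles(self, rng, rates={"tumor_suppressor": 5.0, "predisposition": 8.0}):
        rows = []
        for gt, rate in rates.items():
            for i in range(50):
                L = rng.uniform(1000, 10000)
                rows.append(
                    {
                        "gene": f"{gt}{i}",
                        "gene_type": gt,
                        "coding_length": L,
                        "n_variants": rng.poisson(rate * L / 1000),
                    }
                )
        return pd.DataFrame(rows)

    def test_planted_rate_difference_detected(self, rng):
        """5 vs 8 variants/kb across 50 genes per type is detected in most
        replicates."""
        hits = sum(ancova_gene_type(self._profiles(rng))[1] < 0.05 for _ in range(20))
        assert hits >= 16

    def test_single_type_raises(self, rng):
        prof = self._profiles(rng, rates={"oncogene": 5.0})
        with pytest.raises(ValueError, match="2 gene types"):
            ancova_gene_type(prof)

    def test_generator_defaults_detect_predisposition_excess(self, default_metrics, default_syn):
        from cgprofiler.genes import coding_length, gene_models_from_frames

        models, _ = gene_models_from_frames(default_syn.transcripts, default_syn.gene_list)
        lengths = {m.gene_symbol: coding_length(m) for m in models}
        gp = gene_profiles(default_metrics["filtered"], default_metrics["classes"], lengths)
        gtypes = default_syn.gene_list.set_index("gene_symbol")["gene_type"]
        gp["gene_type"] = gp.gene.map(gtypes)
        f, p = ancova_gene_type(gp)
        assert p < 0.05
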