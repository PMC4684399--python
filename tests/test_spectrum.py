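"""Spectra: strand collapsing, contexts, compositions, enrichment statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from capmut.formats import RegionSet, TargetRegion
from capmut.somatic import classify_somatic
from capmut.simulate import SimulationConfig, simulate_cohort, simulate_panel
from capmut.spectrum import (
    ALL_CONTEXTS,
    SUBSTITUTION_CLASSES,
    collapse_substitution,
    context_of,
    enrichment_test,
    mutation_rate,
    paired_class_notation,
    paired_context_notation,
    sample_heterogeneity,
    spectrum_report,
    stratum_composition,
    titv_ratio,
)
from conftest import DictReference

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class TestCollapse:
    def test_all_twelve_ordered_substitutions(self):
        """Enumerate all ordered substitutions against a hand-built
        complement table: purine refs map onto their pyrimidine mirror."""
        for ref, alt in itertools.permutations("ACGT", 2):
            got = collapse_substitution(ref, alt)
            if ref in "CT":
                assert got == f"{ref}>{alt}"
            else:
                assert got == f"{_COMP[ref]}>{_COMP[alt]}"
            assert got in SUBSTITUTION_CLASSES

    def test_examples(self):
        assert collapse_substitution("G", "T") == "C>A"
        assert collapse_substitution("C", "T") == "C>T"
        assert collapse_substitution("A", "C") == "T>G"

    def test_non_base_fatal(self):
        with pytest.raises(ValueError):
            collapse_substitution("N", "A")

    def test_paired_notation(self):
        assert paired_class_notation("C>T") == "C/G→T/A"
        assert paired_class_notation("T>G") == "T/A→G/C"


class TestContext:
    def test_purine_center_reverse_complemented(self):
        ref = DictReference({"chr1": "TGA"})
        assert context_of("chr1", 2, ref) == "T[C]A"
        assert paired_context_notation("T[C]A") == "T[C]A/T[G]A"

    def test_most_common_context_rendering(self):
        ref = DictReference({"chr1": "TCT"})
        assert context_of("chr1", 2, ref) == "T[C]T"
        assert paired_context_notation("T[C]T") == "T[C]T/A[G]A"

    def test_contig_edge_excluded(self):
        ref = DictReference({"chr1": "ACGT"})
        assert context_of("chr1", 1, ref) is None
        assert context_of("chr1", 4, ref) is None

    def test_n_flank_excluded(self):
        ref = DictReference({"chr1": "NCT"})
        assert context_of("chr1", 2, ref) is None


class TestComposition:
    def test_gc_at_tally(self):
        ref = DictReference({"chr1": "ACGT"})
        rs = RegionSet([TargetRegion("chr1", 0, 4, "CDS")])
        comp = stratum_composition(rs, ref, "coding")
        assert (comp.gc_bases, comp.at_bases, comp.total_bases) == (2, 2, 4)

    def test_trinucleotide_windows_hand_enumerated(self):
        # ACGTA windows: ACG (A[C]G), CGT (center G -> A[C]G), GTA (G[T]A)
        ref = DictReference({"chr1": "ACGTA"})
        rs = RegionSet([TargetRegion("chr1", 0, 5, "CDS")])
        comp = stratum_composition(rs, ref, "coding")
        assert dict(comp.trinuc) == {"A[C]G": 2, "G[T]A": 1}

    def test_n_bases_excluded(self):
        ref = DictReference({"chr1": "ANGTA"})
        rs = RegionSet([TargetRegion("chr1", 0, 5, "CDS")])
        comp = stratum_composition(rs, ref, "coding")
        assert comp.total_bases == 4  # the N base is not tallied
        assert all("N" not in k for k in comp.trinuc)

    def test_flanks_may_extend_outside_stratum(self):
        # CDS covers only the middle base; its window uses both neighbours
        ref = DictReference({"chr1": "ACGTA"})
        rs = RegionSet([TargetRegion("chr1", 2, 3, "CDS")])
        comp = stratum_composition(rs, ref, "coding")
        assert dict(comp.trinuc) == {"A[C]G": 1}  # window CGT collapsed


class TestTiTvAndRates:
    def test_titv_examples(self):
        assert titv_ratio([("A", "G"), ("C", "T"), ("A", "C")]) == pytest.approx(2.0)
        assert titv_ratio([("A", "C"), ("C", "G")]) == 0.0
        assert titv_ratio([("A", "G"), ("C", "T")]) is None  # undefined

    def test_titv_uniform_twelve_substitutions(self):
        pairs = list(itertools.permutations("ACGT", 2))
        assert titv_ratio(pairs) == pytest.approx(4 / 8)

    def test_mutation_rate(self):
        assert mutation_rate(10, 2_000_000) == pytest.approx(5.0)
        assert mutation_rate(0, 1000) == 0.0
        assert round(mutation_rate(21, 1_019_417), 1) == 20.6
        with pytest.raises(ValueError):
            mutation_rate(1, 0)


class TestEnrichment:
    def test_worked_odds_ratio(self):
        res = enrichment_test("C>T", 10, 1000, 5, 2000)
        assert res.odds_ratio == pytest.approx((10 / 990) / (5 / 1995), abs=1e-12)
        assert res.odds_ratio == pytest.approx(4.030, abs=1e-3)

    def test_equal_proportions_or_one(self):
        res = enrichment_test("x", 10, 1000, 20, 2000, m_tests=6)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_raw == pytest.approx(1.0)
        assert res.p_adjusted == 1.0

    def test_bonferroni_identity_and_cap(self):
        res = enrichment_test("x", 30, 1000, 5, 2000, m_tests=1)
        assert res.p_adjusted == res.p_raw
        res32 = enrichment_test("x", 30, 1000, 5, 2000, m_tests=32)
        assert res32.p_adjusted == min(1.0, 32 * res32.p_raw)

    def test_zero_margin_flagged_not_raised(self):
        res = enrichment_test("x", 0, 1000, 5, 2000)
        assert not res.defined and res.odds_ratio is None

    def test_oracle_equivalence_2x2_formula(self):
        """OR and CI agree to 1e-9 with an independent closed-form
        implementation on arbitrary tables."""
        rng = np.random.default_rng(12)
        z = stats.norm.ppf(0.975)
        for _ in range(200):
            ec, en = int(rng.integers(100, 5000)), int(rng.integers(100, 5000))
            mc, mn = int(rng.integers(1, ec // 2)), int(rng.integers(1, en // 2))
            res = enrichment_test("x", mc, ec, mn, en)
            a, b, c, d = mc, ec - mc, mn, en - mn
            or_ = (a / b) / (c / d)
            se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            assert res.odds_ratio == pytest.approx(or_, abs=1e-9, rel=1e-12)
            assert res.ci_low == pytest.approx(or_ * math.exp(-z * se), rel=1e-9)
            assert res.ci_high == pytest.approx(or_ * math.exp(z * se), rel=1e-9)

    def test_p_matches_fisher_in_asymptotic_regime(self):
        """The Wald p is within 10% of Fisher's exact p where the two tests
        are asymptotically equivalent: all cells >= 5 with large counts and
        moderate effects (in deep tails the Wald normal approximation and the
        discrete exact test deviate by construction)."""
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 50:
            ec, en = int(rng.integers(50_000, 200_000)), int(rng.integers(50_000, 200_000))
            p0 = rng.uniform(0.002, 0.01)
            mc = int(rng.binomial(ec, p0 * rng.uniform(0.9, 1.1)))
            mn = int(rng.binomial(en, p0))
            if min(mc, mn) < 100:
                continue
            res = enrichment_test("x", mc, ec, mn, en)
            _, p_fisher = stats.fisher_exact([[mc, ec - mc], [mn, en - mn]])
            if p_fisher < 0.05:
                continue
            assert res.p_raw == pytest.approx(p_fisher, rel=0.10)
            checked += 1

    def test_agrees_with_binomial_logistic_glm(self):
        """The 2x2 Wald statistics equal the stratum coefficient of a
        binomial logistic model fit with statsmodels (independent route)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        for _ in range(20):
            ec, en = int(rng.integers(200, 3000)), int(rng.integers(200, 3000))
            mc, mn = int(rng.integers(5, ec // 3)), int(rng.integers(5, en // 3))
            res = enrichment_test("x", mc, ec, mn, en)
            endog = np.array([[mc, ec - mc], [mn, en - mn]], dtype=float)
            exog = np.array([[1.0, 1.0], [1.0, 0.0]])
            fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
            assert math.exp(fit.params[1]) == pytest.approx(res.odds_ratio, rel=1e-6)
            assert fit.bse[1] == pytest.approx(res.se_log_or, rel=1e-5)

    def test_heterogeneity_diagnostic_bounds(self):
        tables = [(10, 1000, 5, 2000)] * 4
        p = sample_heterogeneity(tables)
        assert p is None or 0.0 <= p <= 1.0
        assert sample_heterogeneity([(0, 1000, 0, 2000)] * 3) is None


@pytest.fixture(scope="module")
def classified_cohort():
    """A simulated cohort with boosted rates, classified to high-confidence
    somatic SNVs with strata."""
    uniform = {c: 1 / 6 for c in SUBSTITUTION_CLASSES}
    config = SimulationConfig(
        seed=19, n_genes=8, flank_bp=0,
        somatic_rate_per_mbp={"coding": 3000.0, "non_coding": 1200.0},
        class_shares={"coding": dict(uniform), "non_coding": dict(uniform)},
        germline_rate=0.0, somatic_indel_fraction=0.0,
    )
    rng = np.random.default_rng(19)
    panel = simulate_panel(config, rng)
    cohort = simulate_cohort(panel, config, rng)
    rows = []
    for sample in cohort.samples:
        for call in cohort.calls[sample]:
            sv = classify_somatic(call)
            if sv is None or sv.confidence != "high" or call.kind != "SNV":
                continue
            stratum = panel.region_set.stratum_of(call.chrom, call.pos - 1)
            if stratum is None:
                continue
            rows.append(
                dict(sample=sample, chrom=call.chrom, pos=call.pos,
                     ref=call.ref, alt=call.alt, stratum=stratum)
            )
    return panel, pd.DataFrame(rows)


class TestReportProperties:
    def test_count_conservation(self, classified_cohort):
        panel, snvs = classified_cohort
        comps = {
            s: stratum_composition(panel.region_set, panel, s)
            for s in ("coding", "non_coding")
        }
        rep = spectrum_report(snvs, comps, panel)
        for stratum in ("coding", "non_coding"):
            n = int((snvs["stratum"] == stratum).sum())
            assert rep.class_counts[(stratum, "pooled")].sum() == n
            assert rep.context_counts[(stratum, "pooled")].sum() == n - sum(
                context_of(c, p, panel) is None
                for c, p, s in zip(snvs["chrom"], snvs["pos"], snvs["stratum"])
                if s == stratum
            )

    def test_strand_invariance(self, classified_cohort):
        """Reverse-complementing the reference and all variants leaves every
        class and context count unchanged."""
        panel, snvs = classified_cohort
        chrom = panel.chroms[0]
        L = panel.length(chrom)
        seq_rc = panel.fetch(chrom, 0, L).translate(str.maketrans("ACGT", "TGCA"))[::-1]
        mirror = DictReference({chrom: seq_rc})
        mirrored = snvs.copy()
        mirrored["pos"] = L + 1 - mirrored["pos"]
        mirrored["ref"] = [_COMP[b] for b in snvs["ref"]]
        mirrored["alt"] = [_COMP[b] for b in snvs["alt"]]

        def tallies(frame, ref):
            classes = pd.Series(
                [collapse_substitution(r, a) for r, a in zip(frame["ref"], frame["alt"])]
            ).value_counts()
            contexts = pd.Series(
                [context_of(c, p, ref) for c, p in zip(frame["chrom"], frame["pos"])]
            ).value_counts()
            return classes.to_dict(), contexts.to_dict()

        assert tallies(snvs, panel) == tallies(mirrored, mirror)

    def test_gc_replacement_fraction(self, classified_cohort):
        panel, snvs = classified_cohort
        comps = {
            s: stratum_composition(panel.region_set, panel, s)
            for s in ("coding", "non_coding")
        }
        only_gc = snvs[snvs["ref"].isin(["G", "C"])]
        rep = spectrum_report(only_gc, comps, panel)
        assert rep.gc_replacement_fraction["coding"] == pytest.approx(1.0)

    def test_planted_enrichment_recovered(self, classified_cohort):
        """With coding rates planted at 2.5x the non-coding rates, the
        class CIs cover the planted per-source odds (the composition
        denominators translate the per-Mbp rates into per-source-base
        rates, so the planted value is computable exactly)."""
        panel, snvs = classified_cohort
        comps = {
            s: stratum_composition(panel.region_set, panel, s)
            for s in ("coding", "non_coding")
        }
        rep = spectrum_report(snvs, comps, panel)
        rate = {"coding": 3000e-6, "non_coding": 1200e-6}
        checked = 0
        for cls, row in rep.class_enrichment.iterrows():
            if not row["defined"] or min(row["mutated_coding"], row["mutated_noncoding"]) < 10:
                continue
            src = "gc_bases" if cls.startswith("C") else "at_bases"
            p = {
                s: rate[s] / 6 * comps[s].total_bases / getattr(comps[s], src)
                for s in ("coding", "non_coding")
            }
            true_or = (p["coding"] / (1 - p["coding"])) / (
                p["non_coding"] / (1 - p["non_coding"])
            )
            assert row["ci_low"] <= true_or <= row["ci_high"]
            checked += 1
        assert checked >= 3


class TestPlantedRhoCoverage:
    def test_ci_covers_planted_relative_risk(self):
        """Planted-truth recovery: over 200 simulated cohorts per rho in
        {1, 2, 4} (~500 mutations each), the Woolf 95% CI covers the
        planted coding/non-coding odds ratio in at least 90% of replicates."""
        base_config = SimulationConfig(seed=33, n_genes=10, flank_bp=0)
        panel = simulate_panel(base_config)
        comps = {
            s: stratum_composition(panel.region_set, panel, s)
            for s in ("coding", "non_coding")
        }
        # per-source-base probability in the non-coding stratum, sized for
        # roughly 500 mutations per cohort at rho = 2
        p_nc = 2.5e-3
        shares = {c: (1.0 if c == "C>T" else 0.0) for c in SUBSTITUTION_CLASSES}
        for rho in (1.0, 2.0, 4.0):
            rate_nc = p_nc * comps["non_coding"].gc_bases / comps["non_coding"].total_bases * 1e6
            rate_c = rho * p_nc * comps["coding"].gc_bases / comps["coding"].total_bases * 1e6
            config = SimulationConfig(
                seed=33, n_genes=10, flank_bp=0,
                somatic_rate_per_mbp={"coding": rate_c, "non_coding": rate_nc},
                class_shares={"coding": shares, "non_coding": shares},
                germline_rate=0.0, somatic_indel_fraction=0.0,
                low_confidence_fraction=0.0, filter_fail_fraction=0.0,
            )
            p_c = rho * p_nc
            true_or = (p_c / (1 - p_c)) / (p_nc / (1 - p_nc))
            rng = np.random.default_rng(101)
            covered = 0
            n_rep = 200
            for _ in range(n_rep):
                cohort = simulate_cohort(panel, config, rng)
                mc = mn = 0
                for sample in cohort.samples:
                    for call in cohort.calls[sample]:
                        sv = classify_somatic(call)
                        if sv is None or sv.confidence != "high":
                            continue
                        stratum = "coding" if sv.stratum == "CDS" else "non_coding"
                        stratum = panel.region_set.stratum_of(call.chrom, call.pos - 1)
                        if stratum == "coding":
                            mc += 1
                        else:
                            mn += 1
                n_samples = len(cohort.samples)
                res = enrichment_test(
                    "C>T",
                    mc, comps["coding"].gc_bases * n_samples,
                    mn, comps["non_coding"].gc_bases * n_samples,
                )
                if res.defined and res.ci_low <= true_or <= res.ci_high:
                    covered += 1
            assert covered / n_rep >= 0.90, f"rho={rho}: coverage {covered / n_rep}"
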