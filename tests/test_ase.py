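"""dCt/ndCt quantification, rank-sum testing and cross-tissue comparison."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from aseqpcr.ase import (
    adjust_sample_significance,
    analyze_assay,
    apply_ct_exclusion,
    assay_summary,
    compare_tissues,
    compute_delta_ct,
    normality_screen,
    normalize,
    rank_sum_test,
)
from aseqpcr.simulate import SimulationConfig, simulate_het_cohort


def permutation_rank_sum_p(x, y):
    """Exhaustive-enumeration oracle for the two-sided Mann-Whitney p.

    Enumerates every assignment of the pooled values into groups of the
    observed sizes (valid for tie-free data), computes the U statistic of
    each, and returns 2 * min(P(U <= u), P(U >= u)) capped at 1.
    """
    pooled = list(x) + list(y)
    n = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_stat(x, y)
    us = [
        u_stat([pooled[i] for i in idx],
               [pooled[i] for i in range(len(pooled)) if i not in set(idx)])
        for idx in itertools.combinations(range(len(pooled)), n)
    ]
    p_le = sum(u <= u_obs for u in us) / len(us)
    p_ge = sum(u >= u_obs for u in us) / len(us)
    return min(1.0, 2.0 * min(p_le, p_ge))


def het_cohort(phi, seed, noise_sd=0.15, n_het=30, dye_bias=0.3):
    config = SimulationConfig(seed=seed, true_fold_change=phi, efficiency=1.0,
                              dye_bias=dye_bias, noise_sd=noise_sd)
    return simulate_het_cohort(n_het, config)


class TestDeltaCt:
    @pytest.mark.parametrize("fam,vic,expected", [
        (25.0, 24.0, 1.0), (25.0, 25.0, 0.0), (24.0, 25.5, -1.5),
    ])
    def test_arithmetic(self, fam, vic, expected):
        assert compute_delta_ct({"ct_fam": fam, "ct_vic": vic}) == expected

    def test_censored_channel_gives_absent(self):
        assert compute_delta_ct({"ct_fam": 25.0, "ct_vic": math.nan}) is None


class TestCtExclusion:
    def make_wells(self, ct_fams, sample="S1"):
        n = len(ct_fams)
        return pd.DataFrame(
            {"plate_id": "P", "well": [f"A{i}" for i in range(n)],
             "sample_id": sample, "assay_id": "A1", "replicate": range(1, n + 1),
             "ct_fam": ct_fams, "ct_vic": [30.0] * n}
        )

    def test_replicate_above_cutoff_dropped(self):
        surviving, log = apply_ct_exclusion(
            self.make_wells([36.5, 30.0, 30.0, 30.0]), min_replicates=3
        )
        assert len(surviving) == 3
        assert log.reason.tolist() == ["CT_ABOVE_CUTOFF"]

    def test_boundary_value_retained(self):
        # the rule is strictly greater than the cut-off
        surviving, log = apply_ct_exclusion(
            self.make_wells([36.0, 30.0, 30.0]), min_replicates=3
        )
        assert len(surviving) == 3 and len(log) == 0

    def test_censored_replicate_dropped(self):
        surviving, log = apply_ct_exclusion(
            self.make_wells([math.nan, 30.0, 30.0, 30.0]), min_replicates=3
        )
        assert len(surviving) == 3
        assert log.reason.tolist() == ["CENSORED"]

    def test_under_replicated_sample_dropped_entirely(self):
        surviving, log = apply_ct_exclusion(
            self.make_wells([37.0, 37.0, 37.0, 30.0, 30.0]), min_replicates=3
        )
        assert len(surviving) == 0
        assert any(r.startswith("TOO_FEW_REPLICATES") for r in log.reason)


class TestNormalize:
    def test_centering_identity(self):
        ndct, mean = normalize([0.5, 0.5, 0.5], [0.5, 0.5])
        assert np.allclose(ndct, 0.0) and mean == 0.0

    def test_gdna_self_centering(self):
        gdna = [0.1, 0.4, -0.2, 0.3]
        _, mean = normalize(gdna, gdna)
        assert mean == pytest.approx(0.0, abs=1e-15)

    def test_twofold_imbalance_closed_form(self):
        # phi=2 at perfect efficiency: cDNA dCt sits 1 cycle below gDNA
        wells, meta = het_cohort(phi=2.0, seed=0, noise_sd=0.0)
        material = dict(zip(meta.sample_id, meta.material))
        dct = (wells.ct_fam - wells.ct_vic).groupby(
            wells.sample_id.map(material)).unique()
        ndct, mean = normalize(dct["cDNA"], dct["gDNA"].repeat(3))
        assert mean == pytest.approx(-1.0, abs=1e-12)
        assert 2.0 ** abs(mean) == pytest.approx(2.0, abs=1e-12)

    def test_no_gdna_rejected(self):
        with pytest.raises(ValueError, match="gDNA"):
            normalize([1.0], [])


class TestRankSum:
    def test_worked_example_exact_third(self):
        res = rank_sum_test([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(1.0 / 3.0)
        assert res.method == "exact"

    def test_identical_groups_p_one(self):
        res = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.pvalue == pytest.approx(1.0)

    def test_degenerate_constant_data_flagged(self):
        res = rank_sum_test([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.pvalue == 1.0 and res.method == "degenerate"

    def test_ties_fall_back_to_corrected_approximation(self):
        res = rank_sum_test([1.0, 2.0, 2.0], [2.0, 3.0, 4.0])
        assert res.method == "asymptotic"
        assert 0.0 < res.pvalue <= 1.0

    @pytest.mark.parametrize("n,m", [(1, 1), (2, 3), (3, 3), (4, 4), (2, 7), (5, 5)])
    def test_matches_enumeration_oracle(self, n, m, rng):
        for _ in range(5):
            x = rng.normal(size=n).tolist()
            y = rng.normal(size=m).tolist()
            res = rank_sum_test(x, y)
            assert res.pvalue == pytest.approx(
                permutation_rank_sum_p(x, y), abs=1e-12
            )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            rank_sum_test([], [1.0])


class TestNormalityScreen:
    def test_skewed_sample_rejected(self, rng):
        skewed = rng.exponential(size=50)
        report = normality_screen(skewed, rng.normal(size=50))
        assert report["groups"]["cDNA"]["rejected"]
        assert report["any_rejected"]

    def test_symmetric_grid_not_rejected(self):
        # p = 0.167 for this grid, agreeing with R's shapiro.test to 7 digits
        grid = [-1.0, 0.0, 1.0] * 2
        report = normality_screen(grid, grid)
        assert not report["groups"]["cDNA"]["rejected"]
        assert report["groups"]["cDNA"]["p"] == pytest.approx(0.1670028, abs=1e-6)

    def test_tiny_group_skipped(self):
        report = normality_screen([1.0, 2.0], [1.0, 2.0, 3.0, 2.5])
        assert report["groups"]["cDNA"]["skipped"]
        assert not report["groups"]["gDNA"]["skipped"]


class TestAssaySummary:
    def test_balanced_cohort_no_ase(self, assay_info):
        wells, meta = het_cohort(phi=1.0, seed=42)
        result = analyze_assay(wells, meta, None, assay_info)
        assert not result.ase_detected
        assert result.direction_label == "A=B"
        assert result.risk_allele_direction == "none"

    def test_imbalanced_cohort_detected_with_direction(self, assay_info):
        wells, meta = het_cohort(phi=2.0, seed=43)
        result = analyze_assay(wells, meta, None, assay_info)
        assert result.ase_detected and result.overall_p < 1e-10
        # FAM (allele A) transcript is twice the VIC (allele B) transcript
        assert result.direction_label == "A>B"
        assert result.risk_allele_direction == "more"
        assert result.fold_change == pytest.approx(2.0, rel=0.15)

    def test_direction_label_uses_dye_orientation(self, assay_info):
        wells, meta = het_cohort(phi=0.5, seed=44)  # VIC allele more expressed
        info = dict(assay_info, fam_allele="G", vic_allele="A", risk_allele="G")
        result = analyze_assay(wells, meta, None, info)
        assert result.direction_label == "G<A"
        assert result.risk_allele_direction == "less"

    def test_zero_heterozygotes_rejected(self, assay_info):
        wells, meta = het_cohort(phi=1.0, seed=45)
        with pytest.raises(ValueError, match="ASSAY01"):
            analyze_assay(wells, meta, [], assay_info)

    def test_benjamini_hochberg_adjustment_is_monotone_and_conservative(
        self, assay_info
    ):
        wells, meta = het_cohort(phi=1.25, seed=51)
        result = analyze_assay(wells, meta, None, assay_info)
        adjusted = adjust_sample_significance(result.sample_results)
        raw = [r.p_value for r in result.sample_results]
        adj = [r.p_value for r in adjusted]
        assert all(a >= p for a, p in zip(adj, raw))
        # adjusted values are monotone in the raw ordering (ties allowed)
        order = np.argsort(raw)
        assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-15)

    def test_diagnosis_never_enters_overall_p(self, assay_info):
        wells, meta = het_cohort(phi=1.5, seed=46)
        base = analyze_assay(wells, meta, None, assay_info)
        permuted = meta.copy()
        permuted["diagnosis"] = permuted["diagnosis"].sample(
            frac=1.0, random_state=0).to_numpy()
        other = analyze_assay(wells, permuted, None, assay_info)
        assert other.overall_p == base.overall_p
        assert other.mean_n_delta_ct == base.mean_n_delta_ct


class TestStructuralInvariants:
    def test_channel_swap_antisymmetry(self, assay_info):
        wells, meta = het_cohort(phi=2.0, seed=47)
        base = analyze_assay(wells, meta, None, assay_info)
        swapped = wells.rename(columns={"ct_fam": "ct_vic", "ct_vic": "ct_fam"})
        other = analyze_assay(swapped, meta, None, assay_info)
        assert other.mean_n_delta_ct == pytest.approx(-base.mean_n_delta_ct)
        assert other.overall_p == pytest.approx(base.overall_p)
        assert base.direction_label == "A>B" and other.direction_label == "A<B"
        for s_base, s_other in zip(base.sample_results, other.sample_results):
            assert s_other.n_delta_ct == pytest.approx(-s_base.n_delta_ct)
            assert s_other.p_value == pytest.approx(s_base.p_value)

    def test_constant_dye_offset_cancels_in_ndct(self, assay_info):
        wells, meta = het_cohort(phi=2.0, seed=48)
        base = analyze_assay(wells, meta, None, assay_info)
        shifted = wells.assign(ct_fam=wells.ct_fam + 0.9)
        other = analyze_assay(shifted, meta, None, assay_info)
        assert other.mean_n_delta_ct == pytest.approx(base.mean_n_delta_ct,
                                                      abs=1e-12)
        for s_base, s_other in zip(base.sample_results, other.sample_results):
            assert s_other.n_delta_ct == pytest.approx(s_base.n_delta_ct,
                                                       abs=1e-12)

    def test_gdna_self_centering_through_pipeline(self, assay_info):
        wells, meta = het_cohort(phi=2.0, seed=49)
        gdna = meta.loc[meta.material == "gDNA", "sample_id"]
        gwells = wells[wells.sample_id.isin(set(gdna))]
        dcts = (gwells.ct_fam - gwells.ct_vic).to_numpy()
        _, mean = normalize(dcts, dcts)
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_rerun(self, assay_info):
        a = analyze_assay(*het_cohort(phi=1.5, seed=50), None, assay_info)
        b = analyze_assay(*het_cohort(phi=1.5, seed=50), None, assay_info)
        assert a.overall_p == b.overall_p
        assert a.mean_n_delta_ct == b.mean_n_delta_ct


def fake_result(assay_id, gene, p, ndct, **kw):
    from types import SimpleNamespace

    return SimpleNamespace(assay_id=assay_id, gene=gene, overall_p=p,
                           ase_detected=p <= 0.05, mean_n_delta_ct=ndct, **kw)


class TestCompareTissues:
    def test_classes(self):
        brain = [
            fake_result("a1", "BCKDK", 1e-15, -0.8),
            fake_result("a2", "RAB7L1", 1e-16, 0.6),
            fake_result("a3", "GPNMB", 0.8, 0.05),
            fake_result("a4", "X", 1e-4, -0.5),
            fake_result("a5", "Y", 0.9, 0.01),
        ]
        blood = [
            fake_result("a1", "BCKDK", 1e-16, -0.7),
            fake_result("a2", "RAB7L1", 0.99, 0.02),
            fake_result("a3", "GPNMB", 0.7, -0.03),
            fake_result("a4", "X", 1e-3, 0.4),
            fake_result("a6", "Z", 0.5, 0.0),
        ]
        table = compare_tissues(brain, blood).set_index("assay_id")
        assert table.at["a1", "class"] == "concordant_ase"
        assert table.at["a2", "class"] == "brain_specific"
        assert table.at["a3", "class"] == "no_ase"
        assert table.at["a4", "class"] == "discordant_direction"
        assert table.at["a5", "class"] == "incomparable"
        assert table.at["a6", "class"] == "incomparable"
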