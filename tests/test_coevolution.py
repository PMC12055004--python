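"""Mirrortree statistics, Fisher r-to-z, control panels, profiling."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from skbio import DistanceMatrix

from conftest import random_distance_matrix
from coevotree.coevolution import (CorrelationResult, PresenceAbsenceProfile,
                                   common_taxa_align, compare_correlations,
                                   control_panel_analysis, fisher_transform,
                                   inverse_fisher_transform,
                                   mirrortree_correlation,
                                   profile_cooccurrence, read_profiles_tsv)
from coevotree.errors import (DegenerateSampleSizeError,
                              InsufficientOverlapError, InvalidParameterError,
                              UndefinedCorrelationError)


def brute_force_mirrortree_r(dm1, dm2):
    """Independent oracle: enumerate unordered taxon pairs explicitly and
    apply the Pearson formula from sums, no vectorized triangles."""
    common = sorted(set(dm1.ids) & set(dm2.ids))
    pairs = list(itertools.combinations(common, 2))
    rs = [dm1[a, b] for a, b in pairs]
    ss = [dm2[a, b] for a, b in pairs]
    rbar, sbar = sum(rs) / len(rs), sum(ss) / len(ss)
    num = sum((x - rbar) * (y - sbar) for x, y in zip(rs, ss))
    den = math.sqrt(sum((x - rbar) ** 2 for x in rs)
                    * sum((y - sbar) ** 2 for y in ss))
    return num / den


class TestCommonTaxaAlign:
    def test_reorders_alphabetically(self, rng):
        ids = ["d", "b", "a", "c"]
        dm1 = random_distance_matrix(rng, ids)
        dm2 = random_distance_matrix(rng, list(reversed(ids)))
        a, b = common_taxa_align(dm1, dm2)
        assert list(a.ids) == list(b.ids) == ["a", "b", "c", "d"]
        assert a["b", "d"] == dm1["b", "d"]

    def test_restricts_to_intersection(self, rng):
        dm1 = random_distance_matrix(rng, list("ABCDEF"))
        dm2 = random_distance_matrix(rng, list("DEFGHI"))
        with pytest.raises(InsufficientOverlapError):
            common_taxa_align(dm1, dm2)
        dm2 = random_distance_matrix(rng, list("CDEFGH"))
        a, b = common_taxa_align(dm1, dm2)
        assert list(a.ids) == ["C", "D", "E", "F"]

    def test_disjoint_sets_error(self, rng):
        dm1 = random_distance_matrix(rng, list("ABCD"))
        dm2 = random_distance_matrix(rng, list("WXYZ"))
        with pytest.raises(InsufficientOverlapError):
            common_taxa_align(dm1, dm2)


class TestMirrortreeCorrelation:
    def test_self_correlation_is_one(self, rng):
        dm = random_distance_matrix(rng, list("ABCDE"))
        res = mirrortree_correlation(dm, dm)
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.n_taxa == 5 and res.n_pairs == 10

    def test_affine_invariance(self, rng):
        dm = random_distance_matrix(rng, list("ABCDE"))
        scaled = DistanceMatrix(2.0 * dm.data + 0.1 * (dm.data > 0), ids=dm.ids)
        assert mirrortree_correlation(dm, scaled).r == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_and_permutation_invariance(self, rng):
        dm1 = random_distance_matrix(rng, list("ABCDEF"))
        dm2 = random_distance_matrix(rng, list("ABCDEF"))
        r12 = mirrortree_correlation(dm1, dm2).r
        r21 = mirrortree_correlation(dm2, dm1).r
        assert r12 == pytest.approx(r21, abs=1e-12)
        perm = ["C", "F", "A", "B", "E", "D"]
        r_perm = mirrortree_correlation(dm1.filter(perm), dm2.filter(perm)).r
        assert r_perm == pytest.approx(r12, abs=1e-12)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_matches_brute_force_enumeration(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        ids = [f"t{i}" for i in range(n_taxa)]
        for _ in range(5):
            dm1 = random_distance_matrix(rng, ids)
            dm2 = random_distance_matrix(rng, ids)
            got = mirrortree_correlation(dm1, dm2).r
            assert got == pytest.approx(brute_force_mirrortree_r(dm1, dm2),
                                        abs=1e-12)

    def test_zero_variance_error(self, rng):
        flat = DistanceMatrix(np.ones((4, 4)) - np.eye(4), ids=list("ABCD"))
        other = random_distance_matrix(rng, list("ABCD"))
        with pytest.raises(UndefinedCorrelationError):
            mirrortree_correlation(flat, other)


class TestFisherTransform:
    def test_known_values(self):
        assert fisher_transform(0.0) == 0.0
        assert fisher_transform(0.8) == pytest.approx(
            0.5 * math.log(1.8 / 0.2), abs=1e-12)

    @given(st.floats(min_value=-0.998, max_value=0.998))
    @settings(deadline=None, derandomize=True)
    def test_odd_and_invertible(self, r):
        assert fisher_transform(-r) == pytest.approx(-fisher_transform(r),
                                                     abs=1e-12)
        assert inverse_fisher_transform(fisher_transform(r)) == pytest.approx(
            r, abs=1e-12)

    def test_strictly_increasing(self):
        grid = np.linspace(-0.99, 0.99, 51)
        vals = [fisher_transform(r) for r in grid]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_boundary_error(self):
        for r in (1.0, -1.0, 1.5):
            with pytest.raises(InvalidParameterError):
                fisher_transform(r)


class TestCompareCorrelations:
    def test_equal_transforms_give_zero(self):
        c1 = CorrelationResult(r=0.7, n_taxa=20, gene_pair=("a", "b"))
        c2 = CorrelationResult(r=0.7, n_taxa=35, gene_pair=("a", "c"))
        cmp = compare_correlations(c1, c2)
        assert cmp.z == 0.0
        assert cmp.p_value == 1.0

    def test_closed_form_example(self):
        c1 = CorrelationResult(r=0.9, n_taxa=30)
        c2 = CorrelationResult(r=0.5, n_taxa=30)
        cmp = compare_correlations(c1, c2)
        se = math.sqrt(2.0 / 27.0)
        expected = (math.atanh(0.9) - math.atanh(0.5)) / se
        assert cmp.z == pytest.approx(expected, abs=1e-12)
        assert abs(cmp.z) == pytest.approx(3.39, abs=0.005)

    def test_precision_grows_with_n(self):
        c1 = CorrelationResult(r=0.9, n_taxa=30)
        c2 = CorrelationResult(r=0.5, n_taxa=30)
        z_small = compare_correlations(c1, c2).z
        z_large = compare_correlations(
            CorrelationResult(r=0.9, n_taxa=60),
            CorrelationResult(r=0.5, n_taxa=60)).z
        assert abs(z_large) > abs(z_small)

    def test_sign_conventions(self):
        c1 = CorrelationResult(r=0.9, n_taxa=30)
        c2 = CorrelationResult(r=0.5, n_taxa=30)
        z_eq = compare_correlations(c1, c2, sign_convention="equation").z
        z_neg = compare_correlations(c1, c2, sign_convention="negated").z
        assert z_eq > 0  # higher first correlation, as-printed equation
        assert z_neg == -z_eq  # flipped: higher correlation -> negative

    def test_small_n_rejected(self):
        good = CorrelationResult(r=0.5, n_taxa=10)
        bad = CorrelationResult(r=0.5, n_taxa=3)
        with pytest.raises(DegenerateSampleSizeError):
            compare_correlations(good, bad)


class TestControlPanel:
    def test_equal_control_zero_z_and_flag(self):
        target = CorrelationResult(r=0.9, n_taxa=25, gene_pair=("t1", "t2"))
        control = CorrelationResult(r=0.9, n_taxa=25, gene_pair=("t1", "c1"))
        report = control_panel_analysis(target, [control])
        assert report.target_above_cutoff
        assert report.table.loc[0, "z_vs_target"] == 0.0

    def test_cutoff_semantics(self):
        target = CorrelationResult(r=0.5, n_taxa=25)
        control = CorrelationResult(r=0.9, n_taxa=25)
        report = control_panel_analysis(target, [control])
        assert not report.target_above_cutoff

    def test_failed_row_flagged_run_continues(self):
        target = CorrelationResult(r=0.9, n_taxa=25)
        controls = [CorrelationResult(r=0.4, n_taxa=25, gene_pair=("t", "ok")),
                    CorrelationResult(r=0.4, n_taxa=3, gene_pair=("t", "bad"))]
        report = control_panel_analysis(target, controls)
        assert len(report.table) == 2
        ok, bad = report.table.iloc[0], report.table.iloc[1]
        assert ok["error"] == "" and np.isfinite(ok["z_vs_target"])
        assert bad["error"] != "" and np.isnan(bad["z_vs_target"])

    def test_bh_correction_optional(self):
        target = CorrelationResult(r=0.9, n_taxa=25)
        controls = [CorrelationResult(r=x, n_taxa=25) for x in (0.2, 0.5, 0.8)]
        report = control_panel_analysis(target, controls, bh_correct=True)
        assert "p_bh" in report.table.columns
        assert (report.table["p_bh"] >= report.table["p"] - 1e-15).all()


class TestProfileCooccurrence:
    def test_identical_profiles(self):
        p = PresenceAbsenceProfile("g1", {"a": True, "b": True, "c": False})
        res = profile_cooccurrence(p, PresenceAbsenceProfile("g2", p.calls))
        assert res.jaccard == 1.0
        assert res.co_presence == 2

    def test_disjoint_presence(self):
        p1 = PresenceAbsenceProfile("g1", {"a": True, "b": False, "c": False})
        p2 = PresenceAbsenceProfile("g2", {"a": False, "b": True, "c": False})
        assert profile_cooccurrence(p1, p2).jaccard == 0.0

    def test_clade_loss_pattern(self):
        """Gene A lost in one clade where gene B persists: agreement below 1,
        co-presence equal to the intersection size."""
        taxa = [f"s{i}" for i in range(10)]
        a_present = set(taxa[:6])            # absent in the s6-s9 clade
        b_present = set(taxa)                # present everywhere
        p1 = PresenceAbsenceProfile("regulator", {t: t in a_present for t in taxa})
        p2 = PresenceAbsenceProfile("effector", {t: t in b_present for t in taxa})
        res = profile_cooccurrence(p1, p2)
        assert res.jaccard < 1.0
        assert res.co_presence == len(a_present & b_present) == 6

    def test_hypergeometric_tail_matches_enumeration(self):
        """Oracle: exact enumeration of all placements of gene B's presences."""
        taxa = list("abcdef")
        p1 = PresenceAbsenceProfile("g1", {t: t in "abc" for t in taxa})
        p2 = PresenceAbsenceProfile("g2", {t: t in "abcd" for t in taxa})
        res = profile_cooccurrence(p1, p2)
        k_obs = res.co_presence
        hits = total = 0
        for combo in itertools.combinations(taxa, 4):
            total += 1
            if len(set(combo) & set("abc")) >= k_obs:
                hits += 1
        assert res.p_value == pytest.approx(hits / total, abs=1e-12)

    def test_no_shared_taxa_error(self):
        p1 = PresenceAbsenceProfile("g1", {"a": True})
        p2 = PresenceAbsenceProfile("g2", {"b": True})
        with pytest.raises(InsufficientOverlapError):
            profile_cooccurrence(p1, p2)

    def test_tsv_round_trip(self, tmp_path):
        df = pd.DataFrame({"taxon": ["a", "b", "a", "b"],
                           "gene": ["g1", "g1", "g2", "g2"],
                           "present": [1, 0, 1, 1]})
        path = tmp_path / "profiles.tsv"
        df.to_csv(path, sep="\t", index=False)
        profiles = read_profiles_tsv(path)
        assert set(profiles) == {"g1", "g2"}
        assert profiles["g1"].present_taxa == frozenset({"a"})
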