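"""Tests for simplex-marker linkage mapping and interval-mapping scans."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polyqtl import linkage as lk
from polyqtl.simulate import Chromosome, CrossConfig, simulate_cross


class TestHaldane:
    def test_known_values(self):
        assert lk.haldane(0.0) == 0.0
        assert lk.haldane(0.2) == pytest.approx(25.54, abs=0.01)

    def test_mutual_inverses(self):
        r = np.linspace(0, 0.49, 50)
        np.testing.assert_allclose(lk.haldane_inverse(lk.haldane(r)), r,
                                   atol=1e-12)

    def test_unlinked_rejected(self):
        with pytest.raises(ValueError):
            lk.haldane(0.5)


class TestSelectSimplex:
    def test_class_filter_and_recoding(self):
        g4 = np.array([3, 0, 4, 2])
        g2 = np.array([2, 1, 1, 1])
        dosage = np.array([
            [1, 2, 1],       # RRRA x RR: excluded
            [1, 0, 1],       # AAAA x RA: dosage 1 -> carrier -> 1
            [3, 2, 1],       # RRRR x RA: dosage 3 -> non-carrier -> 0; 1 invalid
            [0, 1, 2],       # RRAA x RA: excluded (tetraploid heterozygous)
        ], dtype=float)
        keep, M = lk.select_simplex_markers(g4, g2, dosage)
        assert keep.tolist() == [1, 2]
        np.testing.assert_array_equal(M[0], [1, 0, 1])
        assert M[1, 0] == 0 and M[1, 1] == 1 and np.isnan(M[1, 2])


class TestChiSquare:
    @pytest.mark.parametrize("n0,n1,chi2,reject", [
        (50, 50, 0.0, False),
        (70, 30, 16.0, True),       # p ~ 6.3e-5 < 0.001
        (60, 40, 4.0, False),
    ])
    def test_one_to_one(self, n0, n1, chi2, reject):
        c, p = lk.chi_square_1to1(n0, n1)
        assert c == pytest.approx(chi2)
        assert (p <= 0.001) == reject
        if (n0, n1) == (70, 30):
            assert p == pytest.approx(6.3e-5, rel=0.02)

    def test_distortion_filter_false_positive_rate(self):
        """The filter removes about its alpha level of truly 1:1 markers;
        the exact null removal rate (binomial enumeration at n=138) is the
        oracle for the 95% band over 5,000 simulated markers."""
        rng = np.random.default_rng(17)
        n_off, m = 138, 5000
        M = rng.integers(0, 2, size=(m, n_off)).astype(float)
        kept = lk.segregation_filter(M, alpha=0.001)
        removed = int((~kept).sum())
        # exact removal probability of the discrete chi-square rule
        k = np.arange(n_off + 1)
        chi2 = (n_off - 2 * k) ** 2 / n_off
        p_reject = np.sum(stats.binom.pmf(k, n_off, 0.5)
                          * (stats.chi2.sf(chi2, 1) <= 0.001))
        lo, hi = stats.binom.interval(0.95, m, p_reject)
        assert lo <= removed <= hi


class TestPairwiseRecombination:
    def test_identical_and_complementary(self):
        v = np.array([0, 1, 1, 0, 1, 0, 0, 1], dtype=float)
        r, phase, _ = lk.pairwise_recombination(v, v)
        assert r == 0.0 and phase == "coupling"
        r, phase, _ = lk.pairwise_recombination(v, 1 - v)
        assert r == 0.0 and phase == "repulsion"

    def test_counted_mismatches(self):
        a = np.zeros(10)
        b = np.zeros(10)
        b[:2] = 1
        r, phase, lod = lk.pairwise_recombination(a, b)
        assert r == pytest.approx(0.2)
        assert phase == "coupling"

    def test_no_overlap_missing(self):
        a = np.array([1.0, np.nan])
        b = np.array([np.nan, 1.0])
        r, phase, _ = lk.pairwise_recombination(a, b)
        assert np.isnan(r) and phase == "unknown"

    def test_matrix_properties(self):
        rng = np.random.default_rng(2)
        M = rng.integers(0, 2, size=(15, 60)).astype(float)
        M[rng.random(M.shape) < 0.1] = np.nan
        est = lk.pairwise_recombination_matrix(M)
        r = est["r"]
        assert np.allclose(r, r.T, equal_nan=True)
        assert np.all(np.diag(r) == 0)
        ok = np.isfinite(r)
        assert ((r[ok] >= 0) & (r[ok] <= 0.5)).all()


class TestGrouping:
    def test_transitive_closure_chain(self):
        r = np.full((3, 3), 0.5)
        np.fill_diagonal(r, 0.0)
        r[0, 1] = r[1, 0] = 0.1
        r[1, 2] = r[2, 1] = 0.1
        r[0, 2] = r[2, 0] = 0.25   # above threshold, linked via b
        groups, _ = lk.group_markers(r, min_size=2)
        assert len(groups) == 1
        assert groups[0].tolist() == [0, 1, 2]

    def test_unlinked_markers_discarded(self):
        r = np.full((12, 12), 0.5)
        np.fill_diagonal(r, 0.0)
        groups, dropped = lk.group_markers(r, min_size=10)
        assert groups == []
        assert dropped == 12


class TestOrdering:
    def test_three_marker_chain(self):
        r = np.array([[0.0, 0.05, 0.10],
                      [0.05, 0.0, 0.05],
                      [0.10, 0.05, 0.0]])
        order = lk.order_markers(np.arange(3), r)
        assert order.tolist() in ([0, 1, 2], [2, 1, 0])

    def test_reversal_equal_objective(self):
        rng = np.random.default_rng(3)
        pos = np.sort(rng.uniform(0, 100, 12))
        r = lk.haldane_inverse(np.abs(pos[:, None] - pos[None, :]))
        order = lk.order_markers(np.arange(12), r)
        assert lk._path_cost(order, r) == pytest.approx(
            lk._path_cost(order[::-1], r))

    def test_recovers_true_order(self):
        rng = np.random.default_rng(4)
        pos = np.sort(rng.uniform(0, 80, 20))
        r = lk.haldane_inverse(np.abs(pos[:, None] - pos[None, :]))
        order = lk.order_markers(np.arange(20), r)
        tau = stats.kendalltau(order, np.arange(20)).statistic
        assert abs(tau) == pytest.approx(1.0)


def _simulated_map(seed=0, n=150, qtl=(), qtl_class=None):
    cfg = CrossConfig(
        n_offspring=n,
        chromosomes=(Chromosome("chr01", 100.0, 60),),
        parental_class_freqs={(0, 1): 0.5, (4, 1): 0.5},
        qtls=qtl, qtl_marker_class=qtl_class,
        depth_model=(45.0, 10.0), seed=seed)
    res = simulate_cross(cfg)
    mk = res.truth.markers
    keep, M = lk.select_simplex_markers(mk.g4.to_numpy(), mk.g2.to_numpy(),
                                        res.truth.offspring_dosages)
    gmap = lk.build_map(M, [f"m{i}" for i in keep],
                        physical=mk.iloc[keep][["chrom", "pos"]]
                        .reset_index(drop=True))
    return res, gmap


class TestConditionalProbabilities:
    def test_observed_marker_reproduced(self):
        _, gmap = _simulated_map(5)
        grp = gmap.groups[0]
        probs = lk.conditional_genotype_probabilities(grp, grp.cm[:3])
        for j in range(3):
            obs = grp.genotypes[j]
            fin = np.isfinite(obs)
            np.testing.assert_allclose(probs[j, fin], obs[fin], atol=1e-9)

    def test_symmetric_flanks_give_half(self):
        grp = lk.LinkageGroup(
            ["a", "b"], np.array([0.0, 20.0]), np.array([True, True]),
            np.array([[1.0], [0.0]]))
        p = lk.conditional_genotype_probabilities(grp, np.array([10.0]))
        assert p[0, 0] == pytest.approx(0.5)

    def test_tight_concordant_flanks_near_one(self):
        grp = lk.LinkageGroup(
            ["a", "b"], np.array([0.0, 2.0]), np.array([True, True]),
            np.array([[1.0], [1.0]]))
        p = lk.conditional_genotype_probabilities(grp, np.array([1.0]))
        assert p[0, 0] > 0.98

    def test_no_information_prior(self):
        grp = lk.LinkageGroup(
            ["a"], np.array([0.0]), np.array([True]),
            np.array([[np.nan]]))
        p = lk.conditional_genotype_probabilities(grp, np.array([0.0]))
        assert p[0, 0] == 0.5


class TestIntervalMapping:
    def test_sim_scan_at_markers_equals_marker_regression(self):
        """With complete genotypes the SIM statistic at a marker position is
        algebraically the single-marker regression."""
        from polyqtl.cmap import regress_marker

        res, gmap = _simulated_map(6, qtl=(("chr01", 50.0, 0.9),),
                                   qtl_class=(0, 1))
        grp = gmap.groups[0]
        assert np.isfinite(grp.genotypes).all()
        rng = np.random.default_rng(0)
        ids = res.truth.offspring_ids
        y = pd.Series(0.9 * grp.genotypes[10] + rng.normal(0, 0.5, len(ids)),
                      index=ids)
        scan = lk.sim_scan(gmap, y, ids, step=5.0)
        prof = scan["profile"]
        for j in (0, 10, 25):
            row = prof[prof.marker == grp.marker_ids[j]].iloc[0]
            direct = regress_marker(y.to_numpy(), grp.genotypes[j])
            assert row["minus_log10_p"] == pytest.approx(
                -np.log10(direct["p"]), abs=1e-8)
            assert row["effect"] == pytest.approx(direct["slope"], abs=1e-10)

    def test_null_scan_rarely_exceeds_threshold(self):
        exceed = 0
        n_seeds = 10
        for seed in range(n_seeds):
            res, gmap = _simulated_map(100 + seed)
            rng = np.random.default_rng(seed)
            y = pd.Series(rng.normal(0, 1, len(res.truth.offspring_ids)),
                          index=res.truth.offspring_ids)
            scan = lk.sim_scan(gmap, y, res.truth.offspring_ids)
            if scan["profile"]["minus_log10_p"].max() >= 2.0:
                exceed += 1
        assert exceed <= 2   # genome-wide max below 2 in >=80% of seeds

    def test_qtl_detected_near_truth(self):
        hits = 0
        for seed in range(10):
            res, gmap = _simulated_map(200 + seed,
                                       qtl=(("chr01", 50.0, 0.7),),
                                       qtl_class=(0, 1))
            vcs = res.truth
            ids = vcs.offspring_ids
            qi = vcs.qtls[0]["marker_index"]
            rng = np.random.default_rng(seed)
            y = pd.Series(0.7 * vcs.offspring_dosages[qi]
                          + rng.normal(0, 0.7, len(ids)), index=ids)
            scan = lk.sim_scan(gmap, y, ids)
            peaks = scan["peaks"]
            if peaks.empty:
                continue
            grp = gmap.groups[0]
            causal_bp = vcs.markers.iloc[qi]["pos"]
            causal_cm = grp.cm[np.argmin(np.abs(
                grp.physical["pos"].to_numpy() - causal_bp))]
            best = peaks.loc[peaks["minus_log10_p"].idxmax()]
            if abs(best["position_cm"] - causal_cm) <= 10.0:
                hits += 1
        assert hits >= 8

    def test_cim_without_cofactors_equals_sim(self):
        res, gmap = _simulated_map(7, qtl=(("chr01", 30.0, 0.8),),
                                   qtl_class=(0, 1))
        ids = res.truth.offspring_ids
        rng = np.random.default_rng(1)
        qi = res.truth.qtls[0]["marker_index"]
        y = pd.Series(0.8 * res.truth.offspring_dosages[qi]
                      + rng.normal(0, 0.6, len(ids)), index=ids)
        sim = lk.sim_scan(gmap, y, ids)
        cim = lk.cim_scan(gmap, y, ids,
                          cofactors=pd.DataFrame(columns=["group",
                                                          "position_cm"]))
        np.testing.assert_allclose(cim["profile"]["minus_log10_p"],
                                   sim["profile"]["minus_log10_p"], atol=1e-9)

    def test_cofactor_at_test_position_excluded(self):
        res, gmap = _simulated_map(8, qtl=(("chr01", 50.0, 0.8),),
                                   qtl_class=(0, 1))
        ids = res.truth.offspring_ids
        rng = np.random.default_rng(2)
        qi = res.truth.qtls[0]["marker_index"]
        y = pd.Series(0.8 * res.truth.offspring_dosages[qi]
                      + rng.normal(0, 0.6, len(ids)), index=ids)
        cof = pd.DataFrame({"group": [1], "position_cm": [50.0]})
        cim = lk.cim_scan(gmap, y, ids, cofactors=cof, exclusion_window=10.0)
        near = cim["profile"][(cim["profile"].position_cm - 50).abs() < 5]
        assert np.isfinite(near["minus_log10_p"]).all()

    def test_cim_separates_linked_qtl_better_than_sim(self):
        """Two QTL 60 cM apart: CIM resolves both peaks at least as often as
        SIM (comparative simulation on error-free maps)."""
        sim_both, cim_both = 0, 0
        for seed in range(25):
            cfg = CrossConfig(
                n_offspring=200,
                chromosomes=(Chromosome("chr01", 100.0, 40),),
                parental_class_freqs={(0, 1): 1.0},
                qtls=(("chr01", 20.0, 0.6), ("chr01", 80.0, 0.6)),
                seed=700 + seed)
            res = simulate_cross(cfg)
            mk = res.truth.markers
            keep, M = lk.select_simplex_markers(
                mk.g4.to_numpy(), mk.g2.to_numpy(), res.truth.offspring_dosages)
            gmap = lk.build_map(M, [f"m{i}" for i in keep],
                                physical=mk[["chrom", "pos"]]
                                .reset_index(drop=True))
            ids = res.truth.offspring_ids
            rng = np.random.default_rng(seed)
            y = pd.Series(res.truth.genetic_values
                          + rng.normal(0, 0.6, len(ids)), index=ids)
            sim = lk.sim_scan(gmap, y, ids)

            def hits_both(peaks, grp=gmap.groups[0]):
                if len(peaks) < 2:
                    return False
                qcm = []
                for q in res.truth.qtls:
                    bp = mk.iloc[q["marker_index"]]["pos"]
                    qcm.append(grp.cm[np.argmin(np.abs(
                        grp.physical["pos"].to_numpy() - bp))])
                return all(any(abs(p - c) <= 15 for p in peaks["position_cm"])
                           for c in qcm)

            cof = sim["peaks"][["group", "position_cm"]]
            cim = lk.cim_scan(gmap, y, ids, cofactors=cof)
            sim_both += hits_both(sim["peaks"])
            cim_both += hits_both(cim["peaks"])
        assert cim_both >= sim_both
        assert cim_both >= 15


class TestLD:
    def test_self_ld_is_one(self):
        rng = np.random.default_rng(5)
        M = rng.integers(0, 2, size=(5, 50)).astype(float)
        out = lk.pairwise_ld(M)
        np.testing.assert_allclose(np.diag(out["r2"]), 1.0)

    def test_independent_markers_mean_r2(self):
        rng = np.random.default_rng(6)
        n = 400
        M = rng.integers(0, 2, size=(40, n)).astype(float)
        out = lk.pairwise_ld(M)
        iu = np.triu_indices(40, 1)
        assert np.nanmean(out["r2"][iu]) == pytest.approx(1 / n, rel=0.5)

    def test_ld_decays_with_distance(self):
        res, gmap = _simulated_map(9, n=200)
        grp = gmap.groups[0]
        out = lk.pairwise_ld(grp.genotypes, cm=grp.cm)
        rho = stats.spearmanr(out["decay"]["distance_cm"],
                              out["decay"]["r2"]).statistic
        assert rho < -0.5


class TestTranslocation:
    @staticmethod
    def _map_with_chroms(chroms):
        m = len(chroms)
        grp = lk.LinkageGroup(
            [f"m{i}" for i in range(m)], np.linspace(0, 50, m),
            np.ones(m, dtype=bool), np.zeros((m, 4)),
            physical=pd.DataFrame({"chrom": chroms, "pos": range(m)}))
        return lk.GeneticMap([grp])

    def test_pure_group_not_flagged(self):
        rep = lk.detect_translocation(self._map_with_chroms(["chr03"] * 20))
        assert not rep["flagged"].any()

    def test_fusion_flagged(self):
        rep = lk.detect_translocation(
            self._map_with_chroms(["chr03"] * 12 + ["chr08"] * 8))
        assert rep["flagged"].all()

    def test_single_stray_marker_ignored(self):
        rep = lk.detect_translocation(
            self._map_with_chroms(["chr03"] * 24 + ["chr08"]))
        assert not rep["flagged"].any()


def test_map_length_consistency():
    """A 100 cM simulated chromosome maps to within 25% of its true length
    in at least 80% of seeds (Haldane consistency on error-free genotypes)."""
    ok = 0
    n_seeds = 50
    for seed in range(n_seeds):
        cfg = CrossConfig(
            n_offspring=200,
            chromosomes=(Chromosome("chr01", 100.0, 50),),
            parental_class_freqs={(0, 1): 0.5, (4, 1): 0.5},
            qtls=(), seed=900 + seed)
        res = simulate_cross(cfg)
        mk = res.truth.markers
        keep, M = lk.select_simplex_markers(mk.g4.to_numpy(), mk.g2.to_numpy(),
                                            res.truth.offspring_dosages)
        gmap = lk.build_map(M, [f"m{i}" for i in keep])
        if len(gmap.groups) != 1:
            continue
        true_span = (mk.pos_cm.iloc[keep].max() - mk.pos_cm.iloc[keep].min())
        if abs(gmap.groups[0].length_cm - true_span) <= 0.25 * true_span:
            ok += 1
    assert ok >= 0.8 * n_seeds, ok
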