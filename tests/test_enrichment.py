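"""Enrichment, matching, motif, MAF, LD and paired-difference analyses."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_genotypes
from poolqtl.data_io import AnnotationTrack
from poolqtl.enrichment import (
    directionality_agreement,
    effect_size_correlation,
    fold_enrichment,
    ld_expand,
    ld_r2,
    maf_comparison,
    match_backgrounds,
    motif_information_content,
    motif_position_density,
    orient_offsets,
    paired_allelic_difference_test,
    state_enrichment,
)


class TestFoldEnrichment:
    def test_arithmetic(self):
        universe = {f"s{i}" for i in range(1000)}
        query = {f"s{i}" for i in range(100)}
        reference = {f"s{i}" for i in range(80, 130)}
        fold, p = fold_enrichment(query, reference, universe)
        assert fold == pytest.approx((20 / 100) / (50 / 1000))  # 4.0
        assert 0 < p < 1

    def test_query_equals_universe(self):
        u = {f"s{i}" for i in range(50)}
        fold, _ = fold_enrichment(u, {f"s{i}" for i in range(10)}, u)
        assert fold == pytest.approx(1.0)

    def test_empty_sets_missing(self):
        u = {"a", "b"}
        fold, p = fold_enrichment(set(), {"a"}, u)
        assert np.isnan(fold) and np.isnan(p)

    def test_random_query_is_null(self, rng):
        universe = [f"s{i}" for i in range(400)]
        reference = set(universe[:100])
        folds, ps = [], []
        for _ in range(300):
            query = set(rng.choice(universe, 60, replace=False))
            fold, p = fold_enrichment(query, reference, set(universe))
            folds.append(fold)
            ps.append(p)
        assert np.mean(folds) == pytest.approx(1.0, abs=0.05)
        assert np.mean(np.array(ps) < 0.05) < 0.12


class TestDirectionality:
    def test_identical_directions(self):
        ca = pd.DataFrame({"pv": [1e-5] * 3, "direction": [1, -1, 1]}, index=list("abc"))
        ext = pd.DataFrame({"direction": [1, -1, 1]}, index=list("abc"))
        out = directionality_agreement(ca, ext, cutoffs=[1e-3])
        assert out["agreement"].iloc[0] == 1.0

    def test_two_thirds(self):
        ca = pd.DataFrame({"pv": [1e-5] * 3, "direction": [1, 1, -1]}, index=list("abc"))
        ext = pd.DataFrame({"direction": [1, -1, -1]}, index=list("abc"))
        out = directionality_agreement(ca, ext, cutoffs=[1e-3])
        assert out["agreement"].iloc[0] == pytest.approx(2 / 3)

    def test_agreement_rises_with_stringency(self, rng):
        # true directions recovered noisily; stronger hits have cleaner calls
        n = 4000
        truth = rng.choice([-1, 1], n)
        pv = 10.0 ** rng.uniform(-8, 0, n)
        flip = rng.random(n) < 0.4 * (pv ** 0.15)  # noisier at weak p
        obs = np.where(flip, -truth, truth)
        ca = pd.DataFrame({"pv": pv, "direction": obs}, index=[f"s{i}" for i in range(n)])
        ext = pd.DataFrame({"direction": truth}, index=ca.index)
        out = directionality_agreement(ca, ext, cutoffs=[1e-1, 1e-3, 1e-5, 1e-7])
        agree = out["agreement"].to_numpy()
        assert (np.diff(agree) > 0).all()


class TestEffectSizeCorrelation:
    def test_perfect_and_flipped(self, rng):
        shift = pd.Series(rng.normal(0, 0.1, 50), index=[f"s{i}" for i in range(50)])
        assert effect_size_correlation(shift, shift) == pytest.approx(1.0)
        assert effect_size_correlation(shift, -shift, harmonize=False) == pytest.approx(-1.0)
        assert effect_size_correlation(shift, -shift, harmonize=True) == pytest.approx(1.0)

    def test_attenuation_by_noise(self, rng):
        n = 5000
        var_s, var_n = 0.04, 0.01
        s = rng.normal(0, np.sqrt(var_s), n)
        ext = s + rng.normal(0, np.sqrt(var_n), n)
        idx = [f"s{i}" for i in range(n)]
        r = effect_size_correlation(pd.Series(s, idx), pd.Series(ext, idx))
        expected = np.sqrt(var_s / (var_s + var_n))
        assert r == pytest.approx(expected, abs=0.02)

    def test_needs_three_snps(self):
        s = pd.Series([0.1, 0.2], index=["a", "b"])
        with pytest.raises(ValueError):
            effect_size_correlation(s, s)


class TestMatchBackgrounds:
    def test_tolerance_arithmetic(self):
        ca = pd.Series({"q1": 40.0})
        assert len(match_backgrounds(ca, pd.Series({"c1": 30.0}))) == 1  # |log2| ~ 0.415
        assert len(match_backgrounds(ca, pd.Series({"c1": 57.0}))) == 0  # |log2| ~ 0.511

    def test_bijection_determinism_and_tolerance(self, rng):
        ca = pd.Series(rng.poisson(100, 80) + 20.0, index=[f"q{i}" for i in range(80)])
        ctrl = pd.Series(rng.poisson(110, 120) + 20.0, index=[f"c{i}" for i in range(120)])
        pairs = match_backgrounds(ca, ctrl, seed=5)
        again = match_backgrounds(ca, ctrl, seed=5)
        assert [(p.caqtl_id, p.control_id) for p in pairs] == [
            (p.caqtl_id, p.control_id) for p in again
        ]
        controls = [p.control_id for p in pairs]
        assert len(controls) == len(set(controls))  # each control used once
        for p in pairs:
            assert abs(np.log2(p.caqtl_reads) - np.log2(p.control_reads)) < 0.5


class TestStateEnrichment:
    def _track(self):
        iv = pd.DataFrame(
            {"chrom": "chr1",
             "start": [0, 1000, 2000, 3000],
             "end": [1000, 2000, 3000, 4000],
             "state": ["tss", "enhancer", "weak_enhancer", "quiescent"]}
        )
        return AnnotationTrack(iv)

    def test_identical_controls_fold_one(self, rng):
        track = self._track()
        pos = rng.integers(1, 4000, 400)
        snps = pd.DataFrame({"chrom": "chr1", "pos": pos})
        out = state_enrichment(snps, track, snps)
        assert np.allclose(out["controlled_fold"].dropna(), 1.0)

    def test_concentrated_query(self, rng):
        track = self._track()
        ca = pd.DataFrame({"chrom": "chr1", "pos": rng.integers(1, 1000, 200)})
        ctl = pd.DataFrame({"chrom": "chr1", "pos": rng.integers(1, 4000, 100_000)})
        out = state_enrichment(ca, track, ctl)
        assert out.loc["tss", "controlled_fold"] == pytest.approx(4.0, rel=0.1)

    def test_depth_confound_removed_by_matching(self, rng):
        # state "tss" is read-rich; caQTLs are sampled by depth, so raw
        # composition is skewed, but depth-matched controls remove the skew
        n = 4000
        pos = rng.integers(1, 4000, n)
        depth = np.where(pos <= 1000, rng.poisson(200, n), rng.poisson(50, n)) + 20
        ids = pd.Index([f"s{i}" for i in range(n)])
        prob = depth / depth.sum()
        ca_idx = rng.choice(n, 300, replace=False, p=prob)
        rest = np.setdiff1d(np.arange(n), ca_idx)
        ca = pd.DataFrame({"chrom": "chr1", "pos": pos[ca_idx]}, index=ids[ca_idx])
        track = self._track()
        pairs = match_backgrounds(
            pd.Series(depth[ca_idx], index=ids[ca_idx], dtype=float),
            pd.Series(depth[rest], index=ids[rest], dtype=float),
            seed=3,
        )
        pos_of = pd.Series(pos, index=ids)
        matched = pd.DataFrame(
            {"chrom": "chr1", "pos": pos_of[[p.control_id for p in pairs]].to_numpy()}
        )
        naive = pd.DataFrame({"chrom": "chr1", "pos": pos[rest]})
        raw = state_enrichment(ca, track, naive)
        controlled = state_enrichment(ca, track, matched)
        assert raw.loc["tss", "controlled_fold"] > 1.5  # confounded
        assert controlled.loc["tss", "controlled_fold"] == pytest.approx(1.0, abs=0.35)


class TestMotif:
    def test_information_content_bounds(self):
        pwm = np.array([[0.25, 0.25, 0.25, 0.25], [1.0, 0.0, 0.0, 0.0]])
        ic = motif_information_content(pwm)
        assert ic[0] == pytest.approx(0.0)
        assert ic[1] == pytest.approx(2.0)

    def test_density_tracks_information(self, rng):
        L = 19
        conc = rng.dirichlet(np.full(4, 0.3), L)
        ic = motif_information_content(conc)
        lam = 50.0 * (ic + 0.1) / (ic + 0.1).mean()
        counts = rng.poisson(lam)
        offsets = np.repeat(np.arange(L), counts)
        got_counts, got_ic, r = motif_position_density(offsets, conc)
        assert np.array_equal(got_counts, counts)
        assert r > 0.8

    def test_strand_orientation_and_range(self):
        assert list(orient_offsets([0, 3], ["+", "-"], 10)) == [0, 6]
        with pytest.raises(ValueError):
            motif_position_density([5], np.full((3, 4), 0.25))


class TestMafComparison:
    def exact_ranksum_p(self, a, b):
        """Enumerate all group assignments of the pooled sample."""
        pooled = np.concatenate([a, b])
        ranks = pd.Series(pooled).rank().to_numpy()
        obs = ranks[: len(a)].sum()
        total = count = 0
        for comb in itertools.combinations(range(len(pooled)), len(a)):
            s = ranks[list(comb)].sum()
            total += 1
            mean = len(a) * (len(pooled) + 1) / 2
            if abs(s - mean) >= abs(obs - mean) - 1e-9:
                count += 1
        return count / total

    def test_identical_groups(self, rng):
        g = rng.random(200)
        out = maf_comparison({"a": g, "b": g.copy()}, [("a", "b")])
        assert out["pvalue"].iloc[0] > 0.9
        assert out["median_a"].iloc[0] == out["median_b"].iloc[0]

    def test_matches_exact_enumeration(self, rng):
        a = rng.random(7)
        b = rng.random(6) + 0.3
        out = maf_comparison({"a": a, "b": b}, [("a", "b")])
        assert out["pvalue"].iloc[0] == pytest.approx(self.exact_ranksum_p(a, b), abs=1e-9)

    def test_lower_median_convention(self):
        out = maf_comparison(
            {"a": np.array([0.1, 0.2, 0.3, 0.4]), "b": np.array([0.1, 0.2])}, [("a", "b")]
        )
        assert out["median_a"].iloc[0] == 0.2  # lower of the two middle values


class TestLd:
    def test_identical_and_flip_invariance(self, rng):
        dos = rng.integers(0, 3, (40, 3)) / 2
        dos[:, 1] = dos[:, 0]
        dos[:, 2] = 1.0 - dos[:, 0]
        gm = make_genotypes(dos)
        ids = list(gm.snp_ids)
        assert ld_r2(gm, ids[0], ids[1]) == pytest.approx(1.0)
        assert ld_r2(gm, ids[0], ids[2]) == pytest.approx(1.0)  # allele relabel

    def test_monomorphic_undefined(self):
        gm = make_genotypes(np.column_stack([np.zeros(10), np.arange(10) % 2 / 2]))
        ids = list(gm.snp_ids)
        assert np.isnan(ld_r2(gm, ids[0], ids[1]))

    def test_independent_snps_finite_sample_r2(self, rng):
        n_ind, n_snp = 50, 400
        dos = rng.binomial(2, 0.4, (n_ind, n_snp)) / 2
        gm = make_genotypes(dos)
        ids = list(gm.snp_ids)
        r2s = [ld_r2(gm, ids[2 * i], ids[2 * i + 1]) for i in range(n_snp // 2)]
        # E[r^2] ~ 1/n for independent sites
        assert np.nanmean(r2s) == pytest.approx(1 / n_ind, rel=0.4)

    def test_expand_strict_threshold(self, rng):
        dos = rng.integers(0, 3, (30, 4)) / 2
        dos[:, 1] = dos[:, 0]  # perfect LD with the lead
        gm = make_genotypes(dos)
        ids = list(gm.snp_ids)
        expanded = ld_expand([ids[0]], gm, r2_threshold=0.8)
        assert ids[1] in expanded and ids[0] in expanded
        # r^2 = 1 is not strictly greater than 1 -> only the lead remains
        assert ld_expand([ids[0]], gm, r2_threshold=1.0) == {ids[0]}


class TestPairedDifference:
    def test_identical_distributions(self, rng):
        x = rng.normal(0, 1, 300)
        raw, adj = paired_allelic_difference_test(x, x.copy())
        assert adj > 0.5

    def test_cap_at_one(self, rng):
        x = rng.normal(0, 1, 100)
        raw, adj = paired_allelic_difference_test(x, x + 0.01)
        if raw > 0.25:
            assert adj == 1.0

    def test_detects_location_shift(self, rng):
        x = rng.normal(0, 1, 200)
        y = rng.normal(0.5, 1, 200)
        raw, adj = paired_allelic_difference_test(x, y)
        assert adj < 0.05
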