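"""Differential expression, quadrant statistics, Lancaster combination."""

import math

import numpy as np
import pytest
from scipy import stats

from psgscan.errors import InvalidArgumentError, NormalizationError
from psgscan.expression import (
    CountMatrix,
    DeRecord,
    QuadrantTable,
    classify_quadrants,
    de_test,
    directionality_test,
    lancaster_combine,
    quadrant_fisher,
    size_factors,
)
from psgscan.simulate import CountSimSpec, simulate_counts

from _oracles import hypergeom_tail


def _matrix(counts, condition=None, species="spA"):
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    condition = condition or ["young"] * (n_samples // 2) + ["old"] * (n_samples - n_samples // 2)
    return CountMatrix(
        genes=[f"g{i}" for i in range(n_genes)],
        samples=[f"s{j}" for j in range(n_samples)],
        counts=counts,
        condition=condition,
        species=species,
    )


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self, rng):
        col = rng.integers(1, 500, size=(40, 1))
        m = _matrix(np.hstack([col, col, col, col]))
        assert np.allclose(size_factors(m), 1.0)

    def test_doubled_sample_ratio(self, rng):
        col = rng.integers(1, 500, size=(40, 1))
        m = _matrix(np.hstack([col, 2 * col, col, 2 * col]))
        f = size_factors(m)
        assert f[1] / f[0] == pytest.approx(2.0, rel=1e-9)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_permutation_equivariance(self, rng):
        counts = rng.integers(1, 500, size=(30, 4))
        f = size_factors(_matrix(counts))
        perm = [2, 0, 3, 1]
        fp = size_factors(_matrix(counts[:, perm]))
        assert np.allclose(fp, f[perm])

    def test_no_common_gene_raises(self):
        counts = np.array([[5, 0, 3, 1], [0, 4, 2, 9]])
        with pytest.raises(NormalizationError):
            size_factors(_matrix(counts))


class TestDeTest:
    def test_constant_gene_has_zero_lfc(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(200, size=(60, 8))
        counts[0] = 150  # identical in every sample
        recs = de_test(_matrix(counts))
        assert abs(recs[0].lfc) < 0.02

    def test_all_zero_gene_is_not_regulated(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(100, size=(30, 8))
        counts[5] = 0
        recs = de_test(_matrix(counts))
        assert recs[5].lfc == 0.0 and recs[5].p == 1.0 and not recs[5].regulated

    def test_null_type_one_error_calibrated(self):
        """Shuffled-condition null: empirical type-I at 0.05 in [0.02, 0.09]."""
        spec = CountSimSpec(
            n_genes=2000, regulated_fraction=0.0, psg_count=0, seed=11
        )
        ca, _, _ = simulate_counts(spec)
        recs = de_test(ca)
        p = np.array([r.p for r in recs])
        rate = float(np.mean(p < 0.05))
        assert 0.02 <= rate <= 0.09

    def test_planted_signal_sign_recovery(self):
        spec = CountSimSpec(
            n_genes=1000, regulated_fraction=0.3, psg_count=0,
            min_effect=2.0, effect_sd=0.01, dispersion=0.05, seed=12,
            samples_a=(5, 5),
        )
        ca, _, truth = simulate_counts(spec)
        recs = de_test(ca)
        planted = [(r, truth.lfc_a[r.gene]) for r in recs if abs(truth.lfc_a[r.gene]) >= 2]
        correct = sum((r.lfc > 0) == (t > 0) for r, t in planted)
        assert correct >= 0.95 * len(planted)


class TestQuadrants:
    def _de(self, gene, lfc, q):
        return DeRecord(gene=gene, lfc=lfc, p=q, q=q, regulated=q <= 0.1)

    def test_quadrant_assignment(self):
        de_a = [self._de("g1", -1.0, 0.01), self._de("g2", 1.0, 0.01),
                self._de("g3", -1.0, 0.01), self._de("g4", 2.0, 0.01)]
        de_b = [self._de("g1", 1.0, 0.02), self._de("g2", -1.0, 0.02),
                self._de("g3", -2.0, 0.02), self._de("g4", 1.0, 0.02)]
        t = classify_quadrants(de_a, de_b, psgs={"g1"})
        assert t.quadrant == {"g1": "I", "g2": "III", "g3": "II", "g4": "IV"}
        assert t.counts["I"] == {"psg": 1, "other": 0}

    def test_single_species_regulation_excluded(self):
        de_a = [self._de("g1", -1.0, 0.01)]
        de_b = [self._de("g1", 1.0, 0.5)]
        t = classify_quadrants(de_a, de_b, psgs=set())
        assert t.n_genes == 0

    def test_partition_conservation(self):
        rng = np.random.default_rng(3)
        de_a, de_b = [], []
        for i in range(300):
            de_a.append(self._de(f"g{i}", rng.normal(), float(rng.random())))
            de_b.append(self._de(f"g{i}", rng.normal(), float(rng.random())))
        t = classify_quadrants(de_a, de_b, psgs={f"g{i}" for i in range(50)})
        both = sum(1 for a, b in zip(de_a, de_b) if a.regulated and b.regulated)
        assert sum(sum(v.values()) for v in t.counts.values()) == both == t.n_genes


class TestQuadrantFisher:
    def test_three_one_table(self):
        t = QuadrantTable(
            quadrant={**{f"p{i}": "I" for i in range(3)}, "p3": "II",
                      "o0": "I", "o1": "II", "o2": "III", "o3": "IV"},
            psg={**{f"p{i}": True for i in range(4)},
                 **{f"o{i}": False for i in range(4)}},
        )
        assert quadrant_fisher(t) == pytest.approx(17 / 70, abs=1e-12)

    def test_proportional_distribution_not_enriched(self):
        quadrant, psg = {}, {}
        k = 0
        for q, (n_psg, n_other) in {"I": (2, 8), "II": (2, 8), "III": (2, 8), "IV": (2, 8)}.items():
            for _ in range(n_psg):
                quadrant[f"g{k}"], psg[f"g{k}"] = q, True; k += 1
            for _ in range(n_other):
                quadrant[f"g{k}"], psg[f"g{k}"] = q, False; k += 1
        assert quadrant_fisher(QuadrantTable(quadrant=quadrant, psg=psg)) >= 0.5

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 30))
            quadrant, psg = {}, {}
            for i in range(n):
                quadrant[f"g{i}"] = ["I", "II", "III", "IV"][rng.integers(4)]
                psg[f"g{i}"] = bool(rng.random() < 0.4)
            t = QuadrantTable(quadrant=quadrant, psg=psg)
            a = t.counts["I"]["psg"]
            K = sum(1 for v in psg.values() if v)
            nI = a + t.counts["I"]["other"]
            if K == 0 or K == n or nI == 0 or nI == n:
                continue
            expect = hypergeom_tail(a, n, K, nI)
            assert quadrant_fisher(t) == pytest.approx(expect, abs=1e-12)

    def test_degenerate_margin_warns(self):
        t = QuadrantTable(quadrant={"g": "I"}, psg={"g": True})
        with pytest.warns(UserWarning):
            assert quadrant_fisher(t) == 1.0


class TestLancaster:
    def test_equal_weights_reduce_to_fisher(self):
        p = [0.05, 0.05]
        combined = lancaster_combine(p, [2.0, 2.0])
        fisher_stat = -2 * sum(math.log(x) for x in p)
        assert fisher_stat == pytest.approx(11.9829, abs=1e-3)
        assert combined == pytest.approx(stats.chi2.sf(fisher_stat, 4), abs=1e-12)
        assert combined == pytest.approx(0.01747, abs=2e-4)

    def test_single_p_identity_for_any_weight(self):
        for w in (1.0, 2.0, 7.5):
            assert lancaster_combine([0.3], [w]) == pytest.approx(0.3, abs=1e-12)

    def test_uniform_inputs_give_uniform_output(self, rng):
        """Combining independent uniform p-values yields a uniform combined p
        (the calibration property of any valid combination rule)."""
        combined = [
            lancaster_combine(list(rng.random(5)), [2.0] * 5) for _ in range(400)
        ]
        ks = stats.kstest(combined, "uniform")
        assert ks.pvalue > 0.01

    def test_weighting_shifts_influence(self):
        # a heavily weighted small p dominates the combination
        strong = lancaster_combine([0.001, 0.5], [10.0, 2.0])
        weak = lancaster_combine([0.001, 0.5], [2.0, 10.0])
        assert strong < weak

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            assert lancaster_combine([0.0, 0.5], [2.0, 2.0]) < 1e-10

    def test_validation(self):
        with pytest.raises(InvalidArgumentError):
            lancaster_combine([0.5], [2.0, 2.0])
        with pytest.raises(InvalidArgumentError):
            lancaster_combine([0.5], [-1.0])


class TestDirectionality:
    def _de_set(self, rng, n, frac_down, psgs, psg_down_prob):
        recs = []
        for i in range(n):
            g = f"g{i}"
            if g in psgs:
                down = rng.random() < psg_down_prob
            else:
                down = rng.random() < frac_down
            lfc = -1.0 if down else 1.0
            recs.append(DeRecord(gene=g, lfc=lfc, p=0.01, q=0.01, regulated=True))
        return recs

    def test_planted_direction_detected(self, rng):
        psgs = {f"g{i}" for i in range(40)}
        de_a = self._de_set(rng, 400, 0.5, psgs, 0.9)   # PSGs down in A
        de_b = self._de_set(rng, 400, 0.5, psgs, 0.1)   # PSGs up in B
        out = directionality_test(de_a, de_b, psgs)
        assert out["p_combined"] < 0.01
        assert out["p_combined"] <= max(out["p_down_in_a"], out["p_up_in_b"])

    def test_no_regulated_psgs_gives_component_one(self, rng):
        psgs = {"absent"}
        de_a = self._de_set(rng, 100, 0.5, set(), 0.5)
        de_b = self._de_set(rng, 100, 0.5, set(), 0.5)
        out = directionality_test(de_a, de_b, psgs)
        assert out["p_down_in_a"] == 1.0 and out["p_up_in_b"] == 1.0

    def test_single_species_signal_bounded_by_components(self, rng):
        psgs = {f"g{i}" for i in range(30)}
        de_a = self._de_set(rng, 300, 0.5, psgs, 0.95)
        de_b = self._de_set(rng, 300, 0.5, psgs, 0.5)
        out = directionality_test(de_a, de_b, psgs)
        assert min(out["p_down_in_a"], out["p_up_in_b"]) / 10 < out["p_combined"]


class TestCountMatrixValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidArgumentError):
            _matrix(np.array([[-1, 2, 3, 4]]))

    def test_needs_two_samples_per_group(self):
        with pytest.raises(InvalidArgumentError):
            _matrix(np.ones((3, 3), dtype=int), condition=["young", "young", "old"])
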