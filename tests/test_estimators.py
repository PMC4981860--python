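"""Named-estimator examples, family oracles, invariances, aggregation."""

import numpy as np
import pytest

from hepatexture.estimators import (ESTIMATOR_IDS, NAMED_ESTIMATORS,
                                    EstimatorContext, aggregate_patient,
                                    compute_estimators, curvature_fields,
                                    pooled_glcm, registry_manifest)
from hepatexture.protocols import Protocol

from oracles import ORACLES

CTX01 = EstimatorContext(0.0, 1.0)


def vec(pixels, ctx=CTX01):
    return compute_estimators(np.asarray(pixels, float), ctx)


class TestNamedEstimators:
    def test_harmonic_mean_values(self):
        ctx = EstimatorContext(1.0, 4.0)
        assert vec([[1., 1.], [1., 1.]], ctx)["E3"] == pytest.approx(1.0)
        assert vec([[1., 2., 4.]], ctx)["E3"] == pytest.approx(
            3 / (1 + 0.5 + 0.25))

    def test_harmonic_mean_missing_without_guard(self):
        ctx = EstimatorContext(0.0, 4.0, harmonic_shift=False)
        v = vec([[0., 1.], [2., 3.]], ctx)
        assert "E3" in v.missing
        with pytest.raises(KeyError):
            v["E3"]

    def test_harmonic_guard_shifts_by_quantization_step(self):
        ctx = EstimatorContext(0.0, 16.0, n_levels=16)  # step = 1
        shifted = np.array([[1., 2.], [3., 4.]])
        assert vec(shifted - 1.0, ctx)["E3"] == pytest.approx(
            4 / (1 + 0.5 + 1 / 3 + 0.25))

    def test_mode_picks_most_frequent_bin(self):
        assert vec([[5., 5., 7.]], EstimatorContext(5, 7))["E6"] == 5.0

    def test_mode_tie_breaks_toward_smallest(self):
        assert vec([[3., 3.], [9., 9.]], EstimatorContext(3, 9))["E6"] == 3.0

    def test_pearson_asymmetry_values(self):
        assert vec([[1., 2., 3.]])["E22"] == pytest.approx(0.0)
        # mean 2, median 1, population sd sqrt(3)
        assert vec([[1., 1.], [1., 5.]], EstimatorContext(0, 5))["E22"] \
            == pytest.approx(np.sqrt(3.0))

    def test_constant_sample_degenerate_values(self):
        v = vec(np.full((10, 10), 0.5))
        assert v["E3"] == pytest.approx(0.5)
        for eid in ("E22", "E57", "E73", "E75"):
            assert v[eid] == pytest.approx(0.0)


class TestGLCM:
    CHECKER = np.array([[0.0, 1.0], [1.0, 0.0]])
    CTX2 = EstimatorContext(0.0, 2.0, n_levels=2)

    def test_checkerboard_horizontal_pairs(self):
        v = vec(self.CHECKER, self.CTX2)
        assert v["E52"] == pytest.approx(1.0)  # 0-degree contrast
        # pooled over 4 orientations: diagonals contribute zero contrast
        assert v["E57"] == pytest.approx(ORACLES["E57"](
            self.CHECKER.tolist(), self.CTX2))
        assert v["E57"] == pytest.approx(0.5)

    def test_constant_sample_diagonal_matrix(self):
        P = pooled_glcm(np.full((4, 4), 0.3), CTX01)
        assert P.sum() == pytest.approx(1.0)
        level = int(np.floor(0.3 * 16))
        assert P[level, level] == pytest.approx(1.0)
        v = vec(np.full((4, 4), 0.3))
        assert v["E57"] == 0.0 and v["E35"] == pytest.approx(1.0)
        assert v["E31"] == pytest.approx(level)  # degenerate marginal

    def test_pooled_matrix_is_a_probability_distribution(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            P = pooled_glcm(rng.random((9, 9)), CTX01)
            assert np.all(P >= 0)
            assert P.sum() == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_allclose(P, P.T, atol=1e-12)

    def test_column_and_row_marginals_agree_for_symmetric_matrix(self):
        rng = np.random.default_rng(1)
        v = vec(rng.random((11, 11)))
        assert v["E31"] == pytest.approx(v["E32"])

    def test_sample_smaller_than_offset_is_missing(self):
        ctx = EstimatorContext(0, 1, distance=4)
        v = vec(np.random.default_rng(2).random((3, 3)), ctx)
        assert "E57" in v.missing


class TestCurvature:
    def test_flat_surface_zero_everywhere(self):
        f = curvature_fields(np.full((8, 8), 3.0))
        for key in ("H", "K", "k1", "k2"):
            np.testing.assert_allclose(f[key], 0.0, atol=1e-12)

    def test_planar_ramp_has_zero_mean_curvature(self):
        r, c = np.meshgrid(np.arange(10), np.arange(10), indexing="ij")
        f = curvature_fields(0.3 * r + 0.7 * c)
        # edge replication bends the surface within 2 px of the border;
        # the true interior is exactly flat
        np.testing.assert_allclose(f["H"][2:-2, 2:-2], 0.0, atol=1e-10)

    def test_hemisphere_cap_matches_analytic_curvature(self):
        R = 40.0
        n = 15
        r, c = np.meshgrid(np.arange(n) - n // 2, np.arange(n) - n // 2,
                           indexing="ij")
        cap = np.sqrt(R ** 2 - r ** 2 - c ** 2)
        f = curvature_fields(cap, scale=1.0)
        centre = f["H"][5:10, 5:10]
        np.testing.assert_allclose(centre, -1.0 / R, rtol=0.01)
        np.testing.assert_allclose(f["K"][5:10, 5:10], 1.0 / R ** 2,
                                   rtol=0.02)

    def test_too_small_sample_missing(self):
        v = vec(np.random.default_rng(3).random((2, 2)))
        assert "E73" in v.missing and "E75" in v.missing


@pytest.mark.parametrize("eid", ESTIMATOR_IDS)
def test_every_estimator_matches_its_bruteforce_oracle(eid):
    """Each registry entry equals an independent loop-based implementation."""
    rng = np.random.default_rng(123)
    tol = 1e-6 if eid in {f"E{i}" for i in range(61, 81)} else 1e-9
    for _ in range(3):
        pix = rng.random((12, 12))
        got = vec(pix)[eid]
        expected = ORACLES[eid](pix.tolist(), CTX01)
        assert got == pytest.approx(expected, rel=tol, abs=tol)


class TestInvariances:
    @pytest.mark.parametrize("eid", ["E22", "E57", "E73", "E75"])
    def test_shift_invariance_away_from_window_edges(self, eid):
        # adding a constant moves every quantization level equally
        rng = np.random.default_rng(4)
        pix = 0.3 + 0.1 * rng.random((12, 12))
        shift = 4.0 / 16.0  # a whole number of quantization steps
        a = vec(pix)[eid]
        b = vec(pix + shift)[eid]
        assert a == pytest.approx(b, rel=1e-9, abs=1e-9)

    def test_vector_always_covers_84_ids(self):
        v = vec(np.random.default_rng(5).random((10, 10)))
        assert len(v.values) + len(v.missing) == 84

    def test_registry_manifest_frozen(self):
        m = registry_manifest()
        assert m["version"] == "1.0"
        assert len(m["estimators"]) == 84
        by_id = {e["id"]: e for e in m["estimators"]}
        for eid in NAMED_ESTIMATORS:
            assert by_id[eid]["published"]
        families = [e["family"] for e in m["estimators"]]
        assert families[:30] == ["first_order"] * 30
        assert families[30:60] == ["cooccurrence"] * 30
        assert families[60:80] == ["geometric"] * 20
        assert families[80:] == ["spectral"] * 4


class TestAggregation:
    def test_identical_vectors_aggregate_to_themselves(self):
        v = vec(np.random.default_rng(6).random((10, 10)))
        agg = aggregate_patient([v, v, v], Protocol.DYNAMIC)
        for eid, val in v.values.items():
            assert agg.values[eid] == pytest.approx(val)
        assert agg.n_samples == 3

    def test_mean_of_two_samples(self):
        a = vec(np.full((10, 10), 0.2))
        b = vec(np.random.default_rng(7).random((10, 10)))
        agg = aggregate_patient([a, b], Protocol.DYNAMIC)
        assert agg.values["E57"] == pytest.approx(
            (a["E57"] + b["E57"]) / 2)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        vs = [vec(rng.random((10, 10))) for _ in range(4)]
        a = aggregate_patient(vs, Protocol.SSFSE_T2)
        b = aggregate_patient(vs[::-1], Protocol.SSFSE_T2)
        for eid in a.values:
            assert a.values[eid] == pytest.approx(b.values[eid])

    def test_missing_excluded_pairwise(self):
        ctx = EstimatorContext(0.0, 4.0, harmonic_shift=False)
        with_zero = vec(np.array([[0., 1.], [2., 3.]]), ctx)  # E3 missing
        clean = vec(np.array([[1., 2.], [2., 3.]]), ctx)
        agg = aggregate_patient([with_zero, clean], Protocol.DYNAMIC)
        assert agg.values["E3"] == pytest.approx(clean["E3"])

    def test_empty_input_names_protocol(self):
        with pytest.raises(ValueError, match="DYNAMIC"):
            aggregate_patient([], Protocol.DYNAMIC)
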