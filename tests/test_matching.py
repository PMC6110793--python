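import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from benthospec.library import ReferenceSpectrum, SpectralLibrary
from benthospec.matching import (
    SpectralAngleMatcher,
    match_to_library,
    pairwise_contrast_angles,
    spectral_contrast_angle,
)


def brute_force_angle(a, b):
    """Independent oracle: plain sums and math.acos."""
    num = sum(x * y for x, y in zip(a, b))
    den = math.sqrt(sum(x * x for x in a) * sum(y * y for y in b))
    return math.degrees(math.acos(max(-1.0, min(1.0, num / den))))


class TestSpectralContrastAngle:
    def test_identical_spectra_zero_degrees(self):
        a = [0.2, 0.5, 0.9]
        assert spectral_contrast_angle(a, a) == 0.0

    def test_orthogonal_ninety_degrees(self):
        assert spectral_contrast_angle([1.0, 0.0], [0.0, 1.0]) == pytest.approx(90.0)

    def test_scale_invariance(self):
        assert spectral_contrast_angle([1, 2, 3], [2, 4, 6]) == pytest.approx(0.0, abs=1e-5)

    def test_reversed_ramp_frozen_value(self):
        # theta((1,2,3),(3,2,1)) = arccos(10/14)
        theta = spectral_contrast_angle([1, 2, 3], [3, 2, 1])
        assert theta == pytest.approx(44.415308597192976, abs=1e-9)
        assert theta == pytest.approx(brute_force_angle([1, 2, 3], [3, 2, 1]), abs=1e-9)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            spectral_contrast_angle([0.0, 0.0], [1.0, 1.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            spectral_contrast_angle([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_nonnegative_spectra_within_0_90(self):
        rng = np.random.default_rng(42)
        A = rng.uniform(0, 1, size=(10_000, 83))
        B = rng.uniform(0, 1, size=(10_000, 83))
        na, nb = np.linalg.norm(A, axis=1), np.linalg.norm(B, axis=1)
        cos = np.clip((A * B).sum(1) / (na * nb), -1, 1)
        theta = np.degrees(np.arccos(cos))
        assert theta.min() >= 0.0
        assert theta.max() <= 90.0

    @given(
        st.lists(st.floats(0.001, 100.0), min_size=3, max_size=30),
        st.lists(st.floats(0.001, 100.0), min_size=3, max_size=30),
        st.floats(0.01, 50.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_symmetry_and_scale_invariance(self, xs, ys, k):
        n = min(len(xs), len(ys))
        a, b = np.array(xs[:n]), np.array(ys[:n])
        t1 = spectral_contrast_angle(a, b)
        assert t1 == pytest.approx(spectral_contrast_angle(b, a), abs=1e-9)
        assert t1 == pytest.approx(spectral_contrast_angle(k * a, b), abs=1e-5)
        assert spectral_contrast_angle(a, a) == pytest.approx(0.0, abs=1e-5)

    def test_matches_brute_force_on_random_suite(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = rng.uniform(0.01, 2.0, size=20)
            b = rng.uniform(0.01, 2.0, size=20)
            assert spectral_contrast_angle(a, b) == pytest.approx(
                brute_force_angle(a, b), abs=1e-9
            )

    def test_pairwise_matrix_agrees_with_scalar(self, rng):
        A = rng.uniform(0.1, 1.0, size=(4, 9))
        B = rng.uniform(0.1, 1.0, size=(5, 9))
        M = pairwise_contrast_angles(A, B)
        for i in range(4):
            for j in range(5):
                assert M[i, j] == pytest.approx(spectral_contrast_angle(A[i], B[j]), abs=1e-9)


def toy_library(n_entries=4, n_bands=12, seed=3):
    rng = np.random.default_rng(seed)
    wl = 400.0 + 4.0 * np.arange(n_bands)
    lib = SpectralLibrary(wavelengths=wl)
    for i in range(n_entries):
        lib.add(
            ReferenceSpectrum(
                ooi_id=f"e{i}",
                category=f"cat{i}",
                values=rng.uniform(0.1, 1.0, n_bands),
                wavelengths=wl,
            )
        )
    return lib


class TestMatchToLibrary:
    def test_query_equal_to_entry_wins_with_zero_angle(self):
        lib = toy_library()
        entry = lib.entries[2]
        m = match_to_library(entry.values, lib, query_id="q")
        assert m.best_entry == "e2"
        assert m.best_category == "cat2"
        assert m.theta_min == pytest.approx(0.0, abs=1e-5)
        assert m.theta_min == min(m.angles.values())

    def test_single_entry_library_always_wins(self, rng):
        lib = toy_library(n_entries=1)
        m = match_to_library(rng.uniform(0.1, 1.0, 12), lib)
        assert m.best_entry == "e0"

    def test_agrees_with_brute_force_enumeration(self, rng):
        lib = toy_library(n_entries=6)
        refs = [e.values / e.values.max() for e in lib.entries]
        for _ in range(25):
            q = rng.uniform(0.05, 1.0, 12)
            m = match_to_library(q, lib)
            oracle = min(
                range(6), key=lambda i: brute_force_angle(q / q.max(), refs[i])
            )
            assert m.best_entry == f"e{oracle}"
            for i, e in enumerate(lib.entries):
                assert m.angles[e.ooi_id] == pytest.approx(
                    brute_force_angle(q / q.max(), refs[i]), abs=1e-8
                )

    def test_reject_threshold_yields_unassigned(self):
        wl = np.arange(3, dtype=float) + 400
        lib = SpectralLibrary(wavelengths=wl)
        lib.add(ReferenceSpectrum("a", "catA", np.array([1.0, 0.0, 0.0]), wl))
        m = match_to_library(np.array([0.0, 1.0, 0.0]), lib, theta_max=45.0)
        assert m.best_category == "unassigned"
        assert m.theta_min == pytest.approx(90.0)

    def test_empty_library_rejected(self):
        lib = SpectralLibrary(wavelengths=np.arange(3, dtype=float))
        with pytest.raises(ValueError, match="empty"):
            match_to_library(np.ones(3), lib)

    def test_grid_mismatch_rejected(self):
        lib = toy_library(n_bands=12)
        with pytest.raises(ValueError, match="bands"):
            match_to_library(np.ones(10), lib)

    def test_tie_warns_and_takes_first(self):
        wl = np.arange(3, dtype=float) + 400
        lib = SpectralLibrary(wavelengths=wl)
        lib.add(ReferenceSpectrum("first", "catA", np.array([1.0, 2.0, 3.0]), wl))
        lib.add(ReferenceSpectrum("second", "catB", np.array([2.0, 4.0, 6.0]), wl))
        with pytest.warns(UserWarning, match="tied"):
            m = match_to_library(np.array([0.5, 1.0, 1.5]), lib)
        assert m.best_entry == "first"


class TestSpectralAngleMatcherEstimator:
    def test_sklearn_contract(self):
        from sklearn.utils.validation import check_is_fitted
        from sklearn.exceptions import NotFittedError

        m = SpectralAngleMatcher()
        assert m.get_params() == {"theta_max": None}
        with pytest.raises(NotFittedError):
            check_is_fitted(m, "references_")
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        m.fit(X, np.array(["a", "b"]))
        assert list(m.classes_) == ["a", "b"]
        pred = m.predict(np.array([[0.9, 0.1], [0.1, 0.9]]))
        assert list(pred) == ["a", "b"]
        assert m.score(X, np.array(["a", "b"])) == 1.0
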