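"""Spectral contrast angle matching.

The spectral contrast angle between two spectra a and b is

    theta = arccos( sum_i a_i b_i / sqrt(sum_i a_i^2 * sum_i b_i^2) )

i.e. the angle between the spectra viewed as vectors. It is scale
invariant, 0 deg for spectra identical in shape, and at most 90 deg for
nonnegative spectra. An unidentified object is assigned the category of
the library entry with the smallest angle to its mean spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .library import SpectralLibrary

__all__ = [
    "spectral_contrast_angle",
    "pairwise_contrast_angles",
    "MatchResult",
    "SpectralAngleMatcher",
    "match_to_library",
]

_TIE_TOL_DEG = 1e-9


def spectral_contrast_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle in degrees between two spectra of equal length.

    The cosine is clamped to [-1, 1] before the arccos so numerically
    collinear inputs return exactly 0 (or 180) degrees.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError(f"spectra lengths differ: {a.size} vs {b.size}")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("spectral contrast angle undefined for a zero-norm spectrum")
    cos = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def pairwise_contrast_angles(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Angles in degrees between every row of A and every row of B.

    Vectorized form of :func:`spectral_contrast_angle`; returns an
    ``(len(A), len(B))`` matrix.
    """
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    if (na == 0).any() or (nb == 0).any():
        raise ValueError("spectral contrast angle undefined for a zero-norm spectrum")
    cos = np.clip((A @ B.T) / np.outer(na, nb), -1.0, 1.0)
    return np.degrees(np.arccos(cos))


@dataclass
class MatchResult:
    """Angles of one query against every library entry, plus the winner."""

    query_id: str
    angles: dict[str, float]  # entry ooi_id -> angle in degrees
    best_entry: str
    best_category: str
    theta_min: float


class SpectralAngleMatcher(ClassifierMixin, BaseEstimator):
    """Nearest-library-entry classifier under the spectral contrast angle.

    scikit-learn-style estimator: ``fit(X, y)`` stores the reference
    spectra and their categories, ``predict(X)`` assigns each query the
    category of the smallest-angle reference. With ``theta_max`` set,
    queries whose smallest angle exceeds it are labeled
    ``"unassigned"``.

    Parameters
    ----------
    theta_max : float or None
        Optional rejection threshold in degrees (default None: always
        assign).
    """

    def __init__(self, theta_max: float | None = None):
        self.theta_max = theta_max

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a nonempty (n_refs, n_bands) matrix")
        if len(y) != X.shape[0]:
            raise ValueError("X and y length mismatch")
        if (np.linalg.norm(X, axis=1) == 0).any():
            raise ValueError("reference spectra must have nonzero norm")
        self.references_ = X.copy()
        self.reference_labels_ = y.copy()
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        return self

    def angles(self, X) -> np.ndarray:
        """``(n_queries, n_refs)`` matrix of contrast angles in degrees."""
        check_is_fitted(self, "references_")
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"query has {X.shape[1]} bands, references have {self.n_features_in_}"
            )
        return pairwise_contrast_angles(X, self.references_)

    def predict(self, X):
        ang = self.angles(X)
        best = ang.argmin(axis=1)
        theta_min = ang[np.arange(len(ang)), best]
        # warn on near-exact ties; the first (library-order) entry wins
        for i in range(len(ang)):
            tied = np.flatnonzero(ang[i] <= theta_min[i] + _TIE_TOL_DEG)
            if tied.size > 1:
                warnings.warn(
                    f"query {i}: {tied.size} references tied at "
                    f"{theta_min[i]:.6f} deg; assigning the first in library order",
                    stacklevel=2,
                )
        labels = self.reference_labels_[best].astype(object)
        if self.theta_max is not None:
            labels[theta_min > self.theta_max] = "unassigned"
        return np.asarray(labels)


def match_to_library(
    query: np.ndarray,
    lib: SpectralLibrary,
    query_id: str = "query",
    theta_max: float | None = None,
) -> MatchResult:
    """Match one query spectrum against every entry of a library.

    Both query and entries are max-normalized internally for consistency
    of presentation; the angle is scale invariant, so this cannot change
    any assignment.
    """
    from .library import normalize_max

    if len(lib) == 0:
        raise ValueError("cannot match against an empty library")
    q = normalize_max(np.asarray(query, dtype=np.float64))
    if q.size != lib.wavelengths.size:
        raise ValueError(
            f"query has {q.size} bands, library grid has {lib.wavelengths.size}"
        )
    matcher = SpectralAngleMatcher(theta_max=theta_max)
    refs = np.vstack([normalize_max(e.values) for e in lib.entries])
    matcher.fit(refs, np.array([e.ooi_id for e in lib.entries]))
    ang = matcher.angles(q[np.newaxis, :])[0]
    best = int(ang.argmin())
    tied = np.flatnonzero(ang <= ang[best] + _TIE_TOL_DEG)
    if tied.size > 1:
        warnings.warn(
            f"{query_id}: {tied.size} library entries tied at {ang[best]:.6f} deg; "
            "assigning the first in library order",
            stacklevel=2,
        )
    theta_min = float(ang[best])
    category = lib.entries[best].category
    if theta_max is not None and theta_min > theta_max:
        category = "unassigned"
    return MatchResult(
        query_id=query_id,
        angles={e.ooi_id: float(t) for e, t in zip(lib.entries, ang)},
        best_entry=lib.entries[best].ooi_id,
        best_category=category,
        theta_min=theta_min,
    )
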