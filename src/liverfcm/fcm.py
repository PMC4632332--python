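"""Fuzzy c-means clustering of liver ROI pixels into vessel and parenchyma.

Standard Bezdek fuzzy c-means (no gain-field correction): minimise

    J_m(u, v) = sum_i sum_j u_ij^m * ||x_j - v_i||^2
    subject to sum_i u_ij = 1, u_ij in [0, 1]

by alternating membership and centroid updates.  Here C = 2 clusters
(vessel / parenchyma) and the fuzzifier m defaults to 2.  Features are
either the pixel intensity of one echo image alone (1D mode) or that
intensity paired with the pixel's LIC value (2D mode); each feature is
min-max normalised to [0, 1] over the ROI so both axes carry equal weight
in the Euclidean distance.

Hard labels are obtained by thresholding the vessel-cluster membership at a
defuzzification threshold u0: a pixel is vessel iff u_vessel >= u0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateClusteringError,
    DegenerateFeatureError,
    InputError,
)
from .relaxometry import MultiEchoStack, ScalarMap

__all__ = [
    "FeatureMatrix",
    "FCMParams",
    "FCMResult",
    "SegmentationMask",
    "build_features",
    "fcm_cluster",
    "identify_vessel_cluster",
    "defuzzify",
]

_ZERO_DIST = 1e-12


@dataclass
class FeatureMatrix:
    """Clustering input: a k x n matrix of per-pixel feature vectors.

    ``x[0]`` is the min-max-normalised intensity of echo ``te_index``;
    in 2D mode ``x[1]`` is the normalised LIC value.  ``pixel_index`` maps
    column j to its flat index into the image; ROI pixels dropped because
    their LIC fit was invalid are recorded in ``excluded_index``.
    """

    x: np.ndarray  # (k, n), each row in [0, 1]
    pixel_index: np.ndarray  # (n,) flat indices into the image
    mode: str  # "1D" | "2D"
    te_index: int
    shape: tuple[int, int]
    excluded_index: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n(self) -> int:
        return self.x.shape[1]

    @property
    def k(self) -> int:
        return self.x.shape[0]


@dataclass(frozen=True)
class FCMParams:
    """FCM hyper-parameters.  Initialisation is deterministic (centroids at
    the 10th and 90th percentile of each feature), so a run is fully
    reproducible; convergence is max centroid displacement < tol."""

    n_clusters: int = 2
    m: float = 2.0
    tol: float = 1e-6
    max_iter: int = 300

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise InputError("n_clusters must be >= 2")
        if self.m <= 1:
            raise InputError("fuzzifier m must be > 1")
        if self.tol <= 0:
            raise InputError("tol must be > 0")


@dataclass
class FCMResult:
    memberships: np.ndarray  # (C, n), columns sum to 1
    centroids: np.ndarray  # (C, k)
    objective_trace: np.ndarray  # J_m per iteration
    iterations: int
    converged: bool


@dataclass
class SegmentationMask:
    """Hard vessel/parenchyma labels over an image; pixels outside the ROI
    are OUTSIDE.  Encoded 0 outside / 1 parenchyma / 2 vessel."""

    OUTSIDE = 0
    PARENCHYMA = 1
    VESSEL = 2

    labels: np.ndarray
    threshold: float | None = None
    source: str = "manual"

    @classmethod
    def from_vessel_mask(cls, vessel: np.ndarray, roi: np.ndarray, *,
                         threshold: float | None = None,
                         source: str = "manual") -> "SegmentationMask":
        vessel = np.asarray(vessel, dtype=bool)
        roi = np.asarray(roi, dtype=bool)
        if vessel.shape != roi.shape:
            raise InputError("vessel mask and ROI shapes differ")
        if np.any(vessel & ~roi):
            raise InputError("vessel mask extends outside the ROI")
        labels = np.zeros(roi.shape, dtype=np.uint8)
        labels[roi] = cls.PARENCHYMA
        labels[vessel] = cls.VESSEL
        return cls(labels=labels, threshold=threshold, source=source)

    @property
    def roi(self) -> np.ndarray:
        return self.labels != self.OUTSIDE

    @property
    def vessel(self) -> np.ndarray:
        return self.labels == self.VESSEL

    @property
    def parenchyma(self) -> np.ndarray:
        return self.labels == self.PARENCHYMA


def _minmax(values: np.ndarray, what: str) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        raise DegenerateFeatureError(f"{what} is constant over the ROI")
    return (values - lo) / (hi - lo)


def build_features(stack: MultiEchoStack, lic: ScalarMap | None, roi: np.ndarray,
                   mode: str, te_index: int) -> FeatureMatrix:
    """Assemble the 1D (intensity) or 2D (intensity + LIC) feature matrix for
    the ROI pixels of one echo image.

    In 2D mode, ROI pixels whose LIC fit is invalid are excluded from the
    matrix (and recorded), since they have no LIC coordinate.
    """
    if mode not in ("1D", "2D"):
        raise InputError(f"mode must be '1D' or '2D', got {mode!r}")
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != stack.shape:
        raise InputError(f"ROI shape {roi.shape} != stack shape {stack.shape}")
    if not 0 <= te_index < stack.n_echoes:
        raise InputError(f"te_index {te_index} out of range [0, {stack.n_echoes})")
    if mode == "2D" and lic is None:
        raise InputError("2D mode requires an LIC map")

    flat_roi = np.nonzero(roi.ravel())[0]
    intensity = stack.echoes[te_index].ravel()[flat_roi]
    excluded = np.empty(0, dtype=int)
    if mode == "1D":
        x = _minmax(intensity, f"echo {te_index} intensity")[None, :]
        idx = flat_roi
    else:
        lic_ok = lic.valid_mask.ravel()[flat_roi]
        excluded = flat_roi[~lic_ok]
        idx = flat_roi[lic_ok]
        if idx.size == 0:
            raise DegenerateFeatureError("no ROI pixel has a valid LIC value")
        x = np.stack([
            _minmax(intensity[lic_ok], f"echo {te_index} intensity"),
            _minmax(lic.values.ravel()[idx], "LIC"),
        ])
    return FeatureMatrix(x=x, pixel_index=idx, mode=mode, te_index=te_index,
                         shape=stack.shape, excluded_index=excluded)


def _memberships(x: np.ndarray, v: np.ndarray, m: float) -> tuple[np.ndarray, np.ndarray]:
    """Membership update: u_ij = 1 / sum_l (d_ij / d_lj)^(2/(m-1)).
    A point coinciding with a centroid gets crisp membership there."""
    d2 = ((x[None, :, :] - v[:, None, :]) ** 2).sum(axis=2)  # (C, n)
    zero = d2 < _ZERO_DIST
    d2_safe = np.where(zero, _ZERO_DIST, d2)
    inv = d2_safe ** (-1.0 / (m - 1.0))
    u = inv / inv.sum(axis=0, keepdims=True)
    hit = zero.any(axis=0)
    if hit.any():
        u[:, hit] = zero[:, hit] / zero[:, hit].sum(axis=0, keepdims=True)
    return u, d2


def fcm_cluster(features: FeatureMatrix, params: FCMParams = FCMParams()) -> FCMResult:
    """Run fuzzy c-means on a feature matrix.

    Alternates Bezdek updates — memberships from inverse squared Euclidean
    distances, centroids as u^m-weighted means — until the largest centroid
    displacement falls below ``params.tol`` or ``params.max_iter`` is hit.
    Deterministic for a given input.
    """
    x = features.x.T  # (n, k)
    n, k = x.shape
    C, m = params.n_clusters, params.m
    if n < C:
        raise InputError(f"need at least {C} points, got {n}")

    # deterministic init: centroids at per-feature percentiles spread over [10, 90]
    qs = np.linspace(10, 90, C)
    v = np.stack([np.percentile(x, q, axis=0) for q in qs])  # (C, k)

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        u, _ = _memberships(x, v, m)
        um = u ** m
        v_new = (um @ x) / um.sum(axis=1, keepdims=True)
        _, d2 = _memberships(x, v_new, m)
        trace.append(float((um * d2).sum()))
        shift = np.abs(v_new - v).max()
        v = v_new
        if shift < params.tol:
            converged = True
            break
    u, _ = _memberships(x, v, m)  # memberships consistent with final centroids
    return FCMResult(memberships=u, centroids=v,
                     objective_trace=np.asarray(trace), iterations=it,
                     converged=converged)


def identify_vessel_cluster(result: FCMResult, features: FeatureMatrix) -> int:
    """Decide which cluster is the vessel class.

    2D mode: vessels carry little iron, so the vessel cluster is the one
    with the lower LIC-feature centroid.  1D mode: vessel blood retains
    signal while iron-loaded parenchyma decays, so the vessel cluster is the
    brighter one.
    """
    v = result.centroids
    if features.mode == "2D":
        axis, pick = 1, np.argmin
    else:
        axis, pick = 0, np.argmax
    if v[0, axis] == v[1, axis]:
        raise DegenerateClusteringError("clusters have identical centroids")
    return int(pick(v[:, axis]))


def defuzzify(result: FCMResult, vessel_idx: int, u0: float, roi: np.ndarray,
              features: FeatureMatrix, *, source: str | None = None) -> SegmentationMask:
    """Threshold the vessel-cluster membership into a hard label map.

    A clustered pixel is labelled vessel iff its vessel membership >= u0
    (ties go to vessel); every other ROI pixel — including pixels excluded
    from clustering for lack of a valid LIC fit — is parenchyma.
    """
    if not 0.0 <= u0 < 1.0:
        raise InputError(f"u0 must be in [0, 1), got {u0}")
    roi = np.asarray(roi, dtype=bool)
    u_vessel = result.memberships[vessel_idx]
    vessel = np.zeros(roi.shape, dtype=bool).ravel()
    vessel[features.pixel_index[u_vessel >= u0]] = True
    return SegmentationMask.from_vessel_mask(
        vessel.reshape(roi.shape), roi, threshold=u0,
        source=source or f"{features.mode}-FCM")
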