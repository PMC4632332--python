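"""Parameter-selection schemes for FCM vessel segmentation.

Clustering outcomes depend on two free parameters: which echo image feeds
the intensity feature (the TE input) and the defuzzification threshold u0.
Two selection schemes are provided:

* **OP (optimal)** — exhaustive search: every TE paired with every
  threshold of the 50-level grid {0, 0.02, ..., 0.98} is clustered,
  defuzzified and scored by D_TSA against a manual reference mask; with
  the default 20-echo protocol this enumerates 1000 candidates per FCM
  mode.  The best candidate per mode is the D_TSA minimiser (ties broken
  toward lower TE, then lower u0), and MIX takes the better of the 1D and
  2D winners.  OP is defined only relative to a reference segmentation and
  serves as the accuracy ceiling.

* **SA (semi-automatic)** — the TE input is chosen automatically as the
  echo maximising the signal-range-to-noise ratio
  RNR = (max - min of ROI intensities) / noise SD, and only the 50
  threshold gallery per mode is left to the user.  For unattended runs a
  ``reference-auto`` selection emulates the user by picking the
  minimum-D_TSA gallery entry.

Since SA explores a subset of OP's grid, SA's error can never beat OP's on
the same study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateClusteringError,
    DegenerateFeatureError,
    InputError,
    NoiseEstimationError,
)
from .fcm import (
    FCMParams,
    FeatureMatrix,
    FCMResult,
    SegmentationMask,
    build_features,
    defuzzify,
    fcm_cluster,
    identify_vessel_cluster,
)
from .metrics import d_tsa as _d_tsa_fn
from .relaxometry import MultiEchoStack, ScalarMap

__all__ = [
    "default_threshold_grid",
    "OPGrid",
    "SchemeOutcome",
    "RNRProfile",
    "OPResult",
    "SAResult",
    "compute_rnr",
    "select_te_rnr_max",
    "op_search",
    "sa_run",
    "sa_choose",
]


def default_threshold_grid() -> np.ndarray:
    """The 50 defuzzification thresholds {0, 0.02, ..., 0.98}."""
    return np.round(np.arange(50) * 0.02, 10)


@dataclass(frozen=True)
class OPGrid:
    """The exhaustive OP search grid: TE indices x defuzzification
    thresholds (default: all echoes x 50 thresholds)."""

    te_indices: tuple[int, ...] | None = None  # None -> all echoes
    thresholds: np.ndarray = field(default_factory=default_threshold_grid)

    def resolve_tes(self, stack: MultiEchoStack) -> tuple[int, ...]:
        if self.te_indices is None:
            return tuple(range(stack.n_echoes))
        if any(not 0 <= t < stack.n_echoes for t in self.te_indices):
            raise InputError("te_indices out of range for this stack")
        return tuple(self.te_indices)


@dataclass
class SchemeOutcome:
    """One candidate (or selected) segmentation with its provenance and,
    when a reference was available, its accuracy scores."""

    method: str  # "1D-FCM" | "2D-FCM" | "MIX-FCM"
    scheme: str  # "OP" | "SA"
    te_index: int
    te_ms: float
    u0: float
    mask: SegmentationMask
    tsa_parenchyma_pct: float | None = None
    tsa_vessels_pct: float | None = None
    d_tsa_pct: float | None = None
    selected_from: str | None = None  # for MIX: which component won


@dataclass
class RNRProfile:
    """Per-echo signal-range-to-noise ratio and its maximiser."""

    rnr: np.ndarray
    noise_sd: np.ndarray
    argmax_te: int


@dataclass
class OPResult:
    best_1d: SchemeOutcome
    best_2d: SchemeOutcome
    mix: SchemeOutcome
    candidates: pd.DataFrame  # one row per (mode, te, u0) candidate
    n_candidates: dict

    @property
    def best(self) -> dict:
        return {"1D-FCM": self.best_1d, "2D-FCM": self.best_2d, "MIX-FCM": self.mix}


@dataclass
class SAResult:
    profile: RNRProfile
    te_index: int
    candidates_1d: list
    candidates_2d: list
    chosen: SchemeOutcome | None
    thresholds: np.ndarray


def _corner_patch_sd(stack: MultiEchoStack, patch: int = 8) -> np.ndarray:
    """Pooled SD of the four corner patches of each echo image, assumed to
    contain background (air) only."""
    rows, cols = stack.shape
    p = min(patch, rows // 2, cols // 2)
    sds = []
    for img in stack.echoes:
        corners = np.concatenate([
            img[:p, :p].ravel(), img[:p, -p:].ravel(),
            img[-p:, :p].ravel(), img[-p:, -p:].ravel(),
        ])
        sds.append(corners.std(ddof=1))
    return np.asarray(sds)


def compute_rnr(stack: MultiEchoStack, roi: np.ndarray,
                noise_estimator="corner-patches") -> RNRProfile:
    """Signal-range-to-noise ratio per echo:
    RNR[e] = (max - min of echo e inside the ROI) / noise SD of echo e.

    ``noise_estimator`` is the strategy for the per-echo noise SD: the
    default background corner-patch estimate, an explicit per-echo array
    (or scalar), or a callable ``stack -> array``.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != stack.shape:
        raise InputError(f"ROI shape {roi.shape} != stack shape {stack.shape}")
    if not roi.any():
        raise InputError("ROI is empty")
    if callable(noise_estimator):
        sd = np.asarray(noise_estimator(stack), dtype=float)
    elif isinstance(noise_estimator, str):
        if noise_estimator != "corner-patches":
            raise InputError(f"unknown noise estimator {noise_estimator!r}")
        sd = _corner_patch_sd(stack)
    else:
        sd = np.broadcast_to(np.asarray(noise_estimator, dtype=float),
                             (stack.n_echoes,)).copy()
    if sd.shape != (stack.n_echoes,):
        raise InputError("noise SD must be one value per echo")
    if np.any(sd <= 0) or not np.all(np.isfinite(sd)):
        raise NoiseEstimationError("noise SD must be positive and finite for every echo")
    inside = stack.echoes[:, roi]
    rnr = (inside.max(axis=1) - inside.min(axis=1)) / sd
    return RNRProfile(rnr=rnr, noise_sd=sd, argmax_te=int(np.argmax(rnr)))


def select_te_rnr_max(profile: RNRProfile) -> int:
    """TE index with maximum RNR; earliest index on ties (np.argmax)."""
    return int(np.argmax(profile.rnr))


def _score_thresholds(u_vessel: np.ndarray, clustered_ref_vessel: np.ndarray,
                      n_ref_vessel: int, n_ref_parenchyma: int, n_roi: int,
                      thresholds: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised TSA/D_TSA over the threshold grid for one clustering run.

    Pixels excluded from clustering are labelled parenchyma at every
    threshold, which the count algebra below accounts for implicitly.
    """
    pred = u_vessel[None, :] >= thresholds[:, None]  # (T, n)
    n_pred_ves = pred.sum(axis=1)
    tp_ves = (pred & clustered_ref_vessel[None, :]).sum(axis=1)
    fp_ves = n_pred_ves - tp_ves  # predicted vessel but reference parenchyma

    denom_v = n_pred_ves + n_ref_vessel
    tsa_ves = np.where(denom_v > 0, 2.0 * tp_ves * 100.0 / np.maximum(denom_v, 1), 100.0)

    n_pred_par = n_roi - n_pred_ves
    tp_par = n_ref_parenchyma - fp_ves
    denom_p = n_pred_par + n_ref_parenchyma
    tsa_par = np.where(denom_p > 0, 2.0 * tp_par * 100.0 / np.maximum(denom_p, 1), 100.0)
    dt = np.hypot(100.0 - tsa_par, 100.0 - tsa_ves)
    return tsa_par, tsa_ves, dt


def _cluster_once(stack: MultiEchoStack, lic: ScalarMap | None, roi: np.ndarray,
                  mode: str, te_index: int, params: FCMParams
                  ) -> tuple[FeatureMatrix, FCMResult, int]:
    features = build_features(stack, lic, roi, mode, te_index)
    result = fcm_cluster(features, params)
    vessel_idx = identify_vessel_cluster(result, features)
    return features, result, vessel_idx


def op_search(stack: MultiEchoStack, lic: ScalarMap, roi: np.ndarray,
              reference: SegmentationMask, grid: OPGrid | None = None,
              fcm_params: FCMParams = FCMParams()) -> OPResult:
    """Exhaustive OP search over (mode, TE, threshold) scored against a
    manual reference; refuses to run without one (OP is defined relative to
    manual segmentation).

    TEs whose features are degenerate contribute unscored (skipped) rows so
    the enumeration count is preserved; they cannot win.
    """
    if reference is None:
        raise InputError("OP search requires a reference segmentation")
    grid = grid or OPGrid()
    roi = np.asarray(roi, dtype=bool)
    te_indices = grid.resolve_tes(stack)
    thresholds = np.asarray(grid.thresholds, dtype=float)
    n_roi = int(roi.sum())
    ref_vessel_flat = reference.vessel.ravel()
    n_ref_ves = int(reference.vessel.sum())
    n_ref_par = int(reference.parenchyma.sum())

    rows = []
    best: dict[str, tuple] = {}
    n_candidates: dict[str, int] = {}
    for mode in ("1D", "2D"):
        method = f"{mode}-FCM"
        best_key = None  # (d_tsa,) with iteration order giving te/u0 tie-break
        best_ctx = None
        count = 0
        for te in te_indices:
            try:
                features, result, vessel_idx = _cluster_once(
                    stack, lic if mode == "2D" else None, roi, mode, te, fcm_params)
            except (DegenerateFeatureError, DegenerateClusteringError) as exc:
                for u0 in thresholds:
                    rows.append((method, te, float(stack.te_ms[te]), float(u0),
                                 np.nan, np.nan, np.nan, str(exc)))
                count += len(thresholds)
                continue
            u_vessel = result.memberships[vessel_idx]
            crv = ref_vessel_flat[features.pixel_index]
            tsa_par, tsa_ves, dt = _score_thresholds(
                u_vessel, crv, n_ref_ves, n_ref_par, n_roi, thresholds)
            for j, u0 in enumerate(thresholds):
                rows.append((method, te, float(stack.te_ms[te]), float(u0),
                             tsa_par[j], tsa_ves[j], dt[j], ""))
                count += 1
                if best_key is None or dt[j] < best_key:
                    best_key = dt[j]
                    best_ctx = (te, float(u0), features, result, vessel_idx,
                                tsa_par[j], tsa_ves[j], dt[j])
        if best_ctx is None:
            raise DegenerateFeatureError(f"no scorable {method} candidate")
        n_candidates[method] = count
        te, u0, features, result, vessel_idx, tp, tv, dt_best = best_ctx
        mask = defuzzify(result, vessel_idx, u0, roi, features, source=method)
        best[method] = SchemeOutcome(
            method=method, scheme="OP", te_index=te, te_ms=float(stack.te_ms[te]),
            u0=u0, mask=mask, tsa_parenchyma_pct=float(tp),
            tsa_vessels_pct=float(tv), d_tsa_pct=float(dt_best))

    b1, b2 = best["1D-FCM"], best["2D-FCM"]
    winner = b1 if b1.d_tsa_pct <= b2.d_tsa_pct else b2
    mix = SchemeOutcome(
        method="MIX-FCM", scheme="OP", te_index=winner.te_index, te_ms=winner.te_ms,
        u0=winner.u0, mask=winner.mask, tsa_parenchyma_pct=winner.tsa_parenchyma_pct,
        tsa_vessels_pct=winner.tsa_vessels_pct, d_tsa_pct=winner.d_tsa_pct,
        selected_from=winner.method)
    candidates = pd.DataFrame(
        rows, columns=["method", "te_index", "te_ms", "u0", "tsa_parenchyma_pct",
                       "tsa_vessels_pct", "d_tsa_pct", "note"])
    return OPResult(best_1d=b1, best_2d=b2, mix=mix, candidates=candidates,
                    n_candidates=n_candidates)


def sa_run(stack: MultiEchoStack, lic: ScalarMap, roi: np.ndarray,
           thresholds: np.ndarray | None = None,
           reference: SegmentationMask | None = None,
           selection: str = "interactive-export",
           noise_estimator="corner-patches",
           fcm_params: FCMParams = FCMParams()) -> SAResult:
    """Semi-automatic scheme: TE fixed at the RNR maximum, then a
    50-threshold candidate gallery per FCM mode.

    ``selection="reference-auto"`` emulates the user by choosing the
    minimum-D_TSA entry over both galleries (requires a reference);
    ``"interactive-export"`` leaves the choice to the caller (see
    :func:`sa_choose`).
    """
    if selection not in ("interactive-export", "reference-auto"):
        raise InputError(f"unknown selection {selection!r}")
    if selection == "reference-auto" and reference is None:
        raise InputError("reference-auto selection requires a reference mask")
    roi = np.asarray(roi, dtype=bool)
    thresholds = (default_threshold_grid() if thresholds is None
                  else np.asarray(thresholds, dtype=float))
    profile = compute_rnr(stack, roi, noise_estimator)
    te = select_te_rnr_max(profile)

    n_roi = int(roi.sum())
    galleries: dict[str, list] = {}
    for mode in ("1D", "2D"):
        method = f"{mode}-FCM"
        outcomes: list[SchemeOutcome] = []
        features, result, vessel_idx = _cluster_once(
            stack, lic if mode == "2D" else None, roi, mode, te, fcm_params)
        if reference is not None:
            crv = reference.vessel.ravel()[features.pixel_index]
            tsa_par, tsa_ves, dt = _score_thresholds(
                result.memberships[vessel_idx], crv, int(reference.vessel.sum()),
                int(reference.parenchyma.sum()), n_roi, thresholds)
        for j, u0 in enumerate(thresholds):
            mask = defuzzify(result, vessel_idx, float(u0), roi, features, source=method)
            outcomes.append(SchemeOutcome(
                method=method, scheme="SA", te_index=te,
                te_ms=float(stack.te_ms[te]), u0=float(u0), mask=mask,
                tsa_parenchyma_pct=float(tsa_par[j]) if reference is not None else None,
                tsa_vessels_pct=float(tsa_ves[j]) if reference is not None else None,
                d_tsa_pct=float(dt[j]) if reference is not None else None))
        galleries[mode] = outcomes

    chosen = None
    if selection == "reference-auto":
        pool = galleries["1D"] + galleries["2D"]
        winner = min(pool, key=lambda o: o.d_tsa_pct)
        chosen = SchemeOutcome(
            method="MIX-FCM", scheme="SA", te_index=winner.te_index,
            te_ms=winner.te_ms, u0=winner.u0, mask=winner.mask,
            tsa_parenchyma_pct=winner.tsa_parenchyma_pct,
            tsa_vessels_pct=winner.tsa_vessels_pct, d_tsa_pct=winner.d_tsa_pct,
            selected_from=winner.method)
    return SAResult(profile=profile, te_index=te, candidates_1d=galleries["1D"],
                    candidates_2d=galleries["2D"], chosen=chosen,
                    thresholds=thresholds)


def sa_choose(result: SAResult, mode: str, index: int) -> SchemeOutcome:
    """Resolve a user's gallery pick ``MODE:INDEX`` into the SA-MIX outcome."""
    gallery = {"1D": result.candidates_1d, "2D": result.candidates_2d}.get(mode)
    if gallery is None:
        raise InputError(f"mode must be '1D' or '2D', got {mode!r}")
    if not 0 <= index < len(gallery):
        raise InputError(f"index {index} out of range for {len(gallery)} candidates")
    winner = gallery[index]
    return SchemeOutcome(
        method="MIX-FCM", scheme="SA", te_index=winner.te_index, te_ms=winner.te_ms,
        u0=winner.u0, mask=winner.mask,
        tsa_parenchyma_pct=winner.tsa_parenchyma_pct,
        tsa_vessels_pct=winner.tsa_vessels_pct, d_tsa_pct=winner.d_tsa_pct,
        selected_from=winner.method)
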