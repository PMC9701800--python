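"""Necrosis thresholding, Dice similarity, SEM and robustness harness.

The simulated heat volume is converted to a binary coagulation-necrosis
mask by thresholding in the [50, 60] °C range.  Two threshold modes exist:

* **global** — one threshold per phantom, chosen in [50, 60] °C (0.5 °C
  steps) to maximise the 3D Dice against the reference mask;
* **median** — for each acquisition orientation the threshold maximising
  the 2D Dice between the thresholded simulated slice and the thresholded
  measured map is found, and the median of the per-orientation thresholds
  is applied to the volume.

Similarity is the Dice score DSC = 2 TP / (2 TP + FP + FN); uncertainty is
reported as the sample standard deviation and the standard error of the
mean at 95% confidence, SEM = sigma / sqrt(N) * 1.96.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NecrosisMask",
    "RobustnessConfig",
    "ROBUSTNESS_CONFIGS",
    "necrosis_mask",
    "median_threshold",
    "dice",
    "sem",
    "best_threshold",
    "robustness_run",
]

THRESHOLD_RANGE = (50.0, 60.0)
THRESHOLD_STEP = 0.5


@dataclass
class NecrosisMask:
    """Binary coagulation volume obtained by temperature thresholding."""

    mask: np.ndarray
    threshold: float
    mode: str = "global"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)

    @property
    def volume_voxels(self) -> int:
        return int(self.mask.sum())


def necrosis_mask(volume, threshold: float, mode: str = "global") -> NecrosisMask:
    """Threshold a temperature field: necrotic where T >= threshold (°C)."""
    vol = np.asarray(volume, float)
    if not np.all(np.isfinite(vol)):
        raise FloatingPointError("non-finite temperature volume")
    lo, hi = THRESHOLD_RANGE
    if mode == "global" and not (lo <= threshold <= hi):
        warnings.warn(
            f"coagulation threshold {threshold} °C outside the usual "
            f"[{lo}, {hi}] °C range", stacklevel=2,
        )
    return NecrosisMask(mask=vol >= threshold, threshold=float(threshold),
                        mode=mode)


def median_threshold(per_orientation_best) -> float:
    """Median of the per-orientation best thresholds (even count: midpoint)."""
    vals = np.asarray(per_orientation_best, float)
    if vals.size == 0:
        raise ValueError("need at least one threshold")
    return float(np.median(vals))


def dice(a, b) -> float:
    """Dice score 2 TP / (2 TP + FP + FN); 1.0 when both masks are empty."""
    ma = a.mask if isinstance(a, NecrosisMask) else np.asarray(a, bool)
    mb = b.mask if isinstance(b, NecrosisMask) else np.asarray(b, bool)
    if ma.shape != mb.shape:
        raise ValueError("masks must have the same shape")
    tp = np.count_nonzero(ma & mb)
    fp = np.count_nonzero(~ma & mb)
    fn = np.count_nonzero(ma & ~mb)
    denom = 2 * tp + fp + fn
    if denom == 0:
        return 1.0
    return 2.0 * tp / denom


def sem(samples) -> tuple[float, float]:
    """Sample standard deviation and 95% standard error of the mean.

    Returns ``(sigma, sigma / sqrt(N) * 1.96)`` with the n-1 denominator.
    """
    x = np.asarray(samples, float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two samples")
    sigma = float(np.sqrt(np.sum((x - x.mean()) ** 2) / (n - 1)))
    return sigma, sigma / np.sqrt(n) * 1.96


# ---------------------------------------------------------------------------
# robustness harness

@dataclass
class RobustnessConfig:
    """One evaluation configuration: orientation subset or parameter change."""

    id: str
    orientation_subset: list[float] | None = None  # degrees; None = all
    param_overrides: dict = field(default_factory=dict)
    threshold_mode: str = "global"


#: the acquisition/optimisation variations exercised in the robustness study
ROBUSTNESS_CONFIGS: dict[str, RobustnessConfig] = {
    "reference": RobustnessConfig("reference"),
    "1": RobustnessConfig("1", orientation_subset=[0.0, 22.5, 45.0, 67.5]),
    "2": RobustnessConfig("2", orientation_subset=[90.0, 112.5, 135.0, 157.5]),
    "3": RobustnessConfig("3", orientation_subset=[0.0, 22.5]),
    "4": RobustnessConfig("4", orientation_subset=[90.0]),
    "5": RobustnessConfig("5", orientation_subset=[22.5]),
    "6": RobustnessConfig("6", param_overrides={
        "bounds_D": (0.1, 1000.0), "bounds_Tmax": (0.1, 1000.0)}),
    "7": RobustnessConfig("7", param_overrides={
        "initial_D": 10.0, "initial_Tmax": 500.0}),
}


def best_threshold(sim_volume, ref_mask, step: float = THRESHOLD_STEP) -> float:
    """Threshold in [50, 60] °C maximising Dice against a reference mask."""
    lo, hi = THRESHOLD_RANGE
    taus = np.arange(lo, hi + step / 2, step)
    scores = [dice(necrosis_mask(sim_volume, t).mask, ref_mask) for t in taus]
    return float(taus[int(np.argmax(scores))])


def _per_orientation_thresholds(estimator, series) -> list[float]:
    """Best 2D threshold per orientation (last acquired map of each angle)."""
    from .geometry import sample_volume, slice_to_world

    latest: dict[float, object] = {}
    for m in series:
        latest[m.frame.angle] = m
    taus = []
    lo, hi = THRESHOLD_RANGE
    grid_taus = np.arange(lo, hi + THRESHOLD_STEP / 2, THRESHOLD_STEP)
    for angle in sorted(latest):
        m = latest[angle]
        nr, nc = m.values.shape
        rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
        px = np.stack([rows.ravel(), cols.ravel()], axis=1).astype(float)
        pts = slice_to_world(m.frame, px)
        sim, _ = sample_volume(estimator.volume_, pts,
                               boundary_value=estimator.state_.boundary_T)
        sim = sim.reshape(nr, nc)
        valid = m.valid_mask
        scores = [
            dice((sim >= t) & valid, (m.values >= t) & valid)
            for t in grid_taus
        ]
        taus.append(float(grid_taus[int(np.argmax(scores))]))
    return taus


def robustness_run(
    series,
    ground_truth,
    config: RobustnessConfig,
    estimator_kwargs: dict | None = None,
    phantom_id: str = "phantom",
) -> pd.DataFrame:
    """Run the full adaptive pipeline under one robustness configuration.

    Filters the series to the orientation subset, applies parameter
    overrides, fits, and evaluates Dice against the ground-truth necrosis
    under the configured threshold mode.
    """
    from .inverse import AdaptiveBioheatEstimator

    kwargs = dict(estimator_kwargs or {})
    kwargs.update(config.param_overrides)
    if config.orientation_subset is not None:
        if len(config.orientation_subset) == 0:
            raise ValueError("orientation subset must not be empty")
        keep = set(config.orientation_subset)
        sub = [m for m in series
               if any(abs(m.frame.angle - a) < 1e-6 for a in keep)]
        if not sub:
            raise ValueError("orientation subset matches no acquired image")
    else:
        sub = list(series)
    est = AdaptiveBioheatEstimator(**kwargs).fit(sub)
    truth_mask = ground_truth.necrosis_on(est.volume_)
    if config.threshold_mode == "median":
        taus = _per_orientation_thresholds(est, sub)
        tau = median_threshold(taus)
    else:
        tau = best_threshold(est.volume_.field, truth_mask)
    score = dice(necrosis_mask(est.volume_.field, tau,
                               mode=config.threshold_mode).mask, truth_mask)
    return pd.DataFrame([{
        "phantom": phantom_id,
        "config": config.id,
        "threshold_mode": config.threshold_mode,
        "threshold": tau,
        "dice": score,
        "D": est.D_,
        "T_max": est.T_max_,
        "n_images": est.n_images_,
    }])
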