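"""Minimum-mapping-unit accuracy assessment and summary metrics.

Validation follows a 3 m-radius minimum mapping unit (MMU): a species is
scored as predicted-present at a plot if any presence pixel center falls
within 3 m of the plot coordinate. The confusion matrix feeds overall
accuracy, sensitivity/specificity (and their complements), Cohen's kappa
and the true skill statistic TSS = sensitivity + specificity - 1, which
is independent of prevalence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .detection import SpeciesMap
from .synthetic_scene import PlotRecord

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "mmu_evaluate",
    "metrics",
    "uncertainty_at_plots",
]

MMU_RADIUS_M = 3.0


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be nonnegative")
        if self.n == 0:
            raise ValueError("empty confusion matrix")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricReport:
    overall_accuracy: float   # %
    sensitivity: float        # true positive rate, %
    specificity: float        # true negative rate, %
    miss_rate: float          # false negative rate, %
    fallout: float            # false positive rate, %
    kappa: float
    tss: float


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """All summary metrics from a presence/absence confusion matrix.

    Kappa is Cohen's kappa with marginal-product expected agreement; an
    observed class with zero plots makes the corresponding rate nan.
    """
    n = cm.n
    obs_pos = cm.tp + cm.fn
    obs_neg = cm.tn + cm.fp
    overall = 100.0 * (cm.tp + cm.tn) / n
    tpr = 100.0 * cm.tp / obs_pos if obs_pos else float("nan")
    tnr = 100.0 * cm.tn / obs_neg if obs_neg else float("nan")
    po = (cm.tp + cm.tn) / n
    pe = (
        (cm.tp + cm.fp) * obs_pos + (cm.fn + cm.tn) * obs_neg
    ) / (n * n)
    kappa = (po - pe) / (1.0 - pe) if pe < 1.0 else float("nan")
    tss = (tpr + tnr) / 100.0 - 1.0
    return MetricReport(overall, tpr, tnr, 100.0 - tpr, 100.0 - tnr, kappa, tss)


def _disc_values(raster, x, y, radius):
    """Values of pixels whose centers lie within ``radius`` of (x, y)."""
    cell = raster.cell_size
    r0, c0 = raster.world_to_pixel(x, y)
    pad = int(np.ceil(radius / cell)) + 1
    nrow, ncol = raster.shape
    rows = np.arange(max(0, r0 - pad), min(nrow, r0 + pad + 1))
    cols = np.arange(max(0, c0 - pad), min(ncol, c0 + pad + 1))
    if rows.size == 0 or cols.size == 0:
        return np.array([])
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    cx = raster.origin[0] + (cc + 0.5) * cell
    cy = raster.origin[1] - (rr + 0.5) * cell
    inside = (cx - x) ** 2 + (cy - y) ** 2 <= radius**2
    return raster.data[rr[inside], cc[inside]].astype(float)


def mmu_evaluate(
    species_map: SpeciesMap,
    plots: list[PlotRecord],
    radius: float = MMU_RADIUS_M,
    stratum: str | None = None,
    role: str = "validate",
) -> ConfusionMatrix:
    """Cross-tabulate MMU detections against validation plot truth.

    A plot counts as predicted presence iff at least one presence pixel
    center lies inside the ``radius`` disc around its recorded
    coordinate. Plots outside the map extent are excluded with a warning.
    """
    presence = species_map.presence
    tp = fp = fn = tn = 0
    skipped = 0
    for p in plots:
        if role is not None and p.role != role:
            continue
        if stratum is not None and p.stratum != stratum:
            continue
        if not presence.contains(p.x, p.y):
            skipped += 1
            continue
        vals = _disc_values(presence, p.x, p.y, radius)
        detected = bool(np.any(np.nan_to_num(vals, nan=0.0) > 0))
        observed = p.species == species_map.species
        if observed and detected:
            tp += 1
        elif observed:
            fn += 1
        elif detected:
            fp += 1
        else:
            tn += 1
    if skipped:
        warnings.warn(f"{skipped} plots outside map extent were excluded",
                      stacklevel=2)
    return ConfusionMatrix(tp, fp, fn, tn)


def uncertainty_at_plots(
    species_map: SpeciesMap,
    plots: list[PlotRecord],
    radius: float = MMU_RADIUS_M,
    stratum: str | None = None,
    role: str = "validate",
) -> np.ndarray:
    """Per-plot uncertainty U = 1 - max p(true class) over the MMU disc.

    For a presence plot the true-class probability is ``p_presence``; for
    an absence plot it is ``1 - p_presence``. Plots whose disc holds no
    valid probability are skipped with a warning. The returned array is
    sorted for direct use as a cumulative distribution.
    """
    out = []
    skipped = 0
    for p in plots:
        if role is not None and p.role != role:
            continue
        if stratum is not None and p.stratum != stratum:
            continue
        if not species_map.p_presence.contains(p.x, p.y):
            skipped += 1
            continue
        pv = _disc_values(species_map.p_presence, p.x, p.y, radius)
        pv = pv[np.isfinite(pv)]
        if pv.size == 0:
            skipped += 1
            continue
        truth_is_presence = p.species == species_map.species
        p_true = pv if truth_is_presence else 1.0 - pv
        out.append(1.0 - float(np.max(p_true)))
    if skipped:
        warnings.warn(f"{skipped} plots had no valid probability in the MMU",
                      stacklevel=2)
    return np.sort(np.asarray(out))
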