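"""Stratified random-forest presence/absence detection models.

Per species, two binary classifiers are trained: an *open* model (<20%
canopy cover above 2.5 m) that sees SAM rule images plus LiDAR-derived
predictors, and a *closed* model that sees LiDAR-derived predictors only.
Before fitting, an iterative variable-selection loop removes predictors
with negative permutation importance (the mean-decrease-accuracy analog)
and, of each highly correlated pair, the less important member. Predicted
maps carry the ensemble presence probability and the classification
uncertainty ``U = 1 - p_max``; the two strata are merged on the 20%
canopy-cover break into one map per species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .lidar_metrics import StructuralStack
from .raster import RasterGrid
from .synthetic_scene import LANDCOVER_CODES, VEGETATED_CLASSES, PlotRecord

__all__ = [
    "FeatureStack",
    "DetectionModel",
    "SpeciesMap",
    "build_masks",
    "extract_training_table",
    "select_variables",
    "fit_and_predict",
    "merge_strata",
]

DEFAULT_N_TREES = 2000
DEFAULT_CORR_THRESHOLD = 0.7
DECISION_THRESHOLD = 0.5
MIN_CLASS_PLOTS = 10


@dataclass
class FeatureStack:
    """Aligned named predictor rasters for one stratum and species."""

    layers: dict[str, RasterGrid]
    stratum: str              # open | closed
    species: str

    def __post_init__(self) -> None:
        names = list(self.layers)
        first = self.layers[names[0]]
        for n in names[1:]:
            first.require_same_grid(self.layers[n], (names[0], n))
        if self.stratum == "closed":
            bad = [n for n in names if n.startswith("rule_")]
            if bad:
                raise ValueError(f"closed stack must exclude spectral layers: {bad}")

    @property
    def grid(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    def matrix(self, names: list[str] | None = None) -> np.ndarray:
        names = names or list(self.layers)
        return np.stack([self.layers[n].data.astype(float).ravel() for n in names], axis=1)


@dataclass
class DetectionModel:
    variables: list[str]
    ensemble: RandomForestClassifier
    importances: dict[str, float]
    species: str
    stratum: str
    seed: int


@dataclass
class SpeciesMap:
    presence: RasterGrid      # 1/0, nodata outside stratum/mask
    p_presence: RasterGrid    # presence probability
    uncertainty: RasterGrid   # U = 1 - p_max in [0, 0.5]
    species: str
    stratum: str


def build_masks(structural: StructuralStack, landcover: RasterGrid) -> RasterGrid:
    """Analysis mask: >=10% cover below 2.5 m AND vegetated land cover.

    Dirt/bare, paved, buildings and water pixels are masked, as are pixels
    with little understory for the shrubs to occupy.
    """
    structural.cover_below_2p5.require_same_grid(landcover, ("cover_below", "landcover"))
    codes = np.unique(landcover.data[~np.isnan(landcover.data.astype(float))]).astype(int)
    unknown = set(codes) - set(LANDCOVER_CODES.values())
    if unknown:
        raise ValueError(f"unknown land-cover codes {sorted(unknown)}")
    cover_ok = np.nan_to_num(structural.cover_below_2p5.data.astype(float), nan=0.0) >= 0.10
    lc_ok = np.isin(landcover.data.astype(int), VEGETATED_CLASSES)
    return landcover.like((cover_ok & lc_ok).astype(bool), nodata=0)


def extract_training_table(
    stack: FeatureStack, plots: list[PlotRecord]
) -> pd.DataFrame:
    """Feature values at each plot's pixel plus the binary label.

    A plot is a presence for the stack's species if its species matches;
    every other plot (the other species or none) is an absence. Only plots
    of the stack's stratum are used.
    """
    grid = stack.grid
    rows = []
    for p in plots:
        if p.stratum != stack.stratum:
            continue
        if not grid.contains(p.x, p.y):
            continue
        vals = {n: float(lyr.value_at(p.x, p.y)) for n, lyr in stack.layers.items()}
        vals["label"] = int(p.species == stack.species)
        vals["role"] = p.role
        rows.append(vals)
    return pd.DataFrame(rows)


def _mda_importance(model, X, y, seed, n_repeats=5) -> np.ndarray:
    res = permutation_importance(
        model, X, y, n_repeats=n_repeats, random_state=seed, scoring="accuracy"
    )
    return res.importances_mean


def select_variables(
    table: pd.DataFrame,
    corr_threshold: float = DEFAULT_CORR_THRESHOLD,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    importance_fn=None,
) -> list[str]:
    """Iteratively drop negative-importance and correlated variables.

    Each round fits the ensemble, removes variables whose mean decrease
    accuracy is negative, then for every pair with |Pearson r| >=
    ``corr_threshold`` removes the less important member. Stops at a fixed
    point; deterministic under the seed.
    """
    candidates = [c for c in table.columns if c not in ("label", "role")]
    if len(candidates) < 2:
        raise ValueError("need at least two candidate variables")
    y = table["label"].to_numpy()
    while True:
        X = table[candidates].to_numpy(dtype=float)
        if importance_fn is None:
            model = RandomForestClassifier(
                n_estimators=n_trees, random_state=seed, n_jobs=1
            ).fit(X, y)
            imp = _mda_importance(model, X, y, seed)
        else:
            imp = np.asarray(importance_fn(X, y, candidates), dtype=float)
        importance = dict(zip(candidates, imp))
        drop: set[str] = {v for v, w in importance.items() if w < 0}
        keep = [v for v in candidates if v not in drop]
        if len(keep) >= 2:
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.corrcoef(table[keep].to_numpy(dtype=float), rowvar=False)
            corr = np.nan_to_num(corr, nan=0.0)  # constant columns
            for i in range(len(keep)):
                for j in range(i + 1, len(keep)):
                    if abs(corr[i, j]) >= corr_threshold:
                        a, b = keep[i], keep[j]
                        if a in drop or b in drop:
                            continue
                        drop.add(a if importance[a] <= importance[b] else b)
        if not drop:
            return candidates
        candidates = [v for v in candidates if v not in drop]
        if not candidates:
            raise ValueError("variable selection eliminated all variables")
        if len(candidates) == 1:
            return candidates


def fit_and_predict(
    stack: FeatureStack,
    plots: list[PlotRecord],
    mask: RasterGrid,
    stratum_mask: np.ndarray,
    n_trees: int = DEFAULT_N_TREES,
    corr_threshold: float = DEFAULT_CORR_THRESHOLD,
    seed: int = 0,
    select: bool = True,
) -> tuple[SpeciesMap, DetectionModel]:
    """Train the stratum ensemble on training plots and map the stratum.

    Only pixels inside both the analysis mask and the stratum are
    predicted; everything else is nodata. Presence uses the 0.5 majority
    vote; the uncertainty raster is ``1 - max(p, 1-p)``.
    """
    table = extract_training_table(stack, plots)
    # plots whose pixel lacks a defined predictor (e.g. stratum-edge rule
    # image nodata) cannot feed the ensemble
    table = table.dropna()
    train = table[table["role"] == "train"]
    n_pres = int((train["label"] == 1).sum())
    n_abs = int((train["label"] == 0).sum())
    if n_pres == 0 or n_abs == 0:
        raise ValueError("single-class training set")
    if n_pres < MIN_CLASS_PLOTS or n_abs < MIN_CLASS_PLOTS:
        raise ValueError(
            f"too few training plots in stratum {stack.stratum!r} "
            f"({n_pres} presences, {n_abs} absences; need {MIN_CLASS_PLOTS} each)"
        )
    if select:
        variables = select_variables(
            train.drop(columns=["role"]), corr_threshold, n_trees, seed
        )
    else:
        variables = [c for c in table.columns if c not in ("label", "role")]
    X = train[variables].to_numpy(dtype=float)
    y = train["label"].to_numpy()
    model = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, oob_score=True, n_jobs=1
    ).fit(X, y)
    imp = dict(zip(variables, _mda_importance(model, X, y, seed)))

    grid = stack.grid
    predict_mask = (
        np.asarray(mask.data, bool) & np.asarray(stratum_mask, bool)
    ).ravel()
    Xall = stack.matrix(variables)
    valid = predict_mask & np.all(np.isfinite(Xall), axis=1)
    p = np.full(valid.size, np.nan)
    if valid.any():
        proba = model.predict_proba(Xall[valid])
        p_presence = proba[:, list(model.classes_).index(1)]
        p[valid] = p_presence
    presence = np.where(np.isnan(p), np.nan, (p >= DECISION_THRESHOLD).astype(float))
    pmax = np.fmax(p, 1.0 - p)
    uncertainty = np.where(np.isnan(p), np.nan, 1.0 - pmax)
    shp = grid.shape
    smap = SpeciesMap(
        grid.like(presence.reshape(shp)),
        grid.like(p.reshape(shp)),
        grid.like(uncertainty.reshape(shp)),
        stack.species,
        stack.stratum,
    )
    return smap, DetectionModel(variables, model, imp, stack.species, stack.stratum, seed)


def merge_strata(
    open_map: SpeciesMap,
    closed_map: SpeciesMap,
    cover_raster: RasterGrid,
    cover_break: float = 0.20,
) -> SpeciesMap:
    """Combine the open and closed maps on the canopy-cover break."""
    open_map.presence.require_same_grid(closed_map.presence, ("open", "closed"))
    open_map.presence.require_same_grid(cover_raster, ("open", "cover"))
    take_open = np.nan_to_num(cover_raster.data.astype(float), nan=1.0) < cover_break

    def pick(a: RasterGrid, b: RasterGrid) -> RasterGrid:
        return a.like(np.where(take_open, a.data, b.data))

    return SpeciesMap(
        pick(open_map.presence, closed_map.presence),
        pick(open_map.p_presence, closed_map.p_presence),
        pick(open_map.uncertainty, closed_map.uncertainty),
        open_map.species,
        "merged",
    )
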