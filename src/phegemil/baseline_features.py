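"""Hand-crafted baseline features: vegetation indices, channel moments and
date-group aggregation, plus the classical regressors they feed.

The three vegetation indices are the standard normalized differences

    NDVI  = (NIR - Red)     / (NIR + Red)
    NDRE  = (NIR - RedEdge) / (NIR + RedEdge)
    GNDVI = (NIR - Green)   / (NIR + Green)

computed per pixel on five-band multispectral images.  A plot's feature
vector for one date group has 16 entries (mean and mode of each of the 5
bands, plus mean and mode of each of the 3 VI maps), averaged over the
plot's images within the group; all four groups concatenated give 64.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import numpy.ma as ma

from .io_core import MS_BAND_ORDER, ImageInstance, PlotSample

__all__ = [
    "VI_NAMES",
    "DateGrouping",
    "SEASON_2018_GROUPING",
    "FeatureVector",
    "compute_vegetation_indices",
    "channel_moments",
    "assign_date_groups",
    "plot_feature_vector",
    "feature_names",
    "fit_baseline",
    "BaselinePredictor",
]

VI_NAMES = ("ndvi", "ndre", "gndvi")
_VI_BANDS = {"ndvi": "red", "ndre": "rededge", "gndvi": "green"}


@dataclass(frozen=True)
class DateGrouping:
    """Ordered, non-overlapping date ranges (inclusive on both ends)."""

    bounds: tuple[tuple[_dt.date, _dt.date], ...]

    def __post_init__(self):
        for (a0, a1), (b0, b1) in zip(self.bounds, self.bounds[1:]):
            if a1 >= b0:
                raise ValueError("date groups must be ordered and non-overlapping")
        for a0, a1 in self.bounds:
            if a0 > a1:
                raise ValueError("group start must not exceed its end")

    @property
    def n_groups(self) -> int:
        return len(self.bounds)

    def group_of(self, date: _dt.date) -> int:
        for k, (start, end) in enumerate(self.bounds):
            if start <= date <= end:
                return k
        raise ValueError(f"date {date} outside every group of the grouping")


def _d(s: str) -> _dt.date:
    return _dt.date.fromisoformat(s)


#: the four 2017-2018 season windows used for the reference wheat dataset
SEASON_2018_GROUPING = DateGrouping(
    bounds=(
        (_d("2018-01-18"), _d("2018-01-31")),
        (_d("2018-02-01"), _d("2018-03-02")),
        (_d("2018-03-03"), _d("2018-03-10")),
        (_d("2018-03-11"), _d("2018-03-21")),
    )
)


@dataclass
class FeatureVector:
    plot_id: str
    scope: str  # "g1".."g4" or "all"
    values: ma.MaskedArray  # length 16 (single group) or 64 ("all")
    names: list[str]


def compute_vegetation_indices(image: ImageInstance) -> dict[str, ma.MaskedArray]:
    """Per-pixel NDVI/NDRE/GNDVI maps; denominator-zero pixels are masked."""
    if image.channel != "multispectral":
        raise ValueError(
            f"vegetation indices need a multispectral image, got {image.channel!r}"
        )
    nir = image.band("nir")
    out: dict[str, ma.MaskedArray] = {}
    for vi, band_name in _VI_BANDS.items():
        other = image.band(band_name)
        denom = nir + other
        mask = denom == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.where(mask, 0.0, (nir - other) / np.where(mask, 1.0, denom))
        out[vi] = ma.MaskedArray(vals, mask=mask)
    return out


def _mode(values: np.ndarray, n_bins: int) -> float:
    """Center of the most populated histogram bin over the observed range;
    ties break toward the lowest bin."""
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        return vmin
    counts, edges = np.histogram(values, bins=n_bins, range=(vmin, vmax))
    k = int(np.argmax(counts))  # argmax takes the first (lowest) maximal bin
    return float(0.5 * (edges[k] + edges[k + 1]))


def feature_names() -> list[str]:
    names = []
    for band in MS_BAND_ORDER:
        names += [f"{band}_mean", f"{band}_mode"]
    for vi in VI_NAMES:
        names += [f"{vi}_mean", f"{vi}_mode"]
    return names


def channel_moments(image: ImageInstance, n_bins: int = 256) -> ma.MaskedArray:
    """16 moment features of one multispectral image.

    Order: (mean, mode) per band in the fixed band order, then (mean, mode)
    per VI.  Fully-masked VI maps yield masked entries.
    """
    if image.channel != "multispectral":
        raise ValueError("channel moments are defined for multispectral images")
    vals: list[float] = []
    mask: list[bool] = []
    for b in range(5):
        band = image.pixels[:, :, b].ravel()
        vals += [float(band.mean()), _mode(band, n_bins)]
        mask += [False, False]
    for vi, vi_map in compute_vegetation_indices(image).items():
        valid = vi_map.compressed()
        if valid.size == 0:
            vals += [0.0, 0.0]
            mask += [True, True]
        else:
            vals += [float(valid.mean()), _mode(valid, n_bins)]
            mask += [False, False]
    return ma.MaskedArray(vals, mask=mask)


def assign_date_groups(
    dates: list[_dt.date], grouping: DateGrouping | str = "quantile-default"
) -> list[int]:
    """Map each date to a group index.

    With the string ``"quantile-default"`` four quantile-balanced groups are
    built from the observed unique dates (sizes differ by at most one).
    """
    dates = [_dt.date.fromisoformat(d) if isinstance(d, str) else d for d in dates]
    if isinstance(grouping, str):
        if grouping != "quantile-default":
            raise ValueError(f"unknown grouping preset {grouping!r}")
        grouping = quantile_grouping(dates)
    return [grouping.group_of(d) for d in dates]


def quantile_grouping(dates: list[_dt.date], n_groups: int = 4) -> DateGrouping:
    uniq = sorted(set(dates))
    if len(uniq) < n_groups:
        raise ValueError(f"need at least {n_groups} distinct dates")
    chunks = np.array_split(np.arange(len(uniq)), n_groups)
    bounds = tuple((uniq[c[0]], uniq[c[-1]]) for c in chunks)
    return DateGrouping(bounds=bounds)


def plot_feature_vector(
    sample: PlotSample,
    grouping: DateGrouping | str = "quantile-default",
    scope: str = "all",
    n_bins: int = 256,
) -> FeatureVector:
    """Average per-image moment features over a plot's multispectral images.

    `scope` is one of "g1".."g4" (one 16-vector) or "all" (the four group
    vectors concatenated, length 64).  Groups without images are masked.
    """
    images = sample.bags.get("multispectral", [])
    if not images:
        raise ValueError(f"plot {sample.plot_id} has no multispectral images")
    if isinstance(grouping, str):
        grouping = quantile_grouping([img.date for img in images])
    n_groups = grouping.n_groups
    per_group: list[list[ma.MaskedArray]] = [[] for _ in range(n_groups)]
    for img in images:
        per_group[grouping.group_of(img.date)].append(channel_moments(img, n_bins))

    base_names = feature_names()
    group_vectors: list[ma.MaskedArray] = []
    for k in range(n_groups):
        if per_group[k]:
            stacked = ma.stack(per_group[k])
            group_vectors.append(stacked.mean(axis=0))
        else:
            group_vectors.append(ma.MaskedArray(np.zeros(16), mask=np.ones(16, bool)))

    if scope == "all":
        values = ma.concatenate(group_vectors)
        names = [f"g{k + 1}_{n}" for k in range(n_groups) for n in base_names]
    else:
        if not (scope.startswith("g") and scope[1:].isdigit()):
            raise ValueError(f"scope must be 'all' or 'g1'..'g{n_groups}', got {scope!r}")
        k = int(scope[1:]) - 1
        if not 0 <= k < n_groups:
            raise ValueError(f"scope {scope!r} outside the grouping")
        values = group_vectors[k]
        names = [f"{scope}_{n}" for n in base_names]
    return FeatureVector(plot_id=sample.plot_id, scope=scope, values=values, names=names)


# ---------------------------------------------------------------------------
# baseline regressors
# ---------------------------------------------------------------------------

class BaselinePredictor:
    """A fitted baseline with the imputation means frozen at fit time."""

    def __init__(self, model, column_means: np.ndarray):
        self._model = model
        self._column_means = column_means

    def predict(self, features: np.ndarray | ma.MaskedArray) -> np.ndarray:
        X = self._impute(features)
        return self._model.predict(X)

    def _impute(self, features) -> np.ndarray:
        X = ma.masked_invalid(ma.asarray(features, dtype=float))
        X = X.filled(np.nan)
        idx = np.where(np.isnan(X))
        X[idx] = self._column_means[idx[1]]
        return X


def fit_baseline(
    features: np.ndarray | ma.MaskedArray,
    yields: np.ndarray,
    kind: str = "l1-linear",
    cv: int = 5,
    seed: int = 0,
) -> BaselinePredictor:
    """Fit an L1-regularized linear model or a random forest.

    Hyperparameters (L1 strength, forest size) are tuned by internal
    cross-validation on the training rows only; masked feature entries are
    imputed with the training-column means.
    """
    X = ma.masked_invalid(ma.asarray(features, dtype=float)).filled(np.nan)
    y = np.asarray(yields, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"{X.shape[0]} feature rows vs {y.shape[0]} yields")
    column_means = np.nanmean(X, axis=0)
    column_means = np.where(np.isnan(column_means), 0.0, column_means)
    idx = np.where(np.isnan(X))
    X[idx] = column_means[idx[1]]

    cv = min(cv, X.shape[0])
    if kind == "l1-linear":
        from sklearn.linear_model import LassoCV

        model = LassoCV(cv=cv, random_state=seed, max_iter=50_000)
        model.fit(X, y)
    elif kind == "forest":
        from sklearn.ensemble import RandomForestRegressor
        from sklearn.model_selection import GridSearchCV

        search = GridSearchCV(
            RandomForestRegressor(random_state=seed),
            param_grid={"n_estimators": [50, 200], "max_depth": [None, 8]},
            cv=cv,
            scoring="neg_mean_squared_error",
        )
        search.fit(X, y)
        model = search.best_estimator_
    else:
        raise ValueError(f"unknown baseline kind {kind!r}")
    return BaselinePredictor(model, column_means)
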