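"""Synthetic breeding-trial generator.

Emulates the statistical structure of a UAV-phenotyped wheat yield trial:

* genotypes: biallelic SNP dosages under Hardy-Weinberg sampling with a
  controllable heterozygosity and missing-call rate (GBS-like output);
* an additive genetic architecture: a random subset of markers carries
  Gaussian effects, breeding values are standardized to unit variance and a
  target narrow-sense heritability fixes the non-genetic variance;
* field structure: lines assigned to trials, replicated plots, trial and
  residual yield deviations in t/ha;
* imagery: per flight date, a Poisson number of images per plot and channel.
  Multispectral band means are set so that image-level NDVI tracks a latent
  canopy-health trajectory s(d) = q * growth(d), where q summarises the
  plot's growing condition (genetics + trial + residual) and growth(d) is a
  logistic green-up curve.  The NDVI noise floor is smallest at mid-season,
  so mid-season images are the most informative about yield by construction;
  thermal images are inversely related to s(d) with the largest noise, and
  the DEM (height) channel becomes informative late, as canopy/biomass
  accumulates.

Everything is driven by a single integer seed: identical configs produce
identical datasets, byte for byte on disk.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import (
    CHANNELS,
    GenotypeMatrix,
    ImageInstance,
    PlotSample,
    write_genotype_tsv,
    write_image_instance,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_genotypes",
    "simulate_breeding_values",
    "simulate_field_trial",
    "render_plot_images",
    "simulate_dataset",
    "simulate_new_environment",
    "generate_dataset",
    "DEFAULT_FLIGHT_DATES",
]

#: default flights spanning the Jan-Mar window of a winter-cycle season
DEFAULT_FLIGHT_DATES = (
    "2018-01-20",
    "2018-01-29",
    "2018-02-07",
    "2018-02-16",
    "2018-02-25",
    "2018-03-06",
    "2018-03-15",
    "2018-03-21",
)

# reflectance model constants (arbitrary but fixed units)
_NIR_PLUS_RED = 0.8
_NDRE_GAIN = 0.7
_GNDVI_GAIN = 0.6
_THERMAL_BASE, _THERMAL_GAIN = 0.7, 0.3
_DEM_BASE, _DEM_GAIN = 0.05, 0.4
_GROWTH_MID, _GROWTH_RATE = 0.45, 0.12
_VI_PEAK_T = 0.45  # season fraction of minimal NDVI noise (mid growth)


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic trial; `seed` fully determines the output."""

    n_lines: int = 120
    n_markers: int = 200
    n_causal: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    marker_missing_rate: float = 0.05
    het_rate: float = 0.02
    h2_target: float | None = 0.5
    n_trials: int = 6
    n_reps: int = 2
    trial_sd: float = 0.3
    residual_sd: float | None = None  # derived from h2_target when None
    mean_yield: float = 6.0  # t/ha
    flight_dates: tuple[str, ...] = DEFAULT_FLIGHT_DATES
    images_per_plot_per_date_mean: float = 2.0
    image_size: tuple[int, int] = (64, 64)
    channel_set: tuple[str, ...] = ("multispectral", "thermal", "dem")
    pixel_noise_sd: float = 0.02
    vi_noise_mid: float = 0.03
    vi_noise_edge: float = 0.15
    thermal_noise_sd: float = 0.12
    dem_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        for name in ("marker_missing_rate", "het_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.h2_target is not None and not 0.0 <= self.h2_target <= 1.0:
            raise ValueError(f"h2_target must be in [0,1], got {self.h2_target}")
        if self.n_causal > self.n_markers:
            raise ValueError("n_causal cannot exceed n_markers")
        if self.n_trials > self.n_lines:
            raise ValueError("n_trials cannot exceed n_lines")
        if self.h2_target is None and self.residual_sd is None:
            raise ValueError("set h2_target or residual_sd")
        if not self.flight_dates:
            raise ValueError("flight_dates must be non-empty")
        dates = [_dt.date.fromisoformat(d) for d in self.flight_dates]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("flight_dates must be strictly increasing")
        if not set(self.channel_set) <= set(CHANNELS):
            raise ValueError(f"channel_set must be a subset of {CHANNELS}")

    @property
    def dates(self) -> list[_dt.date]:
        return [_dt.date.fromisoformat(d) for d in self.flight_dates]

    def resolved_residual_sd(self) -> float:
        """Residual yield sd; derived from h2_target when not set explicitly.

        With var(g)=1 the identity h2 = 1 / (1 + trial_sd^2 + residual_sd^2)
        pins the residual variance.
        """
        if self.residual_sd is not None:
            return float(self.residual_sd)
        if self.h2_target <= 0:
            raise ValueError("h2_target must be > 0 to derive residual_sd")
        nongenetic = 1.0 / self.h2_target - 1.0
        resid_var = nongenetic - self.trial_sd**2
        if resid_var < 0:
            raise ValueError(
                "trial_sd alone exceeds the non-genetic variance implied by "
                f"h2_target={self.h2_target}"
            )
        return float(np.sqrt(resid_var))


@dataclass
class GroundTruth:
    """Simulation truth, for recovery tests and oracle evaluations."""

    causal_marker_ids: list[str]
    effect_sizes: np.ndarray  # aligned with causal_marker_ids
    breeding_values: dict[str, float]  # line id -> g (unit variance)
    plots: pd.DataFrame | None = None  # plot_id, entry_id, trial_id, u, e, yield
    health: np.ndarray | None = None  # n_plots x n_dates latent s(d) in [0,1]
    dates: list[_dt.date] = field(default_factory=list)


def _season_fraction(dates: list[_dt.date]) -> np.ndarray:
    span = (dates[-1] - dates[0]).days or 1
    return np.array([(d - dates[0]).days / span for d in dates])


def growth_curve(t: np.ndarray | float) -> np.ndarray:
    """Logistic green-up curve over the season fraction t in [0,1]."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(t, dtype=float) - _GROWTH_MID) / _GROWTH_RATE))


def vi_noise_sd(t: float, cfg: SimConfig) -> float:
    """NDVI image-level noise; minimal at mid-season, larger at the edges."""
    w = min(1.0, abs(t - _VI_PEAK_T) / 0.55)
    return cfg.vi_noise_mid + (cfg.vi_noise_edge - cfg.vi_noise_mid) * w


# ---------------------------------------------------------------------------
# genotypes and genetic architecture
# ---------------------------------------------------------------------------

def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw lines x markers dosages under HWE with controlled heterozygosity.

    Per marker the allele frequency p is uniform on `maf_range`; a call is
    heterozygous with probability `het_rate` and otherwise homozygous with
    alternate-allele probability chosen so that E[dosage]/2 = p exactly.
    Missing calls are placed i.i.d. at `marker_missing_rate`.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], cfg.n_markers)
    h = cfg.het_rate
    if np.any(p < h / 2) or np.any(p > 1 - h / 2):
        raise ValueError("het_rate too large for the requested maf_range")
    # P(dos=2) = p - h/2, P(dos=1) = h, P(dos=0) = 1 - p - h/2  => E[dos]/2 = p
    u = rng.random((cfg.n_lines, cfg.n_markers))
    p2 = p - h / 2
    dosages = np.where(u < p2, 2.0, np.where(u < p2 + h, 1.0, 0.0))
    if cfg.marker_missing_rate > 0:
        miss = rng.random((cfg.n_lines, cfg.n_markers)) < cfg.marker_missing_rate
        dosages = np.where(miss, np.nan, dosages)
    return GenotypeMatrix(
        line_ids=[f"L{i:04d}" for i in range(cfg.n_lines)],
        marker_ids=[f"M{j:05d}" for j in range(cfg.n_markers)],
        dosages=dosages,
    )


def simulate_breeding_values(
    G: GenotypeMatrix, cfg: SimConfig, rng: np.random.Generator | None = None
) -> GroundTruth:
    """Additive breeding values from `n_causal` random markers.

    Missing calls are treated as the marker mean; g is standardized to unit
    variance (when non-degenerate) so that h2 bookkeeping is exact.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    X = G.dosages.copy()
    col_mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    nan_idx = np.where(np.isnan(X))
    X[nan_idx] = col_mean[nan_idx[1]]
    Xc = X - X.mean(axis=0)

    causal_idx = np.sort(rng.choice(G.shape[1], size=cfg.n_causal, replace=False))
    effects = rng.normal(0.0, 1.0, cfg.n_causal)
    g = Xc[:, causal_idx] @ effects if cfg.n_causal else np.zeros(G.shape[0])
    sd = g.std()
    if sd > 0:
        g = (g - g.mean()) / sd
    return GroundTruth(
        causal_marker_ids=[G.marker_ids[j] for j in causal_idx],
        effect_sizes=effects,
        breeding_values={l: float(v) for l, v in zip(G.line_ids, g)},
    )


def simulate_field_trial(
    truth: GroundTruth, cfg: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Assign lines to trials, replicate plots and draw yields in t/ha.

    yield = mean_yield + g + trial effect (sd `trial_sd`) + residual.
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    lines = list(truth.breeding_values)
    order = rng.permutation(len(lines))
    trial_of_line: dict[str, int] = {}
    for k, chunk in enumerate(np.array_split(order, cfg.n_trials)):
        for i in chunk:
            trial_of_line[lines[i]] = k
    trial_effects = rng.normal(0.0, cfg.trial_sd, cfg.n_trials)
    resid_sd = cfg.resolved_residual_sd()

    rows = []
    plot_no = 0
    for line in lines:
        t = trial_of_line[line]
        g = truth.breeding_values[line]
        for _rep in range(cfg.n_reps):
            e = rng.normal(0.0, resid_sd)
            rows.append(
                {
                    "plot_id": f"P{plot_no:05d}",
                    "entry_id": line,
                    "trial_id": f"T{t:02d}",
                    "g": g,
                    "u": trial_effects[t],
                    "e": e,
                    "yield": cfg.mean_yield + g + trial_effects[t] + e,
                }
            )
            plot_no += 1
    plots = pd.DataFrame(rows)

    # latent canopy health s(d) = q * growth(d); q in (0,1) summarises the
    # plot's growing condition on the yield scale
    tfrac = _season_fraction(cfg.dates)
    tot_sd = np.sqrt(1.0 + cfg.trial_sd**2 + resid_sd**2)
    z = (plots["yield"].to_numpy() - cfg.mean_yield) / tot_sd
    q = 1.0 / (1.0 + np.exp(-z))
    truth.health = q[:, None] * growth_curve(tfrac)[None, :]
    truth.dates = cfg.dates
    truth.plots = plots
    return plots


# ---------------------------------------------------------------------------
# imagery
# ---------------------------------------------------------------------------

def _render_multispectral(ndvi: float, s: float, cfg: SimConfig, rng) -> np.ndarray:
    h, w = cfg.image_size
    nir = 0.5 * _NIR_PLUS_RED * (1.0 + ndvi)
    red = 0.5 * _NIR_PLUS_RED * (1.0 - ndvi)
    rededge = 0.5 * _NIR_PLUS_RED * (1.0 - _NDRE_GAIN * ndvi)
    green = 0.5 * _NIR_PLUS_RED * (1.0 - _GNDVI_GAIN * ndvi)
    blue = 0.1 + 0.05 * (1.0 - s)
    means = np.array([blue, green, red, rededge, nir])  # io_core.MS_BAND_ORDER
    pixels = np.broadcast_to(means, (h, w, 5)).copy()
    if cfg.pixel_noise_sd > 0:
        pixels += rng.normal(0.0, cfg.pixel_noise_sd, (h, w, 5))
    return pixels


def render_plot_images(
    plot_index: int,
    truth: GroundTruth,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> list[ImageInstance]:
    """Render every image instance of one plot across flight dates.

    Per date and channel the image count is Poisson-distributed (0 allowed,
    emulating irregular coverage).  Multispectral image-level NDVI equals
    s(d) plus date-dependent noise; thermal is inversely related to s(d)
    with the largest noise; DEM tracks accumulated growth and is therefore
    informative late in the season.
    """
    if not cfg.flight_dates:
        raise ValueError("flight_dates must be non-empty")
    if truth.health is None:
        raise ValueError("ground truth lacks health trajectories; run simulate_field_trial")
    h, w = cfg.image_size
    tfrac = _season_fraction(cfg.dates)
    grow = growth_curve(tfrac)
    instances: list[ImageInstance] = []
    for di, date in enumerate(cfg.dates):
        s = float(truth.health[plot_index, di])
        for channel in cfg.channel_set:
            count = rng.poisson(cfg.images_per_plot_per_date_mean)
            for _ in range(count):
                if channel == "multispectral":
                    ndvi = s + rng.normal(0.0, vi_noise_sd(tfrac[di], cfg))
                    ndvi = float(np.clip(ndvi, -0.95, 0.95))
                    pixels = _render_multispectral(ndvi, s, cfg, rng)
                elif channel == "thermal":
                    val = (
                        _THERMAL_BASE
                        - _THERMAL_GAIN * s
                        + rng.normal(0.0, cfg.thermal_noise_sd)
                    )
                    pixels = np.full((h, w, 1), val)
                    if cfg.pixel_noise_sd > 0:
                        pixels = pixels + rng.normal(0.0, cfg.pixel_noise_sd, (h, w, 1))
                else:  # dem
                    val = (
                        _DEM_BASE
                        + _DEM_GAIN * s * grow[di]
                        + rng.normal(0.0, cfg.dem_noise_sd)
                    )
                    pixels = np.full((h, w, 1), val)
                    if cfg.pixel_noise_sd > 0:
                        pixels = pixels + rng.normal(0.0, cfg.pixel_noise_sd, (h, w, 1))
                instances.append(ImageInstance(channel=channel, date=date, pixels=pixels))
    return instances


# ---------------------------------------------------------------------------
# end-to-end simulation
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    config: SimConfig
    genotypes: GenotypeMatrix
    truth: GroundTruth
    plots: pd.DataFrame
    samples: list[PlotSample]


def simulate_dataset(cfg: SimConfig) -> SimResult:
    """Run the full generator in memory: genotypes -> yields -> image bags."""
    rng = np.random.default_rng(cfg.seed)
    G = simulate_genotypes(cfg, rng)
    truth = simulate_breeding_values(G, cfg, rng)
    plots = simulate_field_trial(truth, cfg, rng)

    from .io_core import impute_dosage

    imputed = impute_dosage(G)
    line_index = {l: i for i, l in enumerate(G.line_ids)}
    samples = []
    for idx, row in plots.iterrows():
        instances = render_plot_images(idx, truth, cfg, rng)
        bags: dict[str, list[ImageInstance]] = {ch: [] for ch in CHANNELS}
        for inst in instances:
            bags[inst.channel].append(inst)
        samples.append(
            PlotSample(
                plot_id=row["plot_id"],
                entry_id=row["entry_id"],
                trial_id=row["trial_id"],
                yield_t_ha=float(row["yield"]),
                bags=bags,
                genotype=imputed[line_index[row["entry_id"]]],
            )
        )
    return SimResult(cfg, G, truth, plots, samples)


def simulate_new_environment(
    base: SimResult, cfg: SimConfig | None = None, seed: int | None = None
) -> SimResult:
    """Simulate a second environment sharing the genetic architecture.

    New lines are drawn from the same marker panel and causal effects, with
    fresh trial/residual deviations — the cross-environment prediction
    setting (train on environment A, predict new lines in environment B).
    """
    cfg = cfg or base.config
    if seed is None:
        seed = base.config.seed + 104729
    cfg_b = dataclasses.replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg_b.seed)
    G = simulate_genotypes(cfg_b, rng)
    G = GenotypeMatrix(
        line_ids=[f"B{l[1:]}" for l in G.line_ids],
        marker_ids=list(G.marker_ids),
        dosages=G.dosages,
    )
    # reuse environment A's causal markers and effect sizes
    marker_pos = {m: j for j, m in enumerate(G.marker_ids)}
    causal_idx = np.array([marker_pos[m] for m in base.truth.causal_marker_ids], dtype=int)
    X = G.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_idx = np.where(np.isnan(X))
    X[nan_idx] = col_mean[nan_idx[1]]
    Xc = X - X.mean(axis=0)
    g = Xc[:, causal_idx] @ base.truth.effect_sizes if len(causal_idx) else np.zeros(len(G.line_ids))
    sd = g.std()
    if sd > 0:
        g = (g - g.mean()) / sd
    truth = GroundTruth(
        causal_marker_ids=list(base.truth.causal_marker_ids),
        effect_sizes=base.truth.effect_sizes.copy(),
        breeding_values={l: float(v) for l, v in zip(G.line_ids, g)},
    )
    plots = simulate_field_trial(truth, cfg_b, rng)

    from .io_core import impute_dosage

    imputed = impute_dosage(G)
    line_index = {l: i for i, l in enumerate(G.line_ids)}
    samples = []
    for idx, row in plots.iterrows():
        instances = render_plot_images(idx, truth, cfg_b, rng)
        bags: dict[str, list[ImageInstance]] = {ch: [] for ch in CHANNELS}
        for inst in instances:
            bags[inst.channel].append(inst)
        samples.append(
            PlotSample(
                plot_id="B" + row["plot_id"][1:],
                entry_id=row["entry_id"],
                trial_id="B" + row["trial_id"][1:],
                yield_t_ha=float(row["yield"]),
                bags=bags,
                genotype=imputed[line_index[row["entry_id"]]],
            )
        )
    return SimResult(cfg_b, G, truth, plots, samples)


# ---------------------------------------------------------------------------
# on-disk dataset
# ---------------------------------------------------------------------------

def generate_dataset(cfg: SimConfig, out_dir, overwrite: bool = False) -> Path:
    """Materialise a dataset on disk; returns the manifest path.

    Layout: genotypes.tsv, phenotypes.csv, ground_truth.json,
    images/<plot>/<channel>_<date>_<k>.tif and manifest.json.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} is not empty; pass overwrite=True")
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "images").mkdir(exist_ok=True)

    result = simulate_dataset(cfg)
    write_genotype_tsv(result.genotypes, out_dir / "genotypes.tsv")
    result.plots[["plot_id", "entry_id", "trial_id", "yield"]].to_csv(
        out_dir / "phenotypes.csv", index=False, float_format="%.6f"
    )

    manifest: dict[str, dict] = {}
    for sample in result.samples:
        plot_dir = out_dir / "images" / sample.plot_id
        plot_dir.mkdir(exist_ok=True)
        inst_map: dict[str, list] = {}
        for ch, instances in sample.bags.items():
            entries = []
            for k, inst in enumerate(instances):
                rel = f"images/{sample.plot_id}/{ch}_{inst.date.isoformat()}_{k}.tif"
                write_image_instance(inst, out_dir / rel)
                entries.append([inst.date.isoformat(), rel])
            if entries:
                inst_map[ch] = entries
        manifest[sample.plot_id] = {
            "entry_id": sample.entry_id,
            "trial_id": sample.trial_id,
            "yield": round(float(sample.yield_t_ha), 6),
            "instances": inst_map,
        }

    truth_payload = {
        "causal_marker_ids": result.truth.causal_marker_ids,
        "effect_sizes": [float(v) for v in result.truth.effect_sizes],
        "breeding_values": result.truth.breeding_values,
        "flight_dates": [d.isoformat() for d in cfg.dates],
        "health": [[round(float(v), 8) for v in row] for row in result.truth.health],
    }
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(truth_payload, fh, sort_keys=True, indent=1)

    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    return manifest_path
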