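"""Data containers and I/O: genotype matrices, plot image bags, manifests.

Genotypes are SNP dosages (count of alternate alleles, {0,1,2}) for a set of
breeding lines; missing calls are tracked explicitly.  The quality-control
filters implemented here are the standard genotyping-by-sequencing ones:
markers are dropped when their missing-call fraction or heterozygosity is too
high, and lines with mostly-missing genotypes are removed.

A :class:`PlotSample` is one field plot: a bag of time-stamped image instances
per data channel (multispectral / thermal / DEM) plus the line's genotype and
the measured grain yield in t/ha.  Bags may be empty in any channel — plots
with fewer images or a missing data source are first-class citizens.
"""

from __future__ import annotations

import datetime as _dt
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CHANNELS = ("multispectral", "thermal", "dem")
#: number of bands each image channel must carry
CHANNEL_BANDS = {"multispectral": 5, "thermal": 1, "dem": 1}
#: fixed multispectral band order (blue, green, red, rededge, nir)
MS_BAND_ORDER = ("blue", "green", "red", "rededge", "nir")

MISSING = np.nan


class GenotypeParseError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Lines x markers dosage calls; missing encoded as NaN."""

    line_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray  # float array, values in {0,1,2} or NaN

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosage calls must be in {0,1,2} or missing")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosages.shape

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def marker_missing_fraction(self) -> np.ndarray:
        return self.missing_mask.mean(axis=0)

    def line_missing_fraction(self) -> np.ndarray:
        return self.missing_mask.mean(axis=1)

    def marker_heterozygosity(self) -> np.ndarray:
        """Fraction of non-missing calls equal to 1, per marker."""
        het = (self.dosages == 1.0).sum(axis=0)
        n_typed = (~self.missing_mask).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(n_typed > 0, het / np.maximum(n_typed, 1), 0.0)
        return frac

    def dosage_for(self, line_id: str) -> np.ndarray:
        return self.dosages[self.line_ids.index(line_id)]


@dataclass
class ImageInstance:
    """One multi-channel pixel array: a single MIL instance."""

    channel: str
    date: _dt.date
    pixels: np.ndarray  # height x width x bands (float32: bags can be large)

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[:, :, None]
        expected = CHANNEL_BANDS[self.channel]
        if self.pixels.shape[2] != expected:
            raise ValueError(
                f"{self.channel} image must have {expected} bands, "
                f"got {self.pixels.shape[2]}"
            )
        if not np.isfinite(self.pixels).all():
            raise ValueError("pixel values must be finite")
        if isinstance(self.date, str):
            self.date = _dt.date.fromisoformat(self.date)

    def band(self, name: str) -> np.ndarray:
        if self.channel != "multispectral":
            raise ValueError("named bands only exist for multispectral images")
        return self.pixels[:, :, MS_BAND_ORDER.index(name)]


@dataclass
class PlotSample:
    """One plot (the MIL sample): image bags per channel + genotype + yield."""

    plot_id: str
    entry_id: str
    trial_id: str
    yield_t_ha: float | None
    bags: dict[str, list[ImageInstance]] = field(default_factory=dict)
    genotype: np.ndarray | None = None

    def __post_init__(self):
        for ch in CHANNELS:
            self.bags.setdefault(ch, [])

    @property
    def n_instances(self) -> int:
        n = sum(len(v) for v in self.bags.values())
        return n + (1 if self.genotype is not None else 0)


# ---------------------------------------------------------------------------
# genotype reading / writing
# ---------------------------------------------------------------------------

def read_genotype_matrix(path, fmt: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from a TSV dosage table or a (biallelic) VCF.

    VCF genotypes map 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> missing;
    multi-allelic records are rejected.
    """
    path = Path(path)
    if fmt == "tsv":
        return _read_genotype_tsv(path)
    if fmt == "vcf":
        return _read_genotype_vcf(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_genotype_tsv(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    except Exception as exc:  # pragma: no cover - passthrough context
        raise GenotypeParseError(f"cannot parse {path}: {exc}") from exc
    return GenotypeMatrix(
        line_ids=[str(i) for i in df.index],
        marker_ids=[str(c) for c in df.columns],
        dosages=df.to_numpy(dtype=np.float64),
    )


def _read_genotype_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    marker_ids: list[str] = []
    columns: list[np.ndarray] = []
    for i, variant in enumerate(vcf, start=1):
        if len(variant.ALT) != 1:
            raise GenotypeParseError(
                f"record {i} ({variant.ID or variant.POS}) is not biallelic; "
                "split or drop multi-allelic sites first"
            )
        marker_ids.append(variant.ID or f"{variant.CHROM}_{variant.POS}")
        col = np.full(len(line_ids), MISSING)
        for s, gt in enumerate(variant.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                continue
            col[s] = float(a + b)
        columns.append(col)
    dosages = (
        np.column_stack(columns) if columns else np.empty((len(line_ids), 0))
    )
    return GenotypeMatrix(line_ids, marker_ids, dosages)


def write_genotype_tsv(G: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(G.dosages, index=G.line_ids, columns=G.marker_ids)
    # integral dosages, "NA" for missing
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def filter_markers(
    G: GenotypeMatrix, max_missing: float = 0.40, max_het: float = 0.10
) -> GenotypeMatrix:
    """Keep markers with missing fraction < `max_missing` AND heterozygosity
    < `max_het` (both strict), preserving marker order."""
    for name, t in (("max_missing", max_missing), ("max_het", max_het)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must be in [0,1], got {t}")
    keep = (G.marker_missing_fraction() < max_missing) & (
        G.marker_heterozygosity() < max_het
    )
    return GenotypeMatrix(
        line_ids=list(G.line_ids),
        marker_ids=[m for m, k in zip(G.marker_ids, keep) if k],
        dosages=G.dosages[:, keep],
    )


def filter_lines(G: GenotypeMatrix, max_missing: float = 0.50) -> GenotypeMatrix:
    """Remove lines with *more than* `max_missing` missing data (boundary kept)."""
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError(f"max_missing must be in [0,1], got {max_missing}")
    keep = G.line_missing_fraction() <= max_missing
    if not keep.any():
        raise ValueError("all lines removed by the line-missingness filter")
    return GenotypeMatrix(
        line_ids=[l for l, k in zip(G.line_ids, keep) if k],
        marker_ids=list(G.marker_ids),
        dosages=G.dosages[keep],
    )


def impute_dosage(G: GenotypeMatrix) -> np.ndarray:
    """Replace each missing call with its marker's mean non-missing dosage."""
    mask = G.missing_mask
    if mask.all(axis=0).any():
        bad = [m for m, b in zip(G.marker_ids, mask.all(axis=0)) if b]
        raise ValueError(
            f"markers entirely missing ({bad[:3]}...); run filter_markers first"
        )
    out = G.dosages.copy()
    col_mean = np.nanmean(out, axis=0)
    idx = np.where(mask)
    out[idx] = col_mean[idx[1]]
    return out


# ---------------------------------------------------------------------------
# dataset loading
# ---------------------------------------------------------------------------

def read_image_instance(path, channel: str, date) -> ImageInstance:
    import tifffile

    pixels = tifffile.imread(str(path))
    return ImageInstance(channel=channel, date=date, pixels=pixels)


def write_image_instance(inst: ImageInstance, path) -> None:
    import tifffile

    tifffile.imwrite(str(path), inst.pixels.astype(np.float32))


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"plot_id", "entry_id", "trial_id", "yield"}
    if not required.issubset(df.columns):
        raise ValueError(f"phenotype table must have columns {sorted(required)}")
    return df


def load_dataset(
    manifest_path, genotype_path=None, genotype_format: str = "tsv"
) -> list[PlotSample]:
    """Assemble PlotSamples from a dataset manifest (+ optional genotypes).

    The manifest maps plot id -> {entry_id, trial_id, yield, instances:
    {channel: [[date, image path], ...]}}; image paths are relative to the
    manifest location.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    root = manifest_path.parent

    genotype = None
    imputed = None
    if genotype_path is not None:
        genotype = read_genotype_matrix(genotype_path, genotype_format)
        imputed = impute_dosage(genotype)
        line_index = {l: i for i, l in enumerate(genotype.line_ids)}

    samples: list[PlotSample] = []
    for plot_id in sorted(manifest):
        rec = manifest[plot_id]
        bags: dict[str, list[ImageInstance]] = {ch: [] for ch in CHANNELS}
        for ch, entries in rec.get("instances", {}).items():
            for date_str, rel in entries:
                img_path = root / rel
                if not img_path.exists():
                    raise FileNotFoundError(
                        f"plot {plot_id}: missing image file {rel}"
                    )
                bags[ch].append(
                    read_image_instance(img_path, ch, _dt.date.fromisoformat(date_str))
                )
        dosage = None
        if genotype is not None:
            if rec["entry_id"] in line_index:
                dosage = imputed[line_index[rec["entry_id"]]]
            else:
                warnings.warn(
                    f"plot {plot_id}: entry {rec['entry_id']} has no genotype",
                    stacklevel=2,
                )
        samples.append(
            PlotSample(
                plot_id=plot_id,
                entry_id=rec["entry_id"],
                trial_id=rec["trial_id"],
                yield_t_ha=rec.get("yield"),
                bags=bags,
                genotype=dosage,
            )
        )
    return samples
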