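"""Attention-based interpretation and selection-gain curves.

The attention weights of a trained model form a convex combination over a
plot's instances, so summing them within a data channel (or a flight date)
measures how much of the model's pooled representation each channel (or
date) contributed.  Selection-gain curves translate predictive accuracy into
the breeder's currency: the mean realized yield of the top-f fraction of
lines ranked by predicted yield.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import PlotSample
from .mil_model import CHANNEL_CATEGORIES, PheGeMIL

__all__ = [
    "AttentionSummary",
    "SelectionCurve",
    "attention_by_channel",
    "attention_by_date",
    "selection_gain_curve",
]


@dataclass
class AttentionSummary:
    """Mean attention mass per head, by channel or by date.

    `table` rows are heads; columns are channels (or ISO dates).  Masses are
    means over samples of the per-sample attention mass (which sums to one
    per head by the softmax partition).
    """

    table: pd.DataFrame
    n_samples: int
    kind: str  # "channel" | "date"

    def head_mean(self) -> pd.Series:
        return self.table.mean(axis=0)


def _forward_full(model: PheGeMIL, sample: PlotSample):
    _, result = model.forward(sample, train=False)
    return result


def attention_by_channel(model: PheGeMIL, samples: list[PlotSample]) -> AttentionSummary:
    """Per-head attention mass per data channel, averaged over samples.

    Full bags are used (no subsampling); the genotype instance is its own
    category.  Channels absent from a sample contribute exactly zero mass.
    """
    if not samples:
        raise ValueError("need at least one sample")
    n_heads = model.config.n_heads
    acc = np.zeros((n_heads, len(CHANNEL_CATEGORIES)))
    for sample in samples:
        result = _forward_full(model, sample)
        chan_idx = np.array(
            [CHANNEL_CATEGORIES.index(ch) for ch, _ in result.provenance]
        )
        for h, head in enumerate(result.heads):
            for c in range(len(CHANNEL_CATEGORIES)):
                acc[h, c] += head.weights[chan_idx == c].sum()
    acc /= len(samples)
    table = pd.DataFrame(
        acc,
        index=[f"head_{h}" for h in range(n_heads)],
        columns=list(CHANNEL_CATEGORIES),
    )
    return AttentionSummary(table=table, n_samples=len(samples), kind="channel")


def attention_by_date(
    model: PheGeMIL, samples: list[PlotSample], channel: str | None = None
) -> AttentionSummary:
    """Per-head attention mass per flight date, averaged over samples.

    Only dated (image) instances count and masses are renormalized within
    them per sample, so the genotype instance does not dilute the temporal
    picture.  With `channel` given, only that channel's instances are kept.
    """
    if not samples:
        raise ValueError("need at least one sample")
    n_heads = model.config.n_heads
    masses: dict[_dt.date, np.ndarray] = {}
    counted = 0
    for sample in samples:
        result = _forward_full(model, sample)
        keep = [
            i
            for i, (ch, d) in enumerate(result.provenance)
            if d is not None and (channel is None or ch == channel)
        ]
        if not keep:
            continue
        counted += 1
        for h, head in enumerate(result.heads):
            w = head.weights[keep]
            total = w.sum()
            if total <= 0:
                continue
            w = w / total
            for j, i in enumerate(keep):
                date = result.provenance[i][1]
                if date not in masses:
                    masses[date] = np.zeros(n_heads)
                masses[date][h] += w[j]
    if not masses:
        table = pd.DataFrame(
            np.zeros((n_heads, 0)), index=[f"head_{h}" for h in range(n_heads)]
        )
        return AttentionSummary(table=table, n_samples=0, kind="date")
    dates = sorted(masses)
    acc = np.column_stack([masses[d] / counted for d in dates])
    table = pd.DataFrame(
        acc,
        index=[f"head_{h}" for h in range(n_heads)],
        columns=[d.isoformat() for d in dates],
    )
    return AttentionSummary(table=table, n_samples=counted, kind="date")


@dataclass
class SelectionCurve:
    """Mean realized yield of the top-f selected entries per fraction f."""

    fractions: np.ndarray
    mean_yields: np.ndarray
    n_selected: np.ndarray
    source: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fraction": self.fractions,
                "mean_yield": self.mean_yields,
                "n_selected": self.n_selected,
            }
        )


def selection_gain_curve(
    predictions: np.ndarray,
    observations: np.ndarray,
    fractions: np.ndarray | None = None,
    entry_ids: list[str] | None = None,
    source: str = "",
) -> SelectionCurve:
    """Rank entries by predicted yield, select the top ceil(f*N), and report
    the mean observed yield of the selection for each fraction f.

    Ties in the predictions break by stable entry-id order.
    """
    pred = np.asarray(predictions, dtype=float)
    obs = np.asarray(observations, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("predictions and observations must align")
    if fractions is None:
        fractions = np.round(np.arange(0.05, 0.401, 0.05), 10)
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions <= 0) or np.any(fractions > 1):
        raise ValueError("selection fractions must lie in (0, 1]")
    n = len(pred)
    if entry_ids is None:
        entry_ids = [f"{i:06d}" for i in range(n)]
    # sort by (-prediction, entry id): deterministic tie-breaking
    order = sorted(range(n), key=lambda i: (-pred[i], entry_ids[i]))
    means, counts = [], []
    for f in fractions:
        k = int(np.ceil(f * n))
        sel = order[:k]
        means.append(float(obs[sel].mean()))
        counts.append(k)
    return SelectionCurve(
        fractions=fractions,
        mean_yields=np.array(means),
        n_selected=np.array(counts),
        source=source,
    )
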