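"""Marker fluorescence quantification and positivity calls.

Reporter intensities vary between organs and animals, so absolute
thresholds do not transfer.  Mean per-cell intensities (measured over
the nucleus mask for nuclear-localized reporters, the whole cell mask
for cytoplasmic ones) are therefore z-scored within each organ, and a
cell is "positive" when its z-score reaches the threshold (default 1:
at least one standard deviation above that organ's mean).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import LabeledVolume

__all__ = [
    "mean_marker_intensity",
    "call_positive",
    "cluster_marker_enrichment",
    "chi2_proportions",
]


def mean_marker_intensity(
    cell_labels: LabeledVolume,
    nucleus_labels: LabeledVolume,
    intensity: np.ndarray,
    localization: str = "cytoplasmic",
) -> pd.Series:
    """Per-cell mean marker intensity.

    The averaging mask is the segmented nucleus for ``localization=
    "nuclear"`` and the segmented cell for ``"cytoplasmic"``.  Cells
    whose mask is empty get a missing value with a warning.
    """
    if localization not in ("nuclear", "cytoplasmic"):
        raise ValueError("localization must be 'nuclear' or 'cytoplasmic'")
    masks = nucleus_labels if localization == "nuclear" else cell_labels
    if masks.labels.shape != np.shape(intensity):
        raise ValueError("labels and intensity volume must share a shape")
    cell_ids = cell_labels.ids
    with np.errstate(invalid="ignore"):  # empty masks divide by zero
        means = ndimage.mean(intensity, labels=masks.labels, index=cell_ids)
    counts = ndimage.sum_labels(
        np.ones_like(masks.labels, dtype=np.uint8), masks.labels, cell_ids
    )
    out = pd.Series(means, index=pd.Index(cell_ids, name="label"), dtype=float)
    empty = counts == 0
    if np.any(empty):
        warnings.warn(
            f"{int(empty.sum())} cells have no {localization} mask voxels"
        )
        out[empty] = np.nan
    return out


def call_positive(
    means: pd.Series | np.ndarray,
    organ_ids: np.ndarray | None = None,
    threshold: float = 1.0,
    inclusive: bool = True,
) -> pd.DataFrame:
    """Per-organ z-scores and positivity calls.

    z-scores use the population (1/n) standard deviation within each
    organ.  ``inclusive`` keeps z == threshold positive (the default
    "at least one standard deviation" reading).  Organs with zero
    intensity variance yield no positives, with a warning.
    """
    values = np.asarray(means, dtype=float)
    if organ_ids is None:
        organ_ids = np.zeros(len(values), dtype=int)
    organ_ids = np.asarray(organ_ids)
    z = np.full(len(values), np.nan)
    for org in np.unique(organ_ids):
        sel = organ_ids == org
        if sel.sum() < 2:
            raise ValueError(f"organ {org} has fewer than 2 cells")
        v = values[sel]
        sd = np.nanstd(v)
        if sd < 1e-15:
            warnings.warn(f"organ {org}: zero intensity variance, no positives")
            z[sel] = 0.0
            continue
        z[sel] = (v - np.nanmean(v)) / sd
    pos = z >= threshold if inclusive else z > threshold
    idx = means.index if isinstance(means, pd.Series) else None
    return pd.DataFrame(
        {"mean_intensity": values, "z_intensity": z, "positive": pos}, index=idx
    )


def cluster_marker_enrichment(
    positive: np.ndarray, cluster_labels: np.ndarray
) -> pd.DataFrame:
    """Positive-cell counts and fractions per shape cluster.

    ``fraction_of_cluster`` is positives over cluster size (how marked
    a cluster is); ``fraction_of_positives`` distributes the marker's
    cells over clusters (where the marked population lives).
    """
    positive = np.asarray(positive, dtype=bool)
    cluster_labels = np.asarray(cluster_labels)
    if len(positive) != len(cluster_labels):
        raise ValueError("inputs must have matching length")
    total_pos = int(positive.sum())
    rows = []
    for c in np.unique(cluster_labels):
        sel = cluster_labels == c
        n_pos = int(positive[sel].sum())
        rows.append({
            "cluster": int(c),
            "n_cells": int(sel.sum()),
            "n_positive": n_pos,
            "fraction_of_cluster": n_pos / sel.sum(),
            "fraction_of_positives": n_pos / total_pos if total_pos else 0.0,
        })
    return pd.DataFrame(rows)


def chi2_proportions(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-squared test on a 2D contingency table.

    No continuity correction; dof = (rows-1)(cols-1).  Rejected if any
    expected count is zero.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("need a 2D contingency table")
    expected = stats.contingency.expected_freq(table)
    if np.any(expected <= 0):
        raise ValueError("zero expected count: chi-squared is undefined")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)
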