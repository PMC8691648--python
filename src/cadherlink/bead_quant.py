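"""Bead-aggregation micrograph quantification.

Images of fluorescent-bead fields are thresholded to exclude background
(Otsu by default), aggregates are detected by 8-connected component
labeling, per-aggregate areas are measured in pixels, and replicate series
are summarized the way aggregation assays report them: per-replicate mean
aggregate area, then mean of means, SD and SEM across biological
replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "AggregateTable",
    "ReplicateStats",
    "EmptyImage",
    "quantify_image",
    "summarize_replicates",
    "summarize_manifest",
]

DEFAULT_MIN_SIZE = 4  # px


class EmptyImage(ValueError):
    pass


@dataclass
class AggregateTable:
    image_id: str
    areas: np.ndarray  # px per aggregate, min_size-filtered
    threshold_used: float
    labels: Optional[np.ndarray] = None

    @property
    def count(self) -> int:
        return len(self.areas)

    @property
    def mean_area(self) -> float:
        return float(np.mean(self.areas)) if self.count else 0.0


@dataclass
class ReplicateStats:
    condition: str
    replicate_means: np.ndarray
    mean_of_means: float
    sd: float
    sem: float
    n: int
    warnings: list = field(default_factory=list)


def quantify_image(
    image: np.ndarray,
    threshold: object = "auto",
    min_size: int = DEFAULT_MIN_SIZE,
    image_id: str = "",
    keep_labels: bool = False,
) -> AggregateTable:
    """Threshold a single-channel image and measure aggregate pixel areas.

    ``threshold='auto'`` uses Otsu; a numeric value is used directly
    (pixels strictly above it are foreground).  Components smaller than
    ``min_size`` pixels are discarded.
    """
    img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise EmptyImage("expected a non-empty single-channel 2-D image")
    if threshold == "auto":
        if np.ptp(img) == 0:
            # constant image: nothing above background by definition
            return AggregateTable(image_id, np.array([], int), float(img.flat[0]))
        thr = float(threshold_otsu(img))
    else:
        thr = float(threshold)
    mask = img > thr
    lab = label(mask, connectivity=2)  # 8-connectivity
    areas = np.array(
        [p.area for p in regionprops(lab) if p.area >= min_size], dtype=int
    )
    return AggregateTable(
        image_id=image_id,
        areas=np.sort(areas)[::-1],
        threshold_used=thr,
        labels=lab if keep_labels else None,
    )


def summarize_replicates(
    tables_by_replicate: Sequence[Sequence[AggregateTable]],
    condition: str = "",
) -> ReplicateStats:
    """Mean aggregate area per biological replicate (pooling that
    replicate's images), then mean of means, SD and SEM across replicates.
    With a single replicate the SEM is undefined and reported as 0 with a
    warning."""
    if not tables_by_replicate:
        raise ValueError("need at least one replicate")
    means = []
    for tables in tables_by_replicate:
        areas = np.concatenate([t.areas for t in tables]) if tables else np.array([])
        means.append(float(np.mean(areas)) if len(areas) else 0.0)
    means = np.asarray(means)
    n = len(means)
    notes = []
    if n == 1:
        sd = 0.0
        sem = 0.0
        notes.append("single replicate: SD/SEM undefined, reported as 0")
        warnings.warn(notes[0], stacklevel=2)
    else:
        sd = float(np.std(means, ddof=1))
        sem = sd / np.sqrt(n)
    return ReplicateStats(
        condition=condition,
        replicate_means=means,
        mean_of_means=float(np.mean(means)),
        sd=sd,
        sem=sem,
        n=n,
        warnings=notes,
    )


def summarize_manifest(
    manifest,
    threshold: object = "auto",
    min_size: int = DEFAULT_MIN_SIZE,
):
    """Run the full pipeline over a manifest DataFrame with columns
    (path, condition, replicate[, timepoint]); returns
    (per-image AggregateTables, {(condition[, timepoint]) -> ReplicateStats}).
    """
    import imageio.v3 as iio
    import pandas as pd

    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    group_keys = ["condition"] + (
        ["timepoint"] if "timepoint" in manifest.columns else []
    )
    tables = []
    stats = {}
    for key, grp in manifest.groupby(group_keys, sort=True):
        by_rep = []
        for _, rep_grp in grp.groupby("replicate", sort=True):
            rep_tables = []
            for _, row in rep_grp.iterrows():
                img = np.asarray(iio.imread(row["path"]))
                if img.ndim == 3:
                    img = img.mean(axis=-1)
                rep_tables.append(
                    quantify_image(img, threshold, min_size, image_id=row["path"])
                )
            tables.extend(rep_tables)
            by_rep.append(rep_tables)
        cond = key if isinstance(key, str) else "/".join(str(k) for k in key)
        stats[cond] = summarize_replicates(by_rep, condition=cond)
    return tables, stats
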