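"""Plant identity assignment and projected-area measurement.

Connected components of a cleaned binary mask are assigned stable plant
indices either automatically (numbered left to right by centroid x, ties by
centroid y) or from user-provided seed points (nearest seed wins).  Across a
time series, identities are propagated by nearest-centroid matching so that a
plant fragmenting into several components keeps one id.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import measure

from .session import CalibrationSpec, Frame

__all__ = [
    "PlantSeed",
    "LabeledMask",
    "TraitRecord",
    "label_auto",
    "label_seeded",
    "match_to_centroids",
    "measure_pra",
    "read_seed_file",
    "records_to_frame",
]


@dataclass(frozen=True)
class PlantSeed:
    """User-declared plant centre: id plus (x, y) pixel coordinates."""

    plant_id: int
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.plant_id <= 0:
            raise ValueError("plant_id must be a positive integer")


@dataclass
class LabeledMask:
    """Integer label raster (0 = background, k = plant k) plus declared ids."""

    labels: np.ndarray
    plant_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        present = set(np.unique(self.labels)) - {0}
        if not present <= set(self.plant_ids):
            raise ValueError(
                f"labels {sorted(present - set(self.plant_ids))} not among "
                f"declared plant ids"
            )

    @property
    def n_plants(self) -> int:
        return int(len(np.unique(self.labels)) - (0 in self.labels))

    def plant_mask(self, plant_id: int) -> np.ndarray:
        return self.labels == plant_id

    def area_px(self, plant_id: int) -> int:
        return int(np.count_nonzero(self.labels == plant_id))

    def centroids(self) -> dict[int, tuple[float, float]]:
        """Per-plant centroid as (y, x) row/column coordinates."""
        out = {}
        for pid in self.plant_ids:
            ys, xs = np.nonzero(self.labels == pid)
            if ys.size:
                out[pid] = (float(ys.mean()), float(xs.mean()))
        return out


@dataclass(frozen=True)
class TraitRecord:
    plant_id: int
    timestamp: dt.datetime
    frame_index: int
    period_index: int
    period_kind: str
    pra_px: float
    pra_mm2: float
    missing: bool = False


def _components(mask: np.ndarray):
    lab = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    return lab, measure.regionprops(lab)


def label_auto(mask: np.ndarray) -> LabeledMask:
    """Number components left to right (ascending centroid x, ties by y)."""
    lab, props = _components(mask)
    order = sorted(props, key=lambda p: (p.centroid[1], p.centroid[0]))
    out = np.zeros_like(lab)
    for new_id, p in enumerate(order, start=1):
        out[lab == p.label] = new_id
    return LabeledMask(out, tuple(range(1, len(order) + 1)))


def label_seeded(
    mask: np.ndarray,
    seeds: list[PlantSeed],
    max_dist: float = np.inf,
) -> LabeledMask:
    """Give each component the id of its nearest seed (centroid distance).

    Components farther than ``max_dist`` from every seed are dropped; a seed
    matching no component yields an empty label with a warning.
    """
    if not seeds:
        raise ValueError("seed list is empty")
    ids = [s.plant_id for s in seeds]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate plant_ids in seeds")
    lab, props = _components(mask)
    out = np.zeros_like(lab)
    matched: set[int] = set()
    for p in props:
        cy, cx = p.centroid
        dists = [np.hypot(cx - s.x, cy - s.y) for s in seeds]
        k = int(np.argmin(dists))
        if dists[k] <= max_dist:
            out[lab == p.label] = seeds[k].plant_id
            matched.add(seeds[k].plant_id)
    for s in seeds:
        if s.plant_id not in matched:
            warnings.warn(f"seed for plant {s.plant_id} matched no component")
    return LabeledMask(out, tuple(ids))


def match_to_centroids(
    mask: np.ndarray,
    centroids: dict[int, tuple[float, float]],
    max_dist: float = np.inf,
) -> LabeledMask:
    """Propagate identities: each component joins the nearest previous-frame
    plant centroid, so a fragmented plant keeps a single id."""
    if not centroids:
        raise ValueError("no reference centroids")
    lab, props = _components(mask)
    out = np.zeros_like(lab)
    pids = list(centroids)
    for p in props:
        cy, cx = p.centroid
        dists = [
            np.hypot(cx - centroids[pid][1], cy - centroids[pid][0]) for pid in pids
        ]
        k = int(np.argmin(dists))
        if dists[k] <= max_dist:
            out[lab == p.label] = pids[k]
    return LabeledMask(out, tuple(pids))


def measure_pra(
    labeled: LabeledMask,
    frame: Frame,
    calib: CalibrationSpec,
    period_index: int = -1,
    period_kind: str = "",
) -> list[TraitRecord]:
    """One record per declared plant; an absent label yields a missing record."""
    records = []
    counts = np.bincount(
        labeled.labels.ravel(), minlength=max(labeled.plant_ids, default=0) + 1
    )
    for pid in labeled.plant_ids:
        px = int(counts[pid]) if pid < len(counts) else 0
        records.append(
            TraitRecord(
                plant_id=pid,
                timestamp=frame.timestamp,
                frame_index=frame.frame_index,
                period_index=period_index,
                period_kind=period_kind,
                pra_px=float(px),
                pra_mm2=calib.px_to_mm2(px),
                missing=px == 0,
            )
        )
    return records


def read_seed_file(path: str | Path) -> list[PlantSeed]:
    """Whitespace-delimited seed file: ``plant_id x y`` per line, 0-based px."""
    seeds = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#")[0].strip()
        if not line:
            continue
        pid, x, y = line.split()
        seeds.append(PlantSeed(int(pid), float(x), float(y)))
    if not seeds:
        raise ValueError(f"no seeds in {path}")
    return seeds


def records_to_frame(records: list[TraitRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
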