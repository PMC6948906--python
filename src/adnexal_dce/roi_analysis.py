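"""Hot-spot ROI selection on Ktrans maps and per-lesion aggregation.

In clinical reading, small regions of interest are placed on the most
enhancing ("hot-spot") part of a lesion on the colour-coded Ktrans map so
that the measurement reflects the most vascularised tumour tissue rather
than an average over cysts and necrosis.  Here the placement is automated:
a greedy search selects a fixed number of small, connected, pairwise
disjoint neighbourhoods maximising mean Ktrans inside the lesion mask, and
per-lesion values are the mean over the ROI means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from adnexal_dce.pk_model import FIT_OK, ParameterMap, PKParams
from adnexal_dce.semiquant import EnhancementCurve, SemiQuantParams, compute_descriptors

__all__ = ["ROISet", "find_hotspots", "lesion_summary", "LesionSummary"]

#: Face-neighbour offsets (6-connectivity) in 3-D.
_NEIGHBOUR_OFFSETS = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
)


@dataclass
class ROISet:
    """Disjoint hot-spot ROIs for one lesion.

    ``masks`` are boolean volumes (one per ROI) ordered by descending mean
    map value; all ROIs lie within the lesion mask and are pairwise
    disjoint.
    """

    lesion_id: str
    masks: list[np.ndarray]
    roi_voxels: int
    source_map_id: str = ""

    def __post_init__(self) -> None:
        if not self.masks:
            raise ValueError("ROISet needs at least one mask")
        shape = self.masks[0].shape
        union = np.zeros(shape, dtype=int)
        for m in self.masks:
            if m.shape != shape:
                raise ValueError("ROI masks must share one shape")
            if not m.any():
                raise ValueError("ROI masks must be non-empty")
            union += m.astype(int)
        if union.max() > 1:
            raise ValueError("ROI masks must be pairwise disjoint")

    @property
    def n_rois(self) -> int:
        return len(self.masks)


def _grow_region(values: np.ndarray, available: np.ndarray,
                 seed: tuple[int, int, int], size: int) -> list[tuple] | None:
    """Grow a connected region from ``seed`` by repeatedly absorbing the
    available face-neighbour with the highest map value.  Ties break on the
    lowest flat index for determinism.  Returns None if the region cannot
    reach ``size``."""
    region = [seed]
    in_region = {seed}
    frontier: dict[tuple, float] = {}

    def add_neighbours(vox: tuple) -> None:
        for off in _NEIGHBOUR_OFFSETS:
            nb = (vox[0] + off[0], vox[1] + off[1], vox[2] + off[2])
            if nb in in_region or nb in frontier:
                continue
            if any(c < 0 or c >= s for c, s in zip(nb, values.shape)):
                continue
            if available[nb]:
                frontier[nb] = values[nb]

    add_neighbours(seed)
    while len(region) < size:
        if not frontier:
            return None
        best = min(frontier, key=lambda v: (-frontier[v], np.ravel_multi_index(v, values.shape)))
        del frontier[best]
        region.append(best)
        in_region.add(best)
        add_neighbours(best)
    return region


def find_hotspots(
    ktrans_map: ParameterMap | np.ndarray,
    lesion_mask: np.ndarray,
    n_rois: int = 3,
    roi_voxels: int = 9,
    lesion_id: str = "",
) -> ROISet:
    """Select disjoint connected hot-spot ROIs maximising mean Ktrans.

    Greedy strategy: every remaining lesion voxel seeds a candidate region
    grown by best-neighbour accretion to ``roi_voxels`` voxels; the
    candidate with the highest mean is kept and removed from the pool, and
    the search repeats for the next ROI.  ROIs are returned in descending
    order of mean Ktrans.  If the lesion cannot host the requested number
    of ROIs the count is reduced with a warning.
    """
    if isinstance(ktrans_map, ParameterMap):
        values = np.where(ktrans_map.ok, ktrans_map.ktrans, -np.inf)
    else:
        values = np.asarray(ktrans_map, dtype=float)
    lesion_mask = np.asarray(lesion_mask).astype(bool)
    if lesion_mask.shape != values.shape:
        raise ValueError("lesion mask shape must match the map")
    if not lesion_mask.any():
        raise ValueError("lesion mask is empty")
    if n_rois < 1 or roi_voxels < 1:
        raise ValueError("n_rois and roi_voxels must be positive")

    available = lesion_mask & np.isfinite(values)
    masks: list[np.ndarray] = []
    for _ in range(n_rois):
        best_region = None
        best_key = None
        for seed in map(tuple, np.argwhere(available)):
            region = _grow_region(values, available, seed, roi_voxels)
            if region is None:
                continue
            mean = float(np.mean([values[v] for v in region]))
            key = (-mean, np.ravel_multi_index(seed, values.shape))
            if best_key is None or key < best_key:
                best_key = key
                best_region = region
        if best_region is None:
            break
        mask = np.zeros(values.shape, dtype=bool)
        for v in best_region:
            mask[v] = True
        masks.append(mask)
        available &= ~mask

    if not masks:
        raise ValueError(
            "lesion cannot host a single connected ROI of the requested size"
        )
    if len(masks) < n_rois:
        warnings.warn(
            f"lesion only hosts {len(masks)} of {n_rois} requested ROIs",
            stacklevel=2,
        )
    return ROISet(lesion_id=lesion_id or "lesion", masks=masks,
                  roi_voxels=roi_voxels)


@dataclass(frozen=True)
class LesionSummary:
    """Per-lesion kinetic and descriptor values (mean over ROI means)."""

    lesion_id: str
    ktrans: float
    kep: float
    ve: float
    vp: float
    delta: float
    semiquant: SemiQuantParams

    def as_dict(self) -> dict[str, float]:
        out = {"ktrans": self.ktrans, "kep": self.kep, "ve": self.ve,
               "vp": self.vp, "delta": self.delta}
        out.update(self.semiquant.as_dict())
        return out


def _roi_mean(pmap: ParameterMap, attr: str, mask: np.ndarray) -> float:
    ok = mask & pmap.ok
    return float(getattr(pmap, attr)[ok].mean())


def lesion_summary(
    roiset: ROISet,
    maps: ParameterMap,
    series: np.ndarray,
    times: np.ndarray,
    injection_time: float,
    frame_interval: float,
) -> LesionSummary:
    """Aggregate ROI values to one record per lesion.

    Kinetic parameters are averaged within each ROI over successfully
    fitted voxels (failed voxels are excluded with a warning; a fully
    failed ROI is an error) and then across ROIs with equal weight.  The
    semi-quantitative descriptors are recomputed from each ROI's mean
    signal curve and likewise averaged across ROIs.
    """
    series = np.asarray(series, dtype=float)
    pk_means: dict[str, list[float]] = {k: [] for k in
                                        ("ktrans", "kep", "ve", "vp", "delta")}
    sq_rows: list[SemiQuantParams] = []
    for i, mask in enumerate(roiset.masks):
        ok = mask & maps.ok
        if not ok.any():
            raise ValueError(f"ROI {i} contains no successfully fitted voxel")
        if ok.sum() < mask.sum():
            warnings.warn(
                f"ROI {i}: excluding {int(mask.sum() - ok.sum())} failed voxel(s)",
                stacklevel=2,
            )
        for attr in pk_means:
            pk_means[attr].append(float(getattr(maps, attr)[ok].mean()))
        mean_curve = series[mask].mean(axis=0)
        sq_rows.append(compute_descriptors(EnhancementCurve(
            times=times, signal=mean_curve,
            injection_time=injection_time, frame_interval=frame_interval,
        )))

    sq_mean = SemiQuantParams(**{
        k: float(np.mean([getattr(r, k) for r in sq_rows]))
        for k in sq_rows[0].as_dict()
    })
    return LesionSummary(
        lesion_id=roiset.lesion_id,
        ktrans=float(np.mean(pk_means["ktrans"])),
        kep=float(np.mean(pk_means["kep"])),
        ve=float(np.mean(pk_means["ve"])),
        vp=float(np.mean(pk_means["vp"])),
        delta=float(np.mean(pk_means["delta"])),
        semiquant=sq_mean,
    )
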