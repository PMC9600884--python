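"""Scan-level flagging: region cleanup, per-slice pixel counts, run detection.

A scan is declared positive when at least ``sequence`` consecutive slices each
contain at least ``sig_count`` segmented filter pixels (both comparisons
inclusive).  Before counting, connected components smaller than
``min_region_area`` pixels are discarded from every slice to suppress
spurious specks; larger thresholds make the decision strictly harder to
satisfy, so raising either parameter can only turn positives into negatives.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from skimage import measure
from sklearn.base import BaseEstimator

from .volume_io import MaskVolume


@dataclasses.dataclass
class FlagParams:
    """Decision thresholds for scan flagging.

    sig_count
        Minimum segmented filter pixels per slice (typical settings: 200, 300).
    sequence
        Minimum number of consecutive qualifying slices (typical: 5, 7, 9).
    min_region_area
        Connected components smaller than this many pixels are removed before
        counting.
    connectivity
        2-D neighborhood for components: 8 (default, diagonals connect) or 4.
    """

    sig_count: int = 300
    sequence: int = 7
    min_region_area: int = 10
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.sig_count < 1 or self.sequence < 1:
            raise ValueError("sig_count and sequence must be >= 1")
        if self.min_region_area < 0:
            raise ValueError("min_region_area must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclasses.dataclass
class FlagReport:
    """Outcome of the flagging decision for one scan."""

    flagged: bool
    run_start_slice: int | None
    run_end_slice: int | None
    per_slice_counts: list[int]
    params_used: FlagParams
    scan_id: str = ""

    def to_dict(self) -> dict:
        return {
            "scan_id": self.scan_id,
            "flagged": bool(self.flagged),
            "run_start_slice": self.run_start_slice,
            "run_end_slice": self.run_end_slice,
            "per_slice_counts": [int(c) for c in self.per_slice_counts],
            "params_used": dataclasses.asdict(self.params_used),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def filter_regions(mask_slice: np.ndarray, params: FlagParams) -> np.ndarray:
    """Drop connected components with area below ``min_region_area``; keep the rest intact."""
    sl = np.asarray(mask_slice)
    fg = sl > 0
    if params.min_region_area <= 1 or not fg.any():
        return fg.astype(np.uint8)
    conn = 2 if params.connectivity == 8 else 1
    labeled = measure.label(fg, connectivity=conn)
    areas = np.bincount(labeled.ravel())
    keep = areas >= params.min_region_area
    keep[0] = False
    return keep[labeled].astype(np.uint8)


def slice_counts(mask_volume, params: FlagParams) -> np.ndarray:
    """Post-cleanup foreground pixel count for every slice of a mask volume."""
    labels = mask_volume.labels if isinstance(mask_volume, MaskVolume) else \
        np.asarray(mask_volume)
    return np.array(
        [int(filter_regions(sl, params).sum()) for sl in labels], dtype=np.int64)


def flag_scan(counts, sig_count: int, sequence: int):
    """Decide whether a run of ``sequence`` consecutive counts reaches ``sig_count``.

    Returns ``(flagged, run_start, run_end)`` where the run is the maximal
    stretch of qualifying slices containing the earliest qualifying window;
    ``(False, None, None)`` when no window qualifies (including when the scan
    has fewer slices than ``sequence`` — never an exception).
    """
    if sig_count < 1 or sequence < 1:
        raise ValueError("sig_count and sequence must be >= 1")
    counts = np.asarray(counts, dtype=np.int64)
    if counts.size == 0:
        raise ValueError("counts must be non-empty")
    ok = counts >= sig_count
    run_len = 0
    for i, good in enumerate(ok):
        run_len = run_len + 1 if good else 0
        if run_len >= sequence:
            start = i - run_len + 1
            end = i
            while end + 1 < counts.size and ok[end + 1]:
                end += 1
            return True, int(start), int(end)
    return False, None, None


def make_report(mask_volume, params: FlagParams, scan_id: str = "") -> FlagReport:
    """Clean the mask, count per slice, and run the flag decision."""
    counts = slice_counts(mask_volume, params)
    flagged, start, end = flag_scan(counts, params.sig_count, params.sequence)
    sid = scan_id or getattr(mask_volume, "scan_id", "")
    return FlagReport(
        flagged=flagged, run_start_slice=start, run_end_slice=end,
        per_slice_counts=list(counts), params_used=params, scan_id=sid)


class RunLengthFlagger(BaseEstimator):
    """Scan-level classifier over predicted mask volumes.

    Parameters mirror :class:`FlagParams`.  ``predict`` accepts a list of
    :class:`MaskVolume` (or raw binary 3-D arrays) and returns 0/1 decisions;
    ``report`` returns the full :class:`FlagReport` for one scan.  ``fit`` is
    a no-op (the decision rule has no learned state) and exists for pipeline
    compatibility.
    """

    def __init__(self, sig_count: int = 300, sequence: int = 7,
                 min_region_area: int = 10, connectivity: int = 8):
        self.sig_count = sig_count
        self.sequence = sequence
        self.min_region_area = min_region_area
        self.connectivity = connectivity

    def _params(self) -> FlagParams:
        return FlagParams(sig_count=self.sig_count, sequence=self.sequence,
                          min_region_area=self.min_region_area,
                          connectivity=self.connectivity)

    def fit(self, X=None, y=None):
        self.params_ = self._params()
        self.classes_ = np.array([0, 1])
        return self

    def report(self, mask_volume, scan_id: str = "") -> FlagReport:
        return make_report(mask_volume, self._params(), scan_id=scan_id)

    def predict(self, X) -> np.ndarray:
        if isinstance(X, (MaskVolume, np.ndarray)) and getattr(X, "ndim", 3) == 3:
            X = [X]
        return np.array([int(self.report(m).flagged) for m in X], dtype=np.int64)
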