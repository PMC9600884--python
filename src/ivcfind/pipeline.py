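"""End-to-end scan flagging: preprocess -> segment -> clean -> count -> decide."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .flagger import FlagParams, FlagReport, make_report
from .preprocess import PreprocessConfig, preprocess_volume
from .segmenter import UNetSegmenter
from .volume_io import CTVolume, load_dicom_series, load_nifti


def _load_scan(ct_path) -> CTVolume:
    p = Path(ct_path)
    if p.is_dir():
        return load_dicom_series(p)
    return load_nifti(p)


def write_overlays(volume: CTVolume, mask, report: FlagReport, out_dir) -> list[Path]:
    """Write grayscale PNGs of the detected run with the segmentation in red."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = mask.labels if hasattr(mask, "labels") else np.asarray(mask)
    written = []
    if not report.flagged:
        return written
    for idx in range(report.run_start_slice, report.run_end_slice + 1):
        sl = volume.voxels[idx]
        lo, hi = float(sl.min()), float(sl.max())
        gray = np.zeros_like(sl) if hi == lo else (sl - lo) / (hi - lo)
        rgb = np.stack([gray] * 3, axis=-1)
        rgb[labels[idx] > 0] = [1.0, 0.0, 0.0]
        path = out_dir / f"{report.scan_id or 'scan'}_slice{idx:04d}.png"
        iio.imwrite(path, (rgb * 255).astype(np.uint8))
        written.append(path)
    return written


def run_pipeline(ct_path, segmenter: UNetSegmenter,
                 preprocess_config: PreprocessConfig | None = None,
                 flag_params: FlagParams | None = None,
                 overlay_dir=None) -> FlagReport:
    """Flag one scan from disk with a fitted segmenter.

    Chains preprocessing, per-slice UNet prediction, region cleanup, per-slice
    counting and the consecutive-run decision; optionally writes PNG overlays
    of the detected run.  Slice indices in the report refer to the processed
    grid (the model's slice axis), not the native scan.
    """
    params = flag_params or FlagParams()
    volume = _load_scan(ct_path)
    try:
        processed = preprocess_volume(volume, None, preprocess_config)
        pred = segmenter.predict_volume(processed)
        report = make_report(pred, params, scan_id=volume.scan_id)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed for scan {volume.scan_id!r}: {exc}") from exc
    if overlay_dir is not None and report.flagged:
        write_overlays(processed, pred, report, overlay_dir)
    return report
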