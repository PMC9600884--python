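"""Synthetic CT phantoms with ground truth for every pipeline stage.

Each phantom is a soft-tissue body ellipse (around 0..+80 HU) on an air
background, a bright spine-like column posterior of center, optionally a
metal IVC filter — rendered as a cone of ring cross-sections with strut dots,
HU well above 2500 so hard normalization clips it to 1.0 — spanning a
contiguous run of slices near the volume center, and optionally a ring-like
calcification confuser near the spine that mimics the false-positive
mechanism seen around the spinal foramen.  The mask marks exactly the filter
voxels; the spine and calcification stay background.

This is an idealisation: no beam hardening, streak artifacts, couch, or
anatomy beyond the body/spine blobs.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .volume_io import CTVolume, MaskVolume


@dataclasses.dataclass
class FilterSpec:
    """Conical ring-and-strut metal structure."""

    apex_slice: int = 56
    span_slices: int = 16
    max_ring_radius_px: float = 30.0
    ring_thickness_px: float = 4.0
    n_struts: int = 6
    strut_thickness_px: float = 2.0
    hu: float = 3000.0


@dataclasses.dataclass
class CalcificationSpec:
    """Ring-like calcification confuser near the spine."""

    start_slice: int = 70
    span_slices: int = 8
    ring_radius_px: float = 12.0
    thickness_px: float = 3.0
    hu: float = 1300.0


@dataclasses.dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (128, 512, 512)
    spacing_mm: tuple[float, float, float] = (2.5, 1.0, 1.0)
    body_hu_mean: float = 40.0
    body_hu_std: float = 20.0
    air_hu: float = -1000.0
    spine_offset_rows: float = 0.22     # fraction of height, posterior of center
    spine_radius_px: float = 20.0
    spine_hu: float = 700.0
    filter: FilterSpec | None = dataclasses.field(default_factory=FilterSpec)
    calcification: CalcificationSpec | None = None
    noise_std: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.filter, dict):
            self.filter = FilterSpec(**self.filter)
        if isinstance(self.calcification, dict):
            self.calcification = CalcificationSpec(**self.calcification)
        if len(self.shape) != 3 or min(self.shape) < 1:
            raise ValueError("shape must be 3 positive extents")
        if self.filter is not None:
            f = self.filter
            if f.span_slices < 1:
                raise ValueError("filter span must be >= 1")
            if f.apex_slice < 0 or f.apex_slice + f.span_slices > self.shape[0]:
                raise ValueError(
                    f"filter slices [{f.apex_slice}, {f.apex_slice + f.span_slices}) "
                    f"exceed volume with {self.shape[0]} slices")
            if f.max_ring_radius_px + f.ring_thickness_px > min(self.shape[1:]) / 2:
                raise ValueError("filter ring does not fit inside the volume in-plane")


def ring_radius_at(f: FilterSpec, k: int) -> float:
    """Ring radius on the k-th slice of the span: cone from half to full radius."""
    if f.span_slices == 1:
        return f.max_ring_radius_px
    return f.max_ring_radius_px * (0.5 + 0.5 * k / (f.span_slices - 1))


def expected_ring_area(f: FilterSpec, k: int) -> float:
    """Analytic pixel area of the ring annulus on span slice k (struts excluded)."""
    r = ring_radius_at(f, k)
    t = f.ring_thickness_px
    return np.pi * t * (2 * r - t)


def _render_filter_slice(dist, ang, f: FilterSpec, k: int) -> np.ndarray:
    r = ring_radius_at(f, k)
    out = (dist <= r) & (dist >= r - f.ring_thickness_px)
    # strut cross-sections: small dots sitting just inside the ring
    for j in range(f.n_struts):
        theta = 2 * np.pi * j / f.n_struts
        cy = (r - f.ring_thickness_px / 2) * np.sin(theta)
        cx = (r - f.ring_thickness_px / 2) * np.cos(theta)
        out |= (dist * np.cos(ang) - cx) ** 2 + (dist * np.sin(ang) - cy) ** 2 \
            <= f.strut_thickness_px ** 2
    return out


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, MaskVolume]:
    """Render a phantom volume and its ground-truth filter mask (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    n, h, w = spec.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0

    body = (((yy - cy) / (0.42 * h)) ** 2 + ((xx - cx) / (0.46 * w)) ** 2) <= 1.0
    vox = np.full((n, h, w), spec.air_hu, dtype=np.float32)
    vox[:, body] = spec.body_hu_mean
    vox += rng.normal(0.0, spec.noise_std, size=vox.shape).astype(np.float32)
    vox[:, body] += rng.normal(
        0.0, spec.body_hu_std, size=(n, int(body.sum()))).astype(np.float32)

    sy = cy + spec.spine_offset_rows * h
    spine = ((yy - sy) ** 2 + (xx - cx) ** 2) <= spec.spine_radius_px ** 2
    vox[:, spine] = spec.spine_hu

    if spec.calcification is not None:
        c = spec.calcification
        stop = min(n, c.start_slice + c.span_slices)
        cdist = np.hypot(yy - (sy - spec.spine_radius_px - c.ring_radius_px), xx - cx)
        cring = (cdist <= c.ring_radius_px) & (cdist >= c.ring_radius_px - c.thickness_px)
        vox[c.start_slice:stop, cring] = c.hu

    labels = np.zeros((n, h, w), dtype=np.uint8)
    if spec.filter is not None:
        f = spec.filter
        dist = np.hypot(yy - cy, xx - cx)
        ang = np.arctan2(yy - cy, xx - cx)
        for k in range(f.span_slices):
            fg = _render_filter_slice(dist, ang, f, k)
            vox[f.apex_slice + k][fg] = f.hu
            labels[f.apex_slice + k][fg] = 1

    sid = f"phantom-{spec.seed}"
    return (
        CTVolume(voxels=vox, spacing=spec.spacing_mm, cranial_first=True, scan_id=sid),
        MaskVolume(labels=labels, spacing=spec.spacing_mm, scan_id=sid),
    )


def generate_corpus(n_positive: int, n_negative: int,
                    spec_ranges: dict | None = None, seed: int = 0,
                    base_spec: PhantomSpec | None = None):
    """Draw a reproducible corpus of phantoms with randomized geometry.

    ``spec_ranges`` maps a subset of {"apex_slice", "span_slices",
    "max_ring_radius_px", "noise_std", "calcification_probability"} to
    ``(low, high)`` tuples (probability is a scalar); unset keys fall back to
    defaults derived from ``base_spec``.  Returns a list of
    ``(CTVolume, MaskVolume, label)`` with label 1 iff a filter is present.
    """
    rng = np.random.default_rng(seed)
    ranges = dict(spec_ranges or {})
    base = base_spec or PhantomSpec()
    base_filter = base.filter or FilterSpec()
    n_slices = base.shape[0]
    out = []
    for i in range(n_positive + n_negative):
        positive = i < n_positive
        span_lo, span_hi = ranges.get(
            "span_slices", (base_filter.span_slices, base_filter.span_slices))
        span = int(rng.integers(span_lo, span_hi + 1))
        apex_lo, apex_hi = ranges.get(
            "apex_slice", (max(0, n_slices // 2 - span), n_slices // 2))
        apex = int(rng.integers(apex_lo, max(apex_lo, min(apex_hi, n_slices - span)) + 1))
        r_lo, r_hi = ranges.get(
            "max_ring_radius_px",
            (base_filter.max_ring_radius_px, base_filter.max_ring_radius_px))
        noise_lo, noise_hi = ranges.get("noise_std", (base.noise_std, base.noise_std))
        p_calc = float(ranges.get("calcification_probability", 0.0))
        has_calc = rng.random() < p_calc

        calc = None
        if has_calc:
            calc = CalcificationSpec(
                start_slice=int(rng.integers(0, max(1, n_slices - 8))),
                ring_radius_px=base.spine_radius_px * 0.6,
                thickness_px=2.0,
            )
        spec = dataclasses.replace(
            base,
            filter=FilterSpec(
                apex_slice=apex, span_slices=span,
                max_ring_radius_px=float(rng.uniform(r_lo, r_hi)),
                ring_thickness_px=base_filter.ring_thickness_px,
                n_struts=base_filter.n_struts,
                strut_thickness_px=base_filter.strut_thickness_px,
                hu=base_filter.hu,
            ) if positive else None,
            calcification=calc,
            noise_std=float(rng.uniform(noise_lo, noise_hi)),
            seed=int(rng.integers(2 ** 31)),
        )
        vol, mask = generate_phantom(spec)
        vol.scan_id = mask.scan_id = f"corpus-{seed}-{i:03d}"
        out.append((vol, mask, int(positive)))
    return out
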