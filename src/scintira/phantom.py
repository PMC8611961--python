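"""Planar gamma-camera phantom rendering.

Each patient is rendered as six views: a schematic anterior whole-body
image (stick skeleton over soft-tissue background) plus spot views of
both hands, both feet and the posterior pelvis.  Around every visible,
non-excluded joint the local background is cleared and a Gaussian hotspot
is laid down whose amplitude is normalized so that, noise-free, the mean
count inside the nominal circular ROI divided by the reference-bone count
level equals the joint's true uptake ratio exactly.  Optional Poisson
noise turns the mean-count image into a counting realization.

Counts are stored as 16-bit unsigned integers (the acquisition format);
noise-free images are rounded mean counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .atlas import JointAtlas
from .cohort import PatientTruth
from .config import RenderConfig, config_hash
from .errors import RenderingError


@dataclass
class PlanarScan:
    """One planar count image."""

    counts: np.ndarray  # 2-D unsigned integer grid
    view: str
    pixel_size_mm: float

    def __post_init__(self):
        if self.counts.ndim != 2:
            raise RenderingError(f"scan {self.view}: counts must be 2-D")
        if np.any(np.asarray(self.counts) < 0):
            raise RenderingError(f"scan {self.view}: negative counts")


@dataclass
class ScanSet:
    """All views of one patient plus provenance metadata."""

    patient_id: str
    scans: dict[str, PlanarScan]
    meta: dict = field(default_factory=dict)

    def __getitem__(self, view: str) -> PlanarScan:
        return self.scans[view]

    def __contains__(self, view: str) -> bool:
        return view in self.scans


def disk_mask(shape: tuple[int, int], center: tuple[float, float],
              radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Integer pixel coordinates whose centers lie within ``radius`` (inclusive)."""
    cy, cx = center
    r0 = max(0, int(np.floor(cy - radius)))
    r1 = min(shape[0] - 1, int(np.ceil(cy + radius)))
    c0 = max(0, int(np.floor(cx - radius)))
    c1 = min(shape[1] - 1, int(np.ceil(cx + radius)))
    rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    inside = (rr - cy) ** 2 + (cc - cx) ** 2 <= radius**2 + 1e-9
    return rr[inside], cc[inside]


def _wholebody_template(shape: tuple[int, int], background: float,
                        bone: float) -> np.ndarray:
    """Soft-tissue background with a schematic stick skeleton."""
    img = np.full(shape, background, dtype=float)

    def bar(r0, r1, c0, c1):
        img[r0 : r1 + 1, c0 : c1 + 1] = bone

    bar(10, 26, 34, 46)  # head
    bar(36, 118, 38, 42)  # spine
    bar(39, 41, 20, 60)  # clavicles
    bar(114, 120, 26, 54)  # pelvis
    for c0 in (26, 50):  # femora and tibiae
        bar(104, 150, c0, c0 + 4)
        bar(150, 205, c0, c0 + 4)
    for c0 in (11, 66):  # humeri
        bar(46, 72, c0, c0 + 3)
    return img


_TEMPLATE_CACHE: dict[tuple, np.ndarray] = {}


def _base_template(view: str, rc: RenderConfig) -> np.ndarray:
    key = (view, rc.view_shapes[view], rc.background_count_level, rc.bone_count_level)
    if key not in _TEMPLATE_CACHE:
        shape = rc.view_shapes[view]
        if view == "wholebody_anterior":
            img = _wholebody_template(shape, rc.background_count_level,
                                      rc.bone_count_level)
        else:
            img = np.full(shape, rc.background_count_level, dtype=float)
        _TEMPLATE_CACHE[key] = img
    return _TEMPLATE_CACHE[key].copy()


def render_scanset(patient: PatientTruth, atlas: JointAtlas, rc: RenderConfig,
                   seed: int | None = None) -> ScanSet:
    """Render all views of one patient; deterministic given (config, seed).

    The per-patient noise stream is derived from ``(seed or rc.seed,
    patient.index)`` so that cohort renderings are reproducible patient by
    patient.
    """
    base_seed = rc.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([base_seed, patient.index]))

    views: dict[str, PlanarScan] = {}
    for view, shape in rc.view_shapes.items():
        lam = _base_template(view, rc)
        joints = [j for j in atlas.joints_in_view(view)
                  if j.joint_id not in patient.excluded_joints]
        # clear background around every hotspot first so that neighbouring
        # punch-outs cannot erase already-drawn hotspots
        for j in joints:
            if not (0 <= j.row < shape[0] and 0 <= j.col < shape[1]):
                raise RenderingError(
                    f"landmark of joint {j.joint_id} outside view {view}"
                )
            rr, cc = disk_mask(shape, (j.row, j.col), 2 * j.roi_radius + 1)
            lam[rr, cc] = 0.0
        for j in joints:
            ratio = patient.true_ratios.get(j.joint_id)
            if ratio is None:
                raise RenderingError(f"joint {j.joint_id} has no true ratio")
            target_mean = ratio * rc.bone_count_level
            roi_rr, roi_cc = disk_mask(shape, (j.row, j.col), j.roi_radius)
            g_roi = np.exp(
                -((roi_rr - j.row) ** 2 + (roi_cc - j.col) ** 2)
                / (2.0 * rc.hotspot_kernel_sigma**2)
            )
            amplitude = target_mean * roi_rr.size / g_roi.sum()
            rr, cc = disk_mask(shape, (j.row, j.col), 2 * j.roi_radius + 1)
            g = np.exp(
                -((rr - j.row) ** 2 + (cc - j.col) ** 2)
                / (2.0 * rc.hotspot_kernel_sigma**2)
            )
            lam[rr, cc] += amplitude * g

        if rc.poisson_noise:
            counts = rng.poisson(lam).astype(np.uint16)
        else:
            counts = np.rint(lam).astype(np.uint16)
        views[view] = PlanarScan(counts=counts, view=view,
                                 pixel_size_mm=rc.pixel_size_mm[view])

    meta = {
        "patient_id": patient.patient_id,
        "seed": int(base_seed),
        "patient_index": int(patient.index),
        "config_hash": config_hash(rc),
        "poisson_noise": bool(rc.poisson_noise),
    }
    return ScanSet(patient_id=patient.patient_id, scans=views, meta=meta)


# ------------------------------------------------------------------ disk IO


def write_scanset(scanset: ScanSet, out_dir: str | Path) -> list[Path]:
    """One 16-bit grayscale TIFF per view plus a JSON sidecar each."""
    out = Path(out_dir) / scanset.patient_id
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for view, scan in scanset.scans.items():
        tif = out / f"{view}.tif"
        tifffile.imwrite(tif, scan.counts.astype(np.uint16))
        sidecar = {
            "view": view,
            "pixel_size_mm": scan.pixel_size_mm,
            "shape": list(scan.counts.shape),
            **scanset.meta,
        }
        (out / f"{view}.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
        written.extend([tif, out / f"{view}.json"])
    return written


def read_scanset(patient_dir: str | Path) -> ScanSet:
    patient_dir = Path(patient_dir)
    scans = {}
    meta: dict = {}
    for tif in sorted(patient_dir.glob("*.tif")):
        sidecar = json.loads((patient_dir / f"{tif.stem}.json").read_text())
        scans[sidecar["view"]] = PlanarScan(
            counts=tifffile.imread(tif),
            view=sidecar["view"],
            pixel_size_mm=float(sidecar["pixel_size_mm"]),
        )
        meta = {k: sidecar[k] for k in ("patient_id", "seed", "config_hash")
                if k in sidecar}
    if not scans:
        raise RenderingError(f"no TIFF views found under {patient_dir}")
    return ScanSet(patient_id=meta.get("patient_id", patient_dir.name),
                   scans=scans, meta=meta)
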