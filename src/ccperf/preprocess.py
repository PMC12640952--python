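"""Preprocessing stages: aorta ROI detection, temporal registration,
myocardium/aorta segmentation (pluggable external masks with a classical
fallback), landmark detection and short-axis reorientation.

Coordinate conventions: arrays are (t, z, y, x), voxel indices 0-based,
spacing is (dz, dy, dx) in mm. In-plane angles are degrees from
``atan2(y - cy, x - cx)``, wrapped to [0, 360).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.registration import phase_cross_correlation

from .errors import DegenerateInputError, GeometryError, InputError
from .kinetics import Curve

LABEL_BACKGROUND, LABEL_MYOCARDIUM, LABEL_LV_BLOOD, LABEL_AORTA = 0, 1, 2, 3


@dataclass
class HeartMasks:
    """Label volume {0 background, 1 myocardium, 2 LV blood pool, 3 aorta}."""
    labels: np.ndarray
    spacing_mm: Tuple[float, float, float]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise InputError("label volume must be 3-D (z, y, x)")
        if not np.isin(np.unique(self.labels), [0, 1, 2, 3]).all():
            raise InputError("labels must be within {0, 1, 2, 3}")

    @property
    def myocardium(self) -> np.ndarray:
        return self.labels == LABEL_MYOCARDIUM

    @property
    def lv_blood(self) -> np.ndarray:
        return self.labels == LABEL_LV_BLOOD

    @property
    def aorta(self) -> np.ndarray:
        return self.labels == LABEL_AORTA


@dataclass
class Landmarks:
    """LV center and the anterior/inferior RV insertion points (voxels).

    The insertion angles fix the angular origin of the AHA segmentation.
    """
    lv_center: Tuple[float, float, float]          # (z, y, x)
    septum_upper: Tuple[float, float, float]       # anterior insertion
    septum_lower: Tuple[float, float, float]       # inferior insertion
    anterior_angle_deg: float
    inferior_angle_deg: float

    def __post_init__(self):
        if np.allclose(self.septum_upper, self.septum_lower):
            raise GeometryError("septal points must be distinct")


@dataclass
class AortaROI:
    center_vox: Tuple[float, float, float]
    radius_vox: float
    mask: np.ndarray
    aif: Curve


# ---------------------------------------------------------------------------
# (i) aorta ROI detection
# ---------------------------------------------------------------------------

def roi_tac(study, mask: np.ndarray, onset_fraction: float = 0.05) -> Curve:
    """Baseline-subtracted mean TAC over a boolean ROI.

    The baseline is the mean over pre-arrival frames: every frame strictly
    before the first one exceeding ``onset_fraction`` of the enhancement
    range (late washout/recirculation frames never enter the baseline)."""
    raw = study.frames[:, mask].mean(axis=1)
    lo, hi = raw.min(), raw.max()
    if hi - lo <= 0:
        return Curve(study.frame_times_s, np.zeros_like(raw))
    first = int(np.argmax(raw >= lo + onset_fraction * (hi - lo)))
    baseline = raw[:first].mean() if first > 0 else raw[0]
    return Curve(study.frame_times_s, raw - baseline)


def _slice_circularity(mask2d: np.ndarray) -> float:
    area = float(mask2d.sum())
    if area < 4:
        return 0.0
    per = measure.perimeter(mask2d)
    if per <= 0:
        return 0.0
    return float(min(4 * np.pi * area / per ** 2, 1.2))


def detect_aorta_roi(study, min_enhancement_hu: float = 100.0,
                     range_fraction: float = 0.5,
                     circularity_min: float = 0.6) -> AortaROI:
    """Locate the aorta as the most compact, circular high-enhancement pool.

    Voxels are ranked by temporal enhancement range, thresholded and grouped
    into connected components; each candidate is scored by mean per-slice
    circularity, and among circular candidates the one with the smallest
    cross-section wins (the ascending aorta is smaller than the LV pool in
    short-axis sections). The ROI's mean TAC, baseline-subtracted, is the AIF.
    """
    if study.n_frames < 10:
        raise InputError("need at least 10 frames for AIF detection")
    rng_map = study.frames.max(axis=0) - study.frames.min(axis=0)
    peak = float(rng_map.max())
    if peak < min_enhancement_hu:
        raise DegenerateInputError("no enhancing region found")
    cand = rng_map > range_fraction * peak
    lab, n = ndimage.label(cand)
    candidates = []  # (circularity, mean slice area, component)
    for comp_id in range(1, n + 1):
        comp = lab == comp_id
        if comp.sum() < 8:
            continue
        zs = np.unique(np.nonzero(comp)[0])
        circ = float(np.mean([_slice_circularity(comp[z]) for z in zs]))
        area = float(comp.sum() / zs.size)
        candidates.append((circ, area, comp))
    if not candidates:
        raise DegenerateInputError("no enhancing region found")
    circular = [c for c in candidates if c[0] >= circularity_min]
    if circular:
        comp = min(circular, key=lambda c: c[1])[2]
    else:
        comp = max(candidates, key=lambda c: c[0])[2]
    center = ndimage.center_of_mass(comp)
    zs = np.unique(np.nonzero(comp)[0])
    radius = float(np.sqrt(comp.sum() / zs.size / np.pi))
    # shave the rim: boundary voxels are diluted by partial volume / motion
    cross = np.zeros((1, 3, 3), dtype=bool)
    cross[0] = [[0, 1, 0], [1, 1, 1], [0, 1, 0]]
    core = ndimage.binary_erosion(comp, structure=cross)
    if core.sum() >= 8:
        comp = core
    return AortaROI(tuple(center), radius, comp, roi_tac(study, comp))


# ---------------------------------------------------------------------------
# (ii) temporal registration
# ---------------------------------------------------------------------------

def peak_enhancement_frame(study) -> int:
    """Index of the frame with maximal mean enhancement over the volume."""
    means = study.frames.reshape(study.n_frames, -1).mean(axis=1)
    return int(np.argmax(means))


def register_temporal(study, reference="peak", upsample_factor: int = 10):
    """Translation-only registration of every frame to the reference by
    phase correlation. Returns (registered study, per-frame shifts) where
    ``shifts[t]`` is the (z, y, x) translation applied to frame t.
    """
    ref_idx = peak_enhancement_frame(study) if reference == "peak" else int(reference)
    if not (0 <= ref_idx < study.n_frames):
        raise InputError("reference frame index out of range")
    # edge-padding breaks the FFT's circular wrap-around, which would alias
    # shifts comparable to a short axis extent (e.g. few-slice stacks)
    pad = tuple(max(4, s // 4) for s in study.frames.shape[1:])
    pw = tuple((p, p) for p in pad)
    ref = np.pad(study.frames[ref_idx], pw, mode="edge")
    out = np.empty_like(study.frames)
    shifts = np.zeros((study.n_frames, 3))
    for t in range(study.n_frames):
        frame = study.frames[t]
        if t == ref_idx or float(frame.std()) == 0.0:
            out[t] = frame
            continue
        shift, _, _ = phase_cross_correlation(
            ref, np.pad(frame, pw, mode="edge"),
            upsample_factor=upsample_factor, normalization=None)
        shifts[t] = shift
        if np.any(shift):
            out[t] = ndimage.shift(frame, shift, order=1, mode="nearest")
        else:
            out[t] = frame
    return study.copy_with(frames=out), shifts


# ---------------------------------------------------------------------------
# (iii) segmentation
# ---------------------------------------------------------------------------

def _estimate_noise_sd(study) -> float:
    """Temporal std over the first quartile of frames, medianed spatially."""
    k = max(2, study.n_frames // 4)
    return float(np.median(study.frames[:k].std(axis=0)))


def _fallback_segment(study, fg_hu: float = 10.0,
                      myo_width_mm: float = 16.0) -> HeartMasks:
    peak = study.frames[peak_enhancement_frame(study)]
    sigma = (0.0, 1.0, 1.0) if _estimate_noise_sd(study) > 5.0 else 0.0
    vol = ndimage.gaussian_filter(peak, sigma) if np.any(sigma) else peak
    fg = vol > fg_hu
    if fg.sum() < 16:
        raise DegenerateInputError("no foreground voxels to segment")
    thr = threshold_otsu(vol[fg])
    blood = vol > thr
    lab, n = ndimage.label(blood)
    if n < 2:
        raise DegenerateInputError("could not separate LV pool and aorta")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
    order = np.argsort(sizes)[::-1] + 1
    lv = lab == order[0]
    # aorta: most circular of the remaining blood components
    best_c, aorta = -1.0, None
    for comp_id in order[1:]:
        comp = lab == comp_id
        if comp.sum() < 8:
            continue
        zs = np.unique(np.nonzero(comp)[0])
        c = np.mean([_slice_circularity(comp[z]) for z in zs])
        if c > best_c:
            best_c, aorta = c, comp
    if aorta is None:
        raise DegenerateInputError("could not identify the aorta")

    dz, dy, dx = study.spacing_mm
    it = int(np.ceil(myo_width_mm / min(dy, dx)))
    band = fg & ~blood
    myo = np.zeros_like(band)
    for z in range(band.shape[0]):
        if not lv[z].any():
            continue
        window = ndimage.binary_dilation(lv[z], iterations=it)
        cand = band[z] & window
        lab2, n2 = ndimage.label(cand)
        touch = np.unique(lab2[ndimage.binary_dilation(lv[z], iterations=2)])
        touch = touch[touch > 0]
        for comp_id in touch:
            myo[z] |= lab2 == comp_id
    if not myo.any():
        raise DegenerateInputError("fallback segmentation found no myocardium")
    labels = np.zeros(peak.shape, dtype=np.int16)
    labels[myo] = LABEL_MYOCARDIUM
    labels[lv] = LABEL_LV_BLOOD
    labels[aorta] = LABEL_AORTA
    return HeartMasks(labels, tuple(study.spacing_mm))


def segment_heart(study, method: str = "fallback",
                  external_masks: Optional[HeartMasks] = None) -> HeartMasks:
    """Myocardium/aorta segmentation.

    ``external`` passes through a supplied label volume (the integration point
    for any trained model's output) after geometry validation; ``fallback``
    segments the peak-enhancement frame with thresholding + morphology.
    """
    if method == "external":
        if external_masks is None:
            raise InputError("external method requires external_masks")
        if external_masks.labels.shape != study.frames.shape[1:]:
            raise GeometryError("external masks do not match study geometry")
        if not external_masks.myocardium.any():
            raise InputError("external masks contain no myocardium")
        return external_masks
    if method == "fallback":
        return _fallback_segment(study)
    raise InputError(f"unknown segmentation method: {method!r}")


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def _outer_boundary_point(masks: HeartMasks, angle_deg: float,
                          z: float) -> Tuple[float, float, float]:
    myo = masks.myocardium
    _, cy, cx = ndimage.center_of_mass(masks.lv_blood)
    zs, ys, xs = np.nonzero(myo)
    r = np.hypot(ys - cy, xs - cx)
    ang = np.degrees(np.arctan2(ys - cy, xs - cx)) % 360.0
    d = np.abs((ang - angle_deg + 180.0) % 360.0 - 180.0)
    sel = d < 10.0
    if not sel.any():
        sel = d < 30.0
    rmax = r[sel].max()
    th = np.radians(angle_deg)
    return (float(z), float(cy + rmax * np.sin(th)), float(cx + rmax * np.cos(th)))


def _angular_span(angles_deg: np.ndarray) -> Tuple[float, float]:
    """Endpoints of the tightest circular arc covering the samples."""
    a = np.sort(np.asarray(angles_deg) % 360.0)
    gaps = np.diff(np.concatenate([a, [a[0] + 360.0]]))
    i = int(np.argmax(gaps))
    start = a[(i + 1) % a.size]
    end = a[i]
    return float(start), float(end)


def detect_landmarks(volume: np.ndarray, masks: HeartMasks,
                     septal_angle_deg: Optional[float] = None,
                     septal_span_deg: float = 120.0) -> Landmarks:
    """LV center + septal (RV insertion) points.

    The LV center is the blood-pool centroid over mid-ventricular slices. The
    insertions are found where an RV blood structure abuts the myocardium; if
    the image has no RV, an explicit ``septal_angle_deg`` (anterior insertion;
    the inferior one is ``septal_span_deg`` clockwise) must be given.
    """
    lv = masks.lv_blood
    if not masks.myocardium.any() or not lv.any():
        raise InputError("masks must contain myocardium and LV blood pool")
    zs = np.unique(np.nonzero(lv)[0])
    mid = zs[len(zs) // 3: max(len(zs) // 3 + 1, 2 * len(zs) // 3 + 1)]
    sub = np.zeros_like(lv)
    sub[mid] = lv[mid]
    cz, cy, cx = ndimage.center_of_mass(sub)
    zmid = float(np.median(mid))

    if septal_angle_deg is not None:
        a_ant = float(septal_angle_deg) % 360.0
        a_inf = (a_ant - septal_span_deg) % 360.0
    else:
        # look for RV blood abutting the myocardium from outside
        fg = volume > float(np.percentile(volume[masks.myocardium], 50))
        known = masks.labels > 0
        rv = fg & ~ndimage.binary_dilation(known, iterations=1)
        rv &= ndimage.binary_dilation(masks.myocardium, iterations=3)
        lab, n = ndimage.label(rv)
        if n == 0 or rv.sum() < 8:
            raise GeometryError(
                "no RV structure found; provide septal_angle_deg explicitly")
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, range(1, n + 1))
        comp = lab == (int(np.argmax(sizes)) + 1)
        ys, xs = np.nonzero(comp.any(axis=0))
        ang = np.degrees(np.arctan2(ys - cy, xs - cx)) % 360.0
        start, end = _angular_span(ang)
        # anterior insertion: sweeping counterclockwise (increasing angle)
        # from it crosses the RV-contact arc (the septum)
        a_ant, a_inf = start, end

    upper = _outer_boundary_point(masks, a_ant, zmid)
    lower = _outer_boundary_point(masks, a_inf, zmid)
    shape = masks.labels.shape
    for p in (upper, lower, (cz, cy, cx)):
        if not all(-0.5 <= c <= s - 0.5 for c, s in zip(p, shape)):
            raise GeometryError("landmark outside the volume")
    return Landmarks((float(cz), float(cy), float(cx)), upper, lower,
                     float(a_ant), float(a_inf))


# ---------------------------------------------------------------------------
# reorientation
# ---------------------------------------------------------------------------

def _resample_rotated(vol: np.ndarray, R: np.ndarray, spacing_mm,
                      order: int = 1, cval: float = 0.0) -> np.ndarray:
    """Resample ``vol`` rotated by R (world space, about the volume center)."""
    D = np.diag(spacing_mm)
    Dinv = np.diag(1.0 / np.asarray(spacing_mm))
    M = Dinv @ R.T @ D
    c = (np.asarray(vol.shape) - 1) / 2.0
    offset = c - M @ c
    return ndimage.affine_transform(vol, M, offset=offset, order=order,
                                    mode="constant", cval=cval)


def reorient_short_axis(study, long_axis) -> "object":
    """Resample the study so the z axis aligns with the LV long axis.

    ``long_axis`` is a unit vector in (z, y, x) world components. Identity
    when already aligned (no interpolation applied).
    """
    v = np.asarray(long_axis, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise InputError("long axis must be a non-zero vector")
    if abs(n - 1.0) > 1e-6:
        raise InputError("long axis must be a unit vector")
    ez = np.array([1.0, 0.0, 0.0])
    if np.allclose(v, ez, atol=1e-9):
        return study.copy_with()
    # rotation taking v -> ez (Rodrigues)
    axis = np.cross(v, ez)
    s = np.linalg.norm(axis)
    c = float(v @ ez)
    if s < 1e-12:  # v == -ez
        K = np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float)
        R = np.eye(3) + 2 * K @ K
    else:
        axis = axis / s
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + s * K + (1 - c) * (K @ K)
    fill = float(np.min(study.frames[0]))
    frames = np.stack([_resample_rotated(f, R, study.spacing_mm, order=1,
                                         cval=fill)
                       for f in study.frames])
    out = study.copy_with(frames=frames, truth=None)
    if study.truth is not None and "masks" in study.truth:
        masks = study.truth["masks"]
        lab = _resample_rotated(masks.labels.astype(float), R,
                                study.spacing_mm, order=0, cval=0.0)
        out.truth = dict(study.truth)
        out.truth["masks"] = HeartMasks(np.round(lab).astype(np.int16),
                                        masks.spacing_mm)
    return out
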