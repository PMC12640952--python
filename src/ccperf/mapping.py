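"""Bullseye polar maps and the modified AHA-16 segment model.

The LV myocardium is displayed as a bullseye: apex at the center, base at the
rim, angle measured counterclockwise (viewed from the apex) from the anterior
RV insertion. Sixteen segments: basal ring 1-6 and mid ring 7-12 (60 deg
each), apical ring 13-16 (90 deg); the apical cap (segment 17) is excluded
from MBF analysis. A segment is excluded from reporting when fewer than 30%
of its polar-map pixels are sampled.

Coronary territories assume right-dominant anatomy:
LAD {1,2,7,8,13,14}, RCA {3,4,9,10,15}, LCX {5,6,11,12,16}. The
representative territory MBF is the minimum over spatially adjacent segment
pairs of the pair-mean MBF; adjacency is generated from segment geometry
(same ring and angularly touching, or adjacent rings and angularly
overlapping/touching) — the rule reproduces the canonical LAD pair list
exactly, which ships as a data test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DegenerateInputError, GeometryError, InputError

BASAL = (1, 2, 3, 4, 5, 6)
MID = (7, 8, 9, 10, 11, 12)
APICAL = (13, 14, 15, 16)

TERRITORIES: Dict[str, Tuple[int, ...]] = {
    "LAD": (1, 2, 7, 8, 13, 14),
    "RCA": (3, 4, 9, 10, 15),
    "LCX": (5, 6, 11, 12, 16),
}

#: angular extent of each segment, degrees from the anterior RV insertion,
#: increasing counterclockwise viewed from the apex. Basal/mid sextants start
#: at the insertion and walk through the septum; apical quadrant centers are
#: aligned with the corresponding basal/mid anatomical centers (boundaries
#: offset by 45 deg), the standard AHA display geometry.
_SEXTANT_ORDER_BASAL = (2, 3, 4, 5, 6, 1)
_SEXTANT_ORDER_MID = (8, 9, 10, 11, 12, 7)
_QUADRANT_ORDER_APICAL = (14, 15, 16, 13)
_APICAL_OFFSET_DEG = 15.0  # segment 14 spans [15, 105) etc.


def segment_interval_deg(segment: int) -> Tuple[float, float]:
    """Half-open angular interval [start, end) of a segment (end may exceed
    360 for wrap-around)."""
    if segment in BASAL or segment in MID:
        order = _SEXTANT_ORDER_BASAL if segment in BASAL else _SEXTANT_ORDER_MID
        i = order.index(segment)
        return 60.0 * i, 60.0 * (i + 1)
    if segment in APICAL:
        i = _QUADRANT_ORDER_APICAL.index(segment)
        return _APICAL_OFFSET_DEG + 90.0 * i, _APICAL_OFFSET_DEG + 90.0 * (i + 1)
    raise InputError(f"segment {segment} is not in the 16-segment model")


def _ring(segment: int) -> int:
    return 0 if segment in BASAL else (1 if segment in MID else 2)


def _circ_relation(a: Tuple[float, float], b: Tuple[float, float]):
    """('overlap' | 'touch' | None) between two circular arcs (degrees)."""
    eps = 1e-9

    def pieces(iv):
        s, e = iv[0] % 360.0, iv[0] % 360.0 + (iv[1] - iv[0])
        if e <= 360.0 + eps:
            return [(s, min(e, 360.0))]
        return [(s, 360.0), (0.0, e - 360.0)]

    overlap = touch = False
    for sa, ea in pieces(a):
        for sb, eb in pieces(b):
            lo, hi = max(sa, sb), min(ea, eb)
            if hi - lo > eps:
                overlap = True
            elif abs(hi - lo) <= eps:
                touch = True
            # wrap-around touching at the 0/360 seam
            if abs((ea % 360.0) - (sb % 360.0)) <= eps or \
               abs((eb % 360.0) - (sa % 360.0)) <= eps:
                touch = True
    return "overlap" if overlap else ("touch" if touch else None)


def generate_adjacency(territory: str) -> List[Tuple[int, int]]:
    """Spatially adjacent segment pairs within a territory.

    Same-ring pairs are adjacent when their arcs touch; pairs in adjacent
    rings when their arcs overlap or touch; rings two apart are never
    adjacent.
    """
    segs = TERRITORIES[territory]
    pairs = []
    for i, a in enumerate(segs):
        for b in segs[i + 1:]:
            da = abs(_ring(a) - _ring(b))
            rel = _circ_relation(segment_interval_deg(a), segment_interval_deg(b))
            if da == 0 and rel in ("touch", "overlap"):
                pairs.append(tuple(sorted((a, b))))
            elif da == 1 and rel is not None:
                pairs.append(tuple(sorted((a, b))))
    return sorted(set(pairs))


ADJACENCY: Dict[str, List[Tuple[int, int]]] = {
    t: generate_adjacency(t) for t in TERRITORIES
}


# ---------------------------------------------------------------------------
# polar map
# ---------------------------------------------------------------------------

@dataclass
class PolarMap:
    """Bullseye raster (n_radius x n_angle) of MBF; NaN where unsampled.

    Row 0 is the apex (center of the bullseye), the last row the base; the
    angle origin is the anterior RV insertion, increasing counterclockwise
    viewed from the apex.
    """
    raster: np.ndarray
    n_radius: int
    n_angle: int

    def __post_init__(self):
        self.raster = np.asarray(self.raster, dtype=float)
        if self.raster.shape != (self.n_radius, self.n_angle):
            raise InputError("raster dimensions do not match configuration")
        if self.n_radius % 3 != 0:
            raise InputError("n_radius must be divisible by 3 (three rings)")
        if self.n_angle % 24 != 0:
            raise InputError("n_angle must be a multiple of 24 so that 60 and "
                             "90 degree boundaries fall on bin edges")

    def rotated(self, degrees: float) -> "PolarMap":
        binw = 360.0 / self.n_angle
        shift = degrees / binw
        if abs(shift - round(shift)) > 1e-9:
            raise InputError("rotation must be a whole number of angle bins")
        return PolarMap(np.roll(self.raster, int(round(shift)), axis=1),
                        self.n_radius, self.n_angle)


def build_polar_map(mbf_map: np.ndarray, masks, landmarks,
                    n_radius: int = 24, n_angle: int = 72,
                    apex: str = "first") -> PolarMap:
    """Sample the myocardial MBF map into bullseye bins.

    Each short-axis slice maps linearly to a radius bin (apex at the center);
    myocardial voxels are binned by their angle about the LV center measured
    from the anterior-insertion origin; multiple samples per bin average.
    """
    data = np.asarray(mbf_map, dtype=float)
    myo = masks.myocardium & np.isfinite(data)
    if not myo.any():
        raise DegenerateInputError("no sampled myocardium on any slice")
    slices = np.unique(np.nonzero(myo)[0])
    if apex == "last":
        slices = slices[::-1]
    order = {int(z): i for i, z in enumerate(slices)}
    _, cy, cx = landmarks.lv_center
    theta0 = landmarks.anterior_angle_deg

    zs, ys, xs = np.nonzero(myo)
    vals = data[zs, ys, xs]
    theta = np.degrees(np.arctan2(ys - cy, xs - cx)) % 360.0
    phi = (theta - theta0) % 360.0
    abin = np.minimum((phi / (360.0 / n_angle)).astype(int), n_angle - 1)
    srel = np.array([order[int(z)] for z in zs])

    # each slice paints the whole radial band it maps to (apex -> center)
    n_s = len(slices)
    sums = np.zeros((n_radius, n_angle))
    counts = np.zeros((n_radius, n_angle))
    for i in range(n_s):
        sel = srel == i
        if not sel.any():
            continue
        s1 = np.zeros(n_angle)
        c1 = np.zeros(n_angle)
        np.add.at(s1, abin[sel], vals[sel])
        np.add.at(c1, abin[sel], 1.0)
        r0 = int(np.floor(i / n_s * n_radius))
        r1 = max(int(np.floor((i + 1) / n_s * n_radius)), r0 + 1)
        sums[r0:r1] += s1[None]
        counts[r0:r1] += c1[None]
    with np.errstate(invalid="ignore"):
        raster = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return PolarMap(raster, n_radius, n_angle)


# ---------------------------------------------------------------------------
# AHA-16 report
# ---------------------------------------------------------------------------

def segment_bin_map(n_radius: int, n_angle: int) -> np.ndarray:
    """Segment id (1..16) of every polar-map bin."""
    PolarMap(np.zeros((n_radius, n_angle)), n_radius, n_angle)  # validates dims
    binw = 360.0 / n_angle
    seg = np.zeros((n_radius, n_angle), dtype=int)
    third = n_radius // 3
    off = int(round(_APICAL_OFFSET_DEG / binw))
    for r in range(n_radius):
        ring = min(r // third, 2)  # 0 apical (center), 1 mid, 2 basal
        for a in range(n_angle):
            if ring == 0:
                q = ((a - off) % n_angle) // (n_angle // 4)
                seg[r, a] = _QUADRANT_ORDER_APICAL[q]
            else:
                s = a // (n_angle // 6)
                seg[r, a] = (_SEXTANT_ORDER_MID if ring == 1
                             else _SEXTANT_ORDER_BASAL)[s]
    return seg


#: fraction of a segment's polar-map area that must be sampled
EXCLUSION_FRACTION = 0.30


@dataclass
class AHAReport:
    """Per-segment means with exclusion flags and the global mean over
    included segments. ``segments`` columns: segment, mean_mbf, pixel_count,
    area_pixels, excluded (and relative_mbf after normalization)."""
    segments: pd.DataFrame
    global_mean_mbf: float
    n_radius: int
    n_angle: int

    def mean(self, segment: int) -> float:
        row = self.segments.loc[self.segments.segment == segment]
        if row.empty:
            raise InputError(f"segment {segment} not in report")
        return float(row.mean_mbf.iloc[0])

    def excluded(self, segment: int) -> bool:
        return bool(self.segments.loc[self.segments.segment == segment,
                                      "excluded"].iloc[0])


def aha16_report(polar: PolarMap) -> AHAReport:
    """Segment statistics on the polar raster, with the 30% exclusion rule.

    The apical cap (segment 17) is not part of the model and never reported.
    """
    segmap = segment_bin_map(polar.n_radius, polar.n_angle)
    rows = []
    for s in range(1, 17):
        bins = segmap == s
        area = int(bins.sum())
        vals = polar.raster[bins]
        vals = vals[np.isfinite(vals)]
        count = int(vals.size)
        excluded = count < EXCLUSION_FRACTION * area
        rows.append(dict(segment=s,
                         mean_mbf=float(vals.mean()) if count else np.nan,
                         pixel_count=count, area_pixels=area,
                         excluded=excluded))
    df = pd.DataFrame(rows)
    included = df.loc[~df.excluded, "mean_mbf"]
    if included.empty:
        raise DegenerateInputError("all AHA segments excluded")
    return AHAReport(df, float(included.mean()), polar.n_radius, polar.n_angle)


def report_from_means(means: Dict[int, float], n_radius: int = 24,
                      n_angle: int = 72) -> AHAReport:
    """Build a fully-sampled report directly from segment means (testing and
    cohort-level use)."""
    segmap = segment_bin_map(n_radius, n_angle)
    rows = []
    for s in range(1, 17):
        area = int((segmap == s).sum())
        m = means.get(s, np.nan)
        ok = np.isfinite(m)
        rows.append(dict(segment=s, mean_mbf=float(m) if ok else np.nan,
                         pixel_count=area if ok else 0, area_pixels=area,
                         excluded=not ok))
    df = pd.DataFrame(rows)
    inc = df.loc[~df.excluded, "mean_mbf"]
    if inc.empty:
        raise DegenerateInputError("all AHA segments excluded")
    return AHAReport(df, float(inc.mean()), n_radius, n_angle)


# ---------------------------------------------------------------------------
# territory statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TerritoryMBF:
    vessel: str
    value: float
    pair: Optional[Tuple[int, int]]
    evaluable: bool


def territory_mbf(report: AHAReport, territory: str) -> TerritoryMBF:
    """Representative territory MBF: the minimum pair-mean over spatially
    adjacent included segment pairs; ties keep the first (lowest) pair."""
    if territory not in TERRITORIES:
        raise InputError(f"unknown territory {territory!r}")
    best_val, best_pair = np.inf, None
    for a, b in ADJACENCY[territory]:
        if report.excluded(a) or report.excluded(b):
            continue
        ma, mb = report.mean(a), report.mean(b)
        if not (np.isfinite(ma) and np.isfinite(mb)):
            continue
        v = 0.5 * (ma + mb)
        if v < best_val:
            best_val, best_pair = v, (a, b)
    if best_pair is None:
        return TerritoryMBF(territory, np.nan, None, False)
    return TerritoryMBF(territory, float(best_val), best_pair, True)


def relative_mbf(report: AHAReport) -> AHAReport:
    """Normalize segment means to the territory with the highest
    representative MBF; adds a ``relative_mbf`` column."""
    reps = {t: territory_mbf(report, t) for t in TERRITORIES}
    vals = [r.value for r in reps.values() if r.evaluable]
    if not vals:
        raise DegenerateInputError("no evaluable territory")
    ref = max(vals)
    if ref <= 0:
        raise InputError("maximum representative MBF must be > 0")
    df = report.segments.copy()
    df["relative_mbf"] = df["mean_mbf"] / ref
    return AHAReport(df, report.global_mean_mbf, report.n_radius, report.n_angle)


def classify_ischemic(values, threshold: float) -> np.ndarray:
    """Ischemia flags: MBF strictly below the threshold (a value exactly at
    the threshold is not ischemic)."""
    if threshold <= 0:
        raise InputError("threshold must be > 0")
    return np.asarray(values, dtype=float) < threshold
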