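"""Image-based automated beam-hardening correction (ABHC).

Iodine-induced beam hardening shows up in dynamic cardiac CT as an
enhancement-dependent spatial bias (cupping) across the myocardium. The
corrector models the bias as a radial polynomial scaled by the instantaneous
blood-pool enhancement — the same family the phantom simulator uses, a
deliberate simulation-matched simplification rather than a claim about
scanner physics — and searches the coefficients that minimize an artifact
cost with a derivative-free simplex started at the identity (zero) vector.

Cost = mean over frames of the within-myocardium HU variance (spatial term)
     + lambda * mean squared frame-to-frame change of the pre-contrast-
       referenced myocardial mean HU over pre-contrast and late frames
       (temporal term).

The corrected study never has a larger cost than the uncorrected one: if the
optimizer fails to improve on the identity, the identity is returned with a
warning flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage, optimize

from .errors import InputError

BH_MAX_RHO = 1.25  # normalized-radius support of the correction


@dataclass(frozen=True)
class BHCoeffs:
    """Polynomial correction coefficients (degree 1..n over normalized radius,
    no constant term — it is unidentifiable from a mean-removed cost).
    The zero vector is the identity correction."""
    coefficients: Tuple[float, ...]
    converged: bool = True
    cost_identity: float = float("nan")
    cost_corrected: float = float("nan")

    def __post_init__(self):
        if not np.all(np.isfinite(self.coefficients)):
            raise InputError("coefficients must be finite")


def _radial_map(masks) -> np.ndarray:
    from .phantom import radial_map
    return radial_map(masks)


def _blood_enhancement(study, masks) -> np.ndarray:
    """Per-frame mean blood-pool (LV + aorta) enhancement above its
    pre-contrast mean; the scale of the bias model."""
    blood = masks.lv_blood | masks.aorta
    if not blood.any():
        raise InputError("masks contain no blood pool")
    tac = study.frames[:, blood].mean(axis=1)
    lo, hi = tac.min(), tac.max()
    if hi - lo <= 0:
        return tac - tac[0]
    first = int(np.argmax(tac >= lo + 0.05 * (hi - lo)))
    baseline = tac[:first].mean() if first > 0 else tac[0]
    return tac - baseline


def _apply_correction(frames: np.ndarray, coeffs, rho: np.ndarray,
                      enhancement: np.ndarray) -> np.ndarray:
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.size == 0 or not np.any(coeffs):
        return frames.copy()
    bias = np.zeros_like(rho)
    for i, c in enumerate(coeffs, start=1):
        if c:
            bias += c * rho ** i
    region = rho <= BH_MAX_RHO
    out = frames.copy()
    out[:, region] -= enhancement[:, None] * bias[region][None]
    return out


def _precontrast_and_late(enhancement: np.ndarray) -> np.ndarray:
    """Frames with negligible iodine enhancement (pre-contrast, plus any late
    frames after complete washout): there the myocardial mean must be stable,
    since an enhancement-scaled artifact cannot act on them. The 2% cut keeps
    frames with lingering tissue contrast out of the stability term."""
    return enhancement < 0.02 * max(enhancement.max(), 1e-9)


def _erode_inplane(mask: np.ndarray) -> np.ndarray:
    """One-voxel in-plane erosion; partial-volume voxels on segmentation
    boundaries carry a radial intensity gradient that would masquerade as a
    beam-hardening bias. Falls back to the full mask if erosion empties it."""
    cross = np.zeros((1, 3, 3), dtype=bool)
    cross[0] = [[0, 1, 0], [1, 1, 1], [0, 1, 0]]
    er = ndimage.binary_erosion(mask, structure=cross)
    return er if er.any() else mask


def _cost_of_frames(frames: np.ndarray, masks, enhancement: np.ndarray,
                    lam: float) -> float:
    # Spatial term over the myocardium AND the LV blood pool: the myocardial
    # annulus alone spans too narrow a radial range to identify the
    # polynomial (its mean over the annulus would be a free constant that
    # leaks straight into the tissue TACs); the pool anchors the low-radius
    # behaviour and, with a zero constant term, pins the bias to zero.
    myo = _erode_inplane(masks.myocardium)
    lv = _erode_inplane(masks.lv_blood)
    vals = frames[:, myo]
    spatial = float(vals.var(axis=1).mean())
    if lv.any():
        spatial += float(frames[:, lv].var(axis=1).mean())
    # temporal term: frame-to-frame stability of the myocardial mean within
    # the pre-contrast block and within the late block (never across the gap)
    sel = np.nonzero(_precontrast_and_late(enhancement))[0]
    temporal = 0.0
    if sel.size >= 2:
        means = vals.mean(axis=1)
        adjacent = np.diff(sel) == 1
        if adjacent.any():
            d = means[sel[1:][adjacent]] - means[sel[:-1][adjacent]]
            temporal = float(np.mean(d ** 2))
    return spatial + lam * temporal


def bh_cost(study, masks, coeffs=None, lam: float = 1.0) -> float:
    """Artifact cost of the study after applying the given correction
    coefficients (None or zeros = uncorrected). Deterministic; lower is
    better; invariant to a global HU offset."""
    myo = masks.myocardium
    if not myo.any():
        raise InputError("myocardium mask is empty")
    enh = _blood_enhancement(study, masks)
    if coeffs is None:
        frames = study.frames
    else:
        c = coeffs.coefficients if isinstance(coeffs, BHCoeffs) else coeffs
        frames = _apply_correction(study.frames, c, _radial_map(masks), enh)
    return _cost_of_frames(frames, masks, enh, lam)


def correct_beam_hardening(study, masks, order: int = 3, lam: float = 1.0,
                           max_iter: int = 300):
    """Minimize the artifact cost over polynomial coefficients and apply the
    correction. Returns (corrected study, BHCoeffs)."""
    myo = masks.myocardium
    if not myo.any():
        raise InputError("myocardium mask is empty")
    rho = _radial_map(masks)
    enh = _blood_enhancement(study, masks)

    def cost(c):
        return _cost_of_frames(_apply_correction(study.frames, c, rho, enh),
                               masks, enh, lam)

    c0 = np.zeros(order)
    identity_cost = cost(c0)
    res = optimize.minimize(cost, c0, method="Nelder-Mead",
                            options=dict(xatol=1e-4,
                                         fatol=1e-6 * max(identity_cost, 1.0),
                                         maxiter=max_iter))
    if np.isfinite(res.fun) and res.fun <= identity_cost:
        coeffs = BHCoeffs(tuple(float(v) for v in res.x),
                          converged=bool(res.success),
                          cost_identity=identity_cost,
                          cost_corrected=float(res.fun))
        frames = _apply_correction(study.frames, res.x, rho, enh)
    else:  # non-convergence: fall back to identity, flagged
        coeffs = BHCoeffs((0.0,) * order, converged=False,
                          cost_identity=identity_cost,
                          cost_corrected=identity_cost)
        frames = study.frames.copy()
    return study.copy_with(frames=frames), coeffs
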