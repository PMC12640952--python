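"""Cohort-level statistics: CAD-RADS grading, bootstrap ROC / Youden
threshold derivation, correlation and group tests, and the classifier that
separates flow-limiting stenosis from microvascular disease (MVD).

CAD-RADS grades luminal diameter stenosis 0..5; >= 3 is obstructive.
Threshold derivation restricts to unequivocal territories (grades 0 and 4;
grade 4 is the positive class, expected to have low MBF), bootstraps the
empirical ROC 1,000 times, takes each replicate's Youden-optimal threshold
(J = sensitivity + specificity - 1, ties resolved to the lowest threshold)
and reports the mean with a percentile 95% CI. A patient-stratified variant
resamples patients with all their territories to respect within-patient
clustering.

Per-patient discordance labels, evaluated in order:
  1. flow_limiting        — an obstructive territory with MBF below threshold
  2. mvd_diffuse          — no obstructive vessel and diffuse ischemia
                            (>50% of included segments ischemic AND global
                            mean below threshold)
  3. mvd_focal            — no obstructive vessel, >=1 ischemic territory
  4. discordant_preserved — obstructive disease but all territories preserved
  5. normal
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InputError

LABELS = ("normal", "flow_limiting", "mvd_focal", "mvd_diffuse",
          "discordant_preserved")

#: CAD-RADS bins over integer percent stenosis: {0}, 1-24, 25-49, 50-69,
#: 70-99, {100}
_CADRADS_UPPER = (0, 24, 49, 69, 99, 100)


def cadrads_from_stenosis(stenosis_percent: float) -> int:
    """Grade a luminal diameter stenosis percentage.

    Non-integer reads are truncated toward zero before binning (clinical
    reads are integers; 69.5 -> 69 -> grade 3).
    """
    p = float(stenosis_percent)
    if not (0.0 <= p <= 100.0):
        raise InputError("stenosis percent must be within [0, 100]")
    p = math.trunc(p)
    for grade, upper in enumerate(_CADRADS_UPPER):
        if p <= upper:
            return grade
    raise AssertionError("unreachable")


def is_obstructive(grade: int) -> bool:
    """CAD-RADS >= 3 is considered obstructive stenosis."""
    g = int(grade)
    if not (0 <= g <= 5):
        raise InputError("CAD-RADS grade must be in 0..5")
    return g >= 3


# ---------------------------------------------------------------------------
# ROC / Youden threshold
# ---------------------------------------------------------------------------

def youden_threshold(mbf: np.ndarray, positive: np.ndarray) -> float:
    """Threshold maximizing J = sens + spec - 1 for the call "MBF < t is
    positive", over candidate thresholds at midpoints of sorted unique MBF
    values; ties resolve to the lowest threshold."""
    mbf = np.asarray(mbf, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    if positive.all() or not positive.any():
        raise DegenerateInputError("both classes required for ROC analysis")
    u = np.unique(mbf)
    if u.size < 2:
        raise DegenerateInputError("need at least two distinct MBF values")
    cands = 0.5 * (u[:-1] + u[1:])
    pos, neg = mbf[positive], mbf[~positive]
    sens = (pos[None, :] < cands[:, None]).mean(axis=1)
    spec = (neg[None, :] >= cands[:, None]).mean(axis=1)
    j = sens + spec - 1.0
    # ties (including float-rounding ties) resolve to the lowest threshold
    best = np.nonzero(j >= j.max() - 1e-12)[0][0]
    return float(cands[int(best)])


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    ci_low: float
    ci_high: float
    n_boot: int
    stratified: bool
    seed: int
    replicate_thresholds: Optional[np.ndarray] = None

    def __post_init__(self):
        if not (self.ci_low <= self.threshold <= self.ci_high):
            raise InputError("CI must bracket the threshold")


def bootstrap_youden_threshold(table: pd.DataFrame, n_boot: int = 1000,
                               stratify_by_patient: bool = False,
                               seed: int = 0,
                               restrict_grades: Tuple[int, int] = (0, 4),
                               max_redraws: int = 100) -> ThresholdResult:
    """Mean Youden-optimal MBF threshold over bootstrap replicates.

    The table is restricted to unequivocal grades (default CAD-RADS 0 / 4,
    grade 4 positive). Unstratified replicates resample rows; stratified
    replicates resample patients with all their territories. Replicates that
    draw a single class are redrawn. Deterministic given the seed.
    """
    lo, hi = restrict_grades
    sub = table.loc[table.cadrads.isin([lo, hi])].reset_index(drop=True)
    if sub.empty or sub.cadrads.nunique() < 2:
        raise DegenerateInputError(
            "restricted table must contain both CAD-RADS classes")
    mbf = sub.territory_mbf.to_numpy(dtype=float)
    pos = (sub.cadrads == hi).to_numpy()
    rng = np.random.default_rng(seed)

    patients = sub.patient_id.to_numpy() if "patient_id" in sub else None
    if stratify_by_patient and patients is None:
        raise InputError("patient-stratified bootstrap needs a patient_id column")
    uniq_pat = np.unique(patients) if patients is not None else None
    pat_rows = ({p: np.nonzero(patients == p)[0] for p in uniq_pat}
                if stratify_by_patient else None)

    thresholds = np.empty(n_boot)
    for b in range(n_boot):
        for _ in range(max_redraws):
            if stratify_by_patient:
                chosen = rng.choice(uniq_pat, size=uniq_pat.size, replace=True)
                idx = np.concatenate([pat_rows[p] for p in chosen])
            else:
                idx = rng.integers(0, len(sub), len(sub))
            p = pos[idx]
            if p.any() and not p.all():
                break
        else:
            raise DegenerateInputError("could not draw a two-class replicate")
        thresholds[b] = youden_threshold(mbf[idx], p)

    mean_t = float(thresholds.mean())
    lo_ci, hi_ci = np.percentile(thresholds, [2.5, 97.5])
    return ThresholdResult(mean_t, float(min(lo_ci, mean_t)),
                           float(max(hi_ci, mean_t)), n_boot,
                           stratify_by_patient, seed, thresholds)


# ---------------------------------------------------------------------------
# correlation / group tests
# ---------------------------------------------------------------------------

def spearman_rho(x, y) -> Tuple[float, float]:
    """Mid-rank Spearman correlation with the t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InputError("need paired samples, n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise DegenerateInputError("constant input has no rank correlation")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def unpaired_ttest(a, b) -> Tuple[float, float]:
    """Pooled-variance two-sided Student t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0  # degenerate-variance convention
        return float("inf") * np.sign(a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# patient classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TerritoryAssessment:
    vessel: str
    representative_mbf: float
    cadrads: int


@dataclass(frozen=True)
class PatientClassification:
    label: str
    territory_flags: Dict[str, Dict[str, bool]]  # vessel -> {ischemic, obstructive}
    global_mean_mbf: float

    def __post_init__(self):
        if self.label not in LABELS:
            raise InputError(f"unknown label {self.label!r}")


def classify_patient(territories: Sequence[TerritoryAssessment],
                     threshold: float,
                     aha_report=None) -> PatientClassification:
    """Apply the discordance rules (module docstring) to one patient.

    The diffuse-ischemia criterion uses the AHA report when available
    (>50% of included segments ischemic AND global mean < threshold);
    otherwise the per-territory proxy (>50% of territories ischemic AND mean
    territory MBF < threshold).
    """
    terrs = [t for t in territories if np.isfinite(t.representative_mbf)]
    if not terrs:
        raise DegenerateInputError("no evaluable territory")
    if threshold <= 0:
        raise InputError("threshold must be > 0")
    isch = {t.vessel: t.representative_mbf < threshold for t in terrs}
    obst = {t.vessel: is_obstructive(t.cadrads) for t in terrs}
    mbfs = np.array([t.representative_mbf for t in terrs])

    if aha_report is not None:
        inc = aha_report.segments.loc[~aha_report.segments.excluded]
        frac = float((inc.mean_mbf < threshold).mean())
        gmean = float(aha_report.global_mean_mbf)
    else:
        frac = float(np.mean(list(isch.values())))
        gmean = float(mbfs.mean())
    diffuse = (frac > 0.5) and (gmean < threshold)

    any_obst = any(obst.values())
    if any(obst[v] and isch[v] for v in isch):
        label = "flow_limiting"
    elif not any_obst and diffuse:
        label = "mvd_diffuse"
    elif not any_obst and any(isch.values()):
        label = "mvd_focal"
    elif any_obst and not any(isch.values()):
        label = "discordant_preserved"
    else:
        label = "normal"
    flags = {t.vessel: dict(ischemic=isch[t.vessel], obstructive=obst[t.vessel])
             for t in terrs}
    return PatientClassification(label, flags, gmean)


def classify_cohort(table: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Per-patient classification of a cohort table (one row per patient)."""
    rows = []
    for pid, grp in table.groupby("patient_id"):
        terrs = [TerritoryAssessment(r.vessel, r.territory_mbf, int(r.cadrads))
                 for r in grp.itertuples()]
        c = classify_patient(terrs, threshold)
        row = dict(patient_id=pid, label=c.label,
                   global_mean_mbf=c.global_mean_mbf,
                   n_obstructive=int(sum(f["obstructive"]
                                         for f in c.territory_flags.values())))
        for col in ("diabetes", "sex", "is_mvd"):
            if col in grp:
                row[col] = grp[col].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_summary(table: pd.DataFrame, threshold: float) -> dict:
    """Subgroup label counts, group MBF statistics and (when truth labels are
    present) recovery of the MVD truth label.

    Predicted MVD is the ``mvd_diffuse`` label — the diffuse-ischemia pattern
    is the MVD signature; isolated single-territory low flow is reported as
    ``mvd_focal`` but not counted as a definite MVD call.
    """
    patients = classify_cohort(table, threshold)
    out: dict = {"n_patients": int(patients.shape[0]),
                 "n_territories": int(table.shape[0]),
                 "threshold": float(threshold)}

    # subgroup counts: diabetes x number of obstructive vessels
    if "diabetes" in patients:
        counts = (patients
                  .assign(obst_group=np.minimum(patients.n_obstructive, 2))
                  .groupby(["diabetes", "obst_group", "label"])
                  .size().rename("count").reset_index())
    else:
        counts = patients.groupby("label").size().rename("count").reset_index()
    out["label_counts"] = counts
    out["labels_total"] = int(counts["count"].sum())

    obst = table.loc[table.cadrads >= 3, "territory_mbf"]
    nonobst = table.loc[table.cadrads < 3, "territory_mbf"]
    if "diabetes" in table:
        nd = table.loc[~table.diabetes.astype(bool)]
        obst_nd = nd.loc[nd.cadrads >= 3, "territory_mbf"]
        non_nd = nd.loc[nd.cadrads < 3, "territory_mbf"]
    else:
        obst_nd, non_nd = obst, nonobst
    out["territory_means"] = {
        "obstructed": (float(obst.mean()), float(obst.std(ddof=1))) if len(obst) > 1 else None,
        "non_obstructed": (float(nonobst.mean()), float(nonobst.std(ddof=1))) if len(nonobst) > 1 else None,
        "obstructed_nondiabetic": (float(obst_nd.mean()), float(obst_nd.std(ddof=1))) if len(obst_nd) > 1 else None,
        "non_obstructed_nondiabetic": (float(non_nd.mean()), float(non_nd.std(ddof=1))) if len(non_nd) > 1 else None,
    }
    if len(obst) > 1 and len(nonobst) > 1:
        out["ttest_obstructed_vs_non"] = unpaired_ttest(obst, nonobst)
    rho_tbl = table if "diabetes" not in table else table.loc[~table.diabetes.astype(bool)]
    out["spearman_mbf_vs_cadrads"] = spearman_rho(rho_tbl.territory_mbf,
                                                  rho_tbl.cadrads)

    if "is_mvd" in patients:
        truth = patients.is_mvd.astype(bool).to_numpy()
        pred = (patients.label == "mvd_diffuse").to_numpy()
        tp = int((truth & pred).sum())
        fn = int((truth & ~pred).sum())
        tn = int((~truth & ~pred).sum())
        fp = int((~truth & pred).sum())
        out["mvd_recovery"] = dict(
            sensitivity=tp / (tp + fn) if tp + fn else np.nan,
            specificity=tn / (tn + fp) if tn + fp else np.nan,
            tp=tp, fn=fn, tn=tn, fp=fp)
    out["patients"] = patients
    return out
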