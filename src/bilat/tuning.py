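"""Per-unit directional-tuning statistics and their categorical classifications.

Operates on the long-format response table emitted by
:mod:`bilat.preprocess`.  For each unit and task the module derives per-arm
tuning curves (8-point unimanual, the 4-point unimanual subset matching the
bimanual grid, and 4-point bimanual marginals), then computes

* modulation depth (MD): max - min of the tuning curve,
* preferred direction (PD): grid direction with the maximal response
  (argmax; ties broken toward the smallest angle and flagged),
* delta-PD: circular distance between the two arms' PDs,
* the contralateral preference index (C - I) / (C + I) over each arm's
  maximum absolute response,
* the bilateral Pearson correlation between the two arms' curves,

plus population classifications: preference-quadrant labels across the
unimanual and bimanual tasks, the strongly-correlated fraction (cc > 0.75),
MD-difference summaries, and PD-shift / delta-PD change classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "TuningCurve",
    "TASK_TAGS",
    "preference_index",
    "bimanual_marginal_curve",
    "modulation_depth",
    "preferred_direction",
    "cosine_fit_pd",
    "circular_diff",
    "bilateral_correlation",
    "unit_curves",
    "summarize_tuning",
    "classify_quadrants",
    "strong_cc_fraction",
    "md_difference_stats",
    "pd_shift_stats",
    "delta_pd_change_stats",
]

TASK_TAGS = ("unimanual-8", "unimanual-4", "bimanual-4")


@dataclass
class TuningCurve:
    """Baseline-subtracted response (Hz) per grid direction for one arm and task."""

    arm: str
    task: str
    dirs_deg: np.ndarray
    values_hz: np.ndarray

    def __post_init__(self) -> None:
        self.dirs_deg = np.asarray(self.dirs_deg, dtype=float)
        self.values_hz = np.asarray(self.values_hz, dtype=float)
        if self.arm not in ("ipsi", "contra"):
            raise ValueError(f"arm must be 'ipsi' or 'contra', got {self.arm!r}")
        if self.task not in TASK_TAGS:
            raise ValueError(f"task must be one of {TASK_TAGS}, got {self.task!r}")
        n = {"unimanual-8": 8, "unimanual-4": 4, "bimanual-4": 4}[self.task]
        if len(self.dirs_deg) != n or len(self.values_hz) != n:
            raise ValueError(f"{self.task} curve needs {n} points, got {len(self.dirs_deg)}")
        if np.any(np.diff(self.dirs_deg) <= 0):
            raise ValueError("directions must be strictly increasing")
        if np.any((self.dirs_deg < 0) | (self.dirs_deg >= 360)):
            raise ValueError("directions must lie in [0, 360)")


def preference_index(max_abs_resp_contra: float, max_abs_resp_ipsi: float) -> float:
    """Contralateral preference index (C - I) / (C + I) in [-1, 1].

    C and I are each arm's maximum absolute response within a task.  +1 means
    the unit modulates only with the contralateral arm, -1 only with the
    ipsilateral arm, 0 identically with either.  Both-zero input is undefined
    and returns NaN (the unit is excluded from preference statistics).
    """
    c, i = max_abs_resp_contra, max_abs_resp_ipsi
    if c < 0 or i < 0:
        raise ValueError("maximum absolute responses must be nonnegative")
    if c == 0 and i == 0:
        logger.info("preference_index undefined: both arms have zero maximal response")
        return float("nan")
    return (c - i) / (c + i)


def bimanual_marginal_curve(bimanual: pd.DataFrame, arm: str) -> TuningCurve:
    """Per-arm 4-point tuning curve from the 16 bimanual configuration responses.

    The value at direction theta for the chosen arm is the mean of the four
    responses sharing that arm's direction (averaged over the other arm's
    directions).  ``bimanual`` needs columns ``ipsi_dir_deg, contra_dir_deg,
    response_hz`` with all 16 configurations present.
    """
    if arm not in ("ipsi", "contra"):
        raise ValueError(f"arm must be 'ipsi' or 'contra', got {arm!r}")
    col = f"{arm}_dir_deg"
    other = "contra_dir_deg" if arm == "ipsi" else "ipsi_dir_deg"
    dirs = np.sort(bimanual[col].unique())
    other_dirs = np.sort(bimanual[other].unique())
    if len(bimanual) != len(dirs) * len(other_dirs):
        raise ValueError(
            f"expected {len(dirs) * len(other_dirs)} bimanual configurations, got {len(bimanual)}"
        )
    values = []
    for d in dirs:
        rows = bimanual.loc[bimanual[col] == d, "response_hz"]
        if len(rows) != len(other_dirs):
            raise ValueError(f"missing bimanual configurations for {arm} direction {d}")
        values.append(rows.mean())
    return TuningCurve(arm=arm, task="bimanual-4", dirs_deg=dirs, values_hz=np.array(values))


def modulation_depth(curve: TuningCurve) -> float:
    """MD: difference between the maximum and minimum responses on the curve (Hz)."""
    if len(curve.values_hz) == 0:
        raise ValueError("empty tuning curve")
    return float(curve.values_hz.max() - curve.values_hz.min())


def preferred_direction(curve: TuningCurve) -> tuple[float, bool]:
    """PD: grid direction with the maximal response; returns ``(pd_deg, tie_flag)``.

    Exact ties are broken toward the smallest angle and flagged.
    """
    v = curve.values_hz
    if len(v) == 0:
        raise ValueError("empty tuning curve")
    top = np.flatnonzero(v == v.max())
    return float(curve.dirs_deg[top[0]]), len(top) > 1


def cosine_fit_pd(curve: TuningCurve) -> tuple[float, float]:
    """Least-squares cosine fit ``a + b*cos(theta) + c*sin(theta)``.

    Returns ``(pd_deg, amplitude_hz)``; an off-grid alternative to the argmax
    PD for comparison.  Amplitude is the cosine half-amplitude.
    """
    th = np.deg2rad(curve.dirs_deg)
    X = np.column_stack([np.ones_like(th), np.cos(th), np.sin(th)])
    coef, *_ = np.linalg.lstsq(X, curve.values_hz, rcond=None)
    _, b, c = coef
    return float(np.rad2deg(np.arctan2(c, b)) % 360.0), float(np.hypot(b, c))


def circular_diff(a_deg: float, b_deg: float) -> float:
    """Circular distance between two directions, in [0, 180] degrees."""
    for v in (a_deg, b_deg):
        if not (0 <= v < 360):
            raise ValueError(f"direction {v} outside [0, 360)")
    d = abs(a_deg - b_deg)
    return min(d, 360.0 - d)


def bilateral_correlation(curve_ipsi: TuningCurve, curve_contra: TuningCurve) -> float:
    """Pearson correlation between the two arms' tuning curves.

    NaN sentinel when either curve is constant (correlation undefined; the
    unit is excluded from cc distributions).
    """
    if curve_ipsi.task != curve_contra.task:
        raise ValueError("curves must share a task tag")
    if not np.array_equal(curve_ipsi.dirs_deg, curve_contra.dirs_deg):
        raise ValueError("curves must share the direction grid")
    x, y = curve_ipsi.values_hz, curve_contra.values_hz
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.info("bilateral correlation undefined: constant tuning curve")
        return float("nan")
    return float(sps.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# per-unit curve construction and the per-unit/per-task summary table
# ---------------------------------------------------------------------------

def unit_curves(unit_responses: pd.DataFrame, bimanual_dirs: np.ndarray | None = None):
    """Tuning curves of one unit: dict ``(task, arm) -> TuningCurve``.

    ``unit_responses`` is that unit's slice of the long response table.  The
    unimanual-4 subset uses ``bimanual_dirs`` (default: the directions seen
    in the bimanual block).
    """
    out: dict[tuple[str, str], TuningCurve] = {}
    bi = unit_responses[unit_responses["block_type"] == "bimanual"]
    if bimanual_dirs is None and len(bi):
        bimanual_dirs = np.sort(bi["ipsi_dir_deg"].unique())
    for arm in ("ipsi", "contra"):
        block = unit_responses[unit_responses["block_type"] == arm]
        if len(block):
            sub = block.sort_values(f"{arm}_dir_deg")
            dirs = sub[f"{arm}_dir_deg"].to_numpy()
            vals = sub["response_hz"].to_numpy()
            out[("unimanual-8", arm)] = TuningCurve(arm, "unimanual-8", dirs, vals)
            if bimanual_dirs is not None:
                mask = np.isin(dirs, bimanual_dirs)
                if mask.sum() == 4:
                    out[("unimanual-4", arm)] = TuningCurve(
                        arm, "unimanual-4", dirs[mask], vals[mask]
                    )
        if len(bi):
            out[("bimanual-4", arm)] = bimanual_marginal_curve(bi, arm)
    return out


def summarize_tuning(responses: pd.DataFrame, bimanual_dirs: np.ndarray | None = None) -> pd.DataFrame:
    """Per-unit, per-task tuning summary table.

    Columns: ``unit_id, task, md_ipsi_hz, md_contra_hz, pd_ipsi_deg,
    pd_contra_deg, pd_tie, delta_pd_deg, max_abs_ipsi_hz, max_abs_contra_hz,
    preference_index, bilateral_cc``.  Tasks follow :data:`TASK_TAGS` as
    available in ``responses``.
    """
    rows = []
    for unit, grp in responses.groupby("unit_id", sort=True):
        curves = unit_curves(grp, bimanual_dirs)
        for task in TASK_TAGS:
            ci, cc_ = curves.get((task, "ipsi")), curves.get((task, "contra"))
            if ci is None or cc_ is None:
                continue
            pd_i, tie_i = preferred_direction(ci)
            pd_c, tie_c = preferred_direction(cc_)
            max_i = float(np.abs(ci.values_hz).max())
            max_c = float(np.abs(cc_.values_hz).max())
            rows.append(
                dict(
                    unit_id=unit,
                    task=task,
                    md_ipsi_hz=modulation_depth(ci),
                    md_contra_hz=modulation_depth(cc_),
                    pd_ipsi_deg=pd_i,
                    pd_contra_deg=pd_c,
                    pd_tie=tie_i or tie_c,
                    delta_pd_deg=circular_diff(pd_c, pd_i),
                    max_abs_ipsi_hz=max_i,
                    max_abs_contra_hz=max_c,
                    preference_index=preference_index(max_c, max_i),
                    bilateral_cc=bilateral_correlation(ci, cc_),
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# population classifications
# ---------------------------------------------------------------------------

QUADRANT_LABELS = ("contra→contra", "ipsi→contra", "ipsi→ipsi", "contra→ipsi")


def classify_quadrants(indices: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Preference-quadrant label per unit from (unimanual, bimanual) index signs.

    ``indices`` needs columns ``unit_id, uni_index, bi_index``; units with an
    undefined (NaN) index are excluded and logged.  An index of exactly 0
    counts as ipsilateral-preferring (conservative toward the
    contralateral-shift conclusion).  Returns ``(per_unit, counts)`` where
    ``counts`` has one row per quadrant with ``n`` and ``fraction``.
    """
    defined = indices.dropna(subset=["uni_index", "bi_index"])
    if len(defined) < len(indices):
        logger.info("excluding %d units with undefined preference index", len(indices) - len(defined))

    def _label(row) -> str:
        uni_c = row.uni_index > 0
        bi_c = row.bi_index > 0
        return f"{'contra' if uni_c else 'ipsi'}→{'contra' if bi_c else 'ipsi'}"

    per_unit = defined.assign(quadrant=[_label(r) for r in defined.itertuples()])
    n = len(per_unit)
    counts = pd.DataFrame(
        [
            dict(quadrant=q, n=int((per_unit["quadrant"] == q).sum()))
            for q in QUADRANT_LABELS
        ]
    )
    counts["fraction"] = counts["n"] / n if n else np.nan
    return per_unit, counts


def strong_cc_fraction(ccs, threshold: float = 0.75) -> float:
    """Fraction of units with cc strictly above ``threshold``; NaN ccs excluded."""
    arr = np.asarray(ccs, dtype=float)
    arr = arr[~np.isnan(arr)]
    if len(arr) == 0:
        return float("nan")
    return float(np.mean(arr > threshold))


def md_difference_stats(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-task contra-minus-ipsi MD differences with population mean/median."""
    rows = []
    for task, grp in summary.groupby("task", sort=False):
        diff = grp["md_contra_hz"] - grp["md_ipsi_hz"]
        rows.append(
            dict(
                task=task,
                n=len(diff),
                mean_diff_hz=diff.mean(),
                median_diff_hz=diff.median(),
                n_contra_larger=int((diff > 0).sum()),
            )
        )
    return pd.DataFrame(rows)


def pd_shift_stats(
    summary: pd.DataFrame,
    uni_task: str = "unimanual-4",
    shift_threshold_deg: float = 0.0,
) -> dict:
    """Per-arm PD shifts across the unimanual and bimanual tasks.

    For each unit present in both tasks, the shift is the circular distance
    between its unimanual and bimanual PD per arm.  ``shift_threshold_deg``
    defines a "significant" shift (strictly greater; 0 means any change on
    the grid).  Units with flagged PD ties in either task are excluded from
    the shift classification.  Returns per-unit shifts, mean +/- SEM per arm,
    and the class fractions (ipsi-shift only / contra-shift only / both /
    neither).
    """
    uni = summary[summary["task"] == uni_task].set_index("unit_id")
    bi = summary[summary["task"] == "bimanual-4"].set_index("unit_id")
    units = uni.index.intersection(bi.index)
    rows = []
    for u in units:
        rows.append(
            dict(
                unit_id=u,
                shift_ipsi_deg=circular_diff(uni.loc[u, "pd_ipsi_deg"], bi.loc[u, "pd_ipsi_deg"]),
                shift_contra_deg=circular_diff(uni.loc[u, "pd_contra_deg"], bi.loc[u, "pd_contra_deg"]),
                pd_tie=bool(uni.loc[u, "pd_tie"] or bi.loc[u, "pd_tie"]),
            )
        )
    per_unit = pd.DataFrame(rows)
    out = {"per_unit": per_unit}
    if len(per_unit):
        for arm in ("ipsi", "contra"):
            s = per_unit[f"shift_{arm}_deg"]
            out[f"mean_shift_{arm}_deg"] = float(s.mean())
            out[f"sem_shift_{arm}_deg"] = float(s.std(ddof=1) / np.sqrt(len(s))) if len(s) > 1 else 0.0
        ok = per_unit[~per_unit["pd_tie"]]
        n = len(ok)
        sig_i = ok["shift_ipsi_deg"] > shift_threshold_deg
        sig_c = ok["shift_contra_deg"] > shift_threshold_deg
        out["classes"] = dict(
            n=n,
            frac_ipsi_shift=float(sig_i.mean()) if n else float("nan"),
            frac_contra_shift=float(sig_c.mean()) if n else float("nan"),
            frac_both=float((sig_i & sig_c).mean()) if n else float("nan"),
            frac_neither=float((~sig_i & ~sig_c).mean()) if n else float("nan"),
        )
    return out


def delta_pd_change_stats(summary: pd.DataFrame, uni_task: str = "unimanual-4") -> dict:
    """How the between-arm PD difference changes from the unimanual to bimanual task."""
    uni = summary[summary["task"] == uni_task].set_index("unit_id")
    bi = summary[summary["task"] == "bimanual-4"].set_index("unit_id")
    units = uni.index.intersection(bi.index)
    d_uni = uni.loc[units, "delta_pd_deg"].to_numpy(dtype=float)
    d_bi = bi.loc[units, "delta_pd_deg"].to_numpy(dtype=float)
    n = len(units)
    if n == 0:
        return dict(n=0)
    sem = lambda x: float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
    return dict(
        n=n,
        mean_delta_pd_uni_deg=float(d_uni.mean()),
        sem_delta_pd_uni_deg=sem(d_uni),
        mean_delta_pd_bi_deg=float(d_bi.mean()),
        sem_delta_pd_bi_deg=sem(d_bi),
        frac_changed=float(np.mean(d_uni != d_bi)),
        frac_larger_uni=float(np.mean(d_uni > d_bi)),
        frac_larger_bi=float(np.mean(d_bi > d_uni)),
    )
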