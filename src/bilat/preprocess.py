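"""Spike events -> smoothed firing rates, PETHs, baseline-subtracted responses.

Spikes are counted in 20 ms bins aligned to each trial's Prepare onset,
converted to Hz, and smoothed with a 300 ms (SD) Gaussian kernel truncated at
+/-3 SD with edge renormalization, so a constant rate is preserved exactly at
trial boundaries.  The baseline of a unit is the mean (and SD) of its rate
over all Prepare-phase bins of the day; the neural response to a target
configuration is the trial-averaged Go-phase mean rate minus the baseline
mean.  A unit is task-related to a movement if, for at least one of its
target configurations, |response| exceeds one baseline SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

logger = logging.getLogger(__name__)

__all__ = [
    "BinnedRates",
    "bin_and_smooth",
    "select_units",
    "compute_baseline",
    "compute_peth",
    "go_phase_means",
    "compute_responses",
    "modulation_ratio",
    "classify_task_related",
]

CONFIG_KEYS = ["block_type", "ipsi_dir_deg", "contra_dir_deg"]


@dataclass
class BinnedRates:
    """Per-trial binned (and optionally smoothed) firing rates.

    ``rates[t]`` is an ``(n_units, n_bins_t)`` array in Hz for trial ``t``
    (trials may differ in length because the Prepare duration is jittered);
    ``bin_starts[t]`` holds the absolute start time of each half-open bin.
    """

    bin_s: float
    unit_ids: list[str]
    trial_ids: np.ndarray
    rates: list[np.ndarray]
    bin_starts: list[np.ndarray]

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def trial_index(self, trial_id) -> int:
        idx = np.flatnonzero(self.trial_ids == trial_id)
        if len(idx) == 0:
            raise KeyError(f"trial_id {trial_id} not in BinnedRates")
        return int(idx[0])


def _smooth(mat: np.ndarray, sd_bins: float) -> np.ndarray:
    """Gaussian smoothing along bins, truncated +/-3 SD, edge-renormalized.

    Dividing by the smoothed all-ones vector makes the operation an average
    with locally renormalized weights: constants pass through unchanged and
    total spike mass is conserved up to the (renormalized) edge weights.
    """
    sm = gaussian_filter1d(mat, sd_bins, axis=-1, mode="constant", truncate=3.0)
    norm = gaussian_filter1d(np.ones(mat.shape[-1]), sd_bins, mode="constant", truncate=3.0)
    return sm / norm


def bin_and_smooth(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    bin_ms: float = 20.0,
    kernel_sd_ms: float = 300.0,
    unit_ids: list[str] | None = None,
) -> BinnedRates:
    """Bin spike counts per trial on a ``bin_ms`` grid and smooth.

    Bins are half-open ``[t, t + bin)`` aligned to Prepare onset; a trailing
    partial bin is dropped.  ``kernel_sd_ms`` is the Gaussian SD; 0 disables
    smoothing.  Units absent from ``spikes`` but listed in ``unit_ids`` get
    all-zero rows (silent units are allowed).  Spikes falling outside every
    trial window are ignored (a count is logged).
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be > 0")
    if kernel_sd_ms < 0:
        raise ValueError("kernel_sd_ms must be >= 0")
    bin_s = bin_ms / 1000.0
    if unit_ids is None:
        unit_ids = sorted(spikes["unit_id"].unique())
    unit_pos = {u: i for i, u in enumerate(unit_ids)}
    n_units = len(unit_ids)

    codes = spikes["unit_id"].map(unit_pos)
    if codes.isna().any():
        dropped = int(codes.isna().sum())
        logger.info("dropping %d spikes from units outside unit_ids", dropped)
    keep = codes.notna().to_numpy()
    times = spikes["time_s"].to_numpy()[keep]
    codes = codes.to_numpy(dtype=float)[keep].astype(int)
    order = np.argsort(times, kind="stable")
    times, codes = times[order], codes[order]

    rates, starts_all = [], []
    n_outside = len(times)
    sd_bins = (kernel_sd_ms / bin_ms) if kernel_sd_ms > 0 else 0.0
    for row in trials.itertuples(index=False):
        t0, t1 = row.prepare_onset_s, row.end_s
        if not (t1 > t0):
            raise ValueError(f"trial {row.trial_id} has non-positive duration")
        n_bins = int(np.floor((t1 - t0) / bin_s + 1e-9))
        if n_bins == 0:
            raise ValueError(f"trial {row.trial_id} shorter than one bin")
        edges = t0 + np.arange(n_bins + 1) * bin_s
        lo, hi = np.searchsorted(times, (t0, edges[-1]))
        counts, _, _ = np.histogram2d(
            codes[lo:hi], times[lo:hi], bins=[np.arange(n_units + 1) - 0.5, edges]
        )
        n_outside -= hi - lo
        mat = counts / bin_s
        if sd_bins > 0:
            mat = _smooth(mat, sd_bins)
        rates.append(mat)
        starts_all.append(edges[:-1])
    if n_outside > 0:
        logger.info("ignored %d spikes outside all trial windows", n_outside)
    return BinnedRates(
        bin_s=bin_s,
        unit_ids=list(unit_ids),
        trial_ids=trials["trial_id"].to_numpy(),
        rates=rates,
        bin_starts=starts_all,
    )


def _phase_masks(rates: BinnedRates, row) -> tuple[np.ndarray, np.ndarray]:
    """(prepare, go) bin masks for one trial row, by bin start time."""
    starts = rates.bin_starts[rates.trial_index(row.trial_id)]
    eps = 1e-9
    prepare = starts < row.go_onset_s - eps
    go = (starts >= row.go_onset_s - eps) & (starts < row.rest_onset_s - eps)
    return prepare, go


def select_units(rates: BinnedRates, trials: pd.DataFrame, threshold_hz: float = 1.0) -> list[str]:
    """Units whose grand mean rate over all bins of all trials is strictly above threshold."""
    if len(trials) == 0:
        raise ValueError("need at least one trial")
    total = np.zeros(rates.n_units)
    n_bins = 0
    for mat in rates.rates:
        total += mat.sum(axis=1)
        n_bins += mat.shape[1]
    grand_mean = total / n_bins
    return [u for u, m in zip(rates.unit_ids, grand_mean) if m > threshold_hz]


def compute_baseline(rates: BinnedRates, trials: pd.DataFrame) -> pd.DataFrame:
    """Per-unit mean and SD of the firing rate over all Prepare-phase bins.

    Pooled over every trial of the day (all blocks); SD is the sample SD
    (ddof=1) across pooled bins.
    """
    chunks = []
    for row in trials.itertuples(index=False):
        prepare, _ = _phase_masks(rates, row)
        chunks.append(rates.rates[rates.trial_index(row.trial_id)][:, prepare])
    pooled = np.concatenate(chunks, axis=1)
    return pd.DataFrame(
        {
            "unit_id": rates.unit_ids,
            "mean_hz": pooled.mean(axis=1),
            "sd_hz": pooled.std(axis=1, ddof=1),
        }
    )


def compute_peth(
    rates: BinnedRates,
    trials: pd.DataFrame,
    window_s: tuple[float, float] = (-0.5, 2.5),
) -> dict[tuple, dict]:
    """Trial-averaged rate traces aligned to Go onset, grouped by configuration.

    Returns a dict keyed by ``(block_type, ipsi_dir_deg, contra_dir_deg)``
    with entries ``time_s`` (relative to Go onset), ``mean`` and ``sem``
    (``n_units x n_t``), and ``n_trials``.  Per-trial traces are linearly
    interpolated onto the common grid (trial grids are offset from one
    another by the Prepare jitter).
    """
    grid = np.arange(window_s[0], window_s[1], rates.bin_s) + rates.bin_s / 2
    out: dict[tuple, dict] = {}
    for key, grp in trials.groupby(CONFIG_KEYS, dropna=False):
        traces = []
        for row in grp.itertuples(index=False):
            ti = rates.trial_index(row.trial_id)
            centers = rates.bin_starts[ti] + rates.bin_s / 2 - row.go_onset_s
            mat = rates.rates[ti]
            tr = np.empty((mat.shape[0], len(grid)))
            for u in range(mat.shape[0]):
                tr[u] = np.interp(grid, centers, mat[u])
            traces.append(tr)
        if not traces:
            logger.warning("configuration %s has no trials; omitted from PETH", key)
            continue
        stack = np.stack(traces)
        n = stack.shape[0]
        sem = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(stack[0])
        out[key] = dict(time_s=grid, mean=stack.mean(axis=0), sem=sem, n_trials=n)
    return out


def go_phase_means(rates: BinnedRates, trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trial mean Go-phase rate per unit: rows = trials, columns = unit ids."""
    mats = []
    for row in trials.itertuples(index=False):
        _, go = _phase_masks(rates, row)
        if not go.any():
            raise ValueError(f"trial {row.trial_id} has no Go-phase bins")
        mats.append(rates.rates[rates.trial_index(row.trial_id)][:, go].mean(axis=1))
    return pd.DataFrame(mats, index=trials["trial_id"].to_numpy(), columns=rates.unit_ids)


def compute_responses(
    rates: BinnedRates, trials: pd.DataFrame, baseline: pd.DataFrame
) -> pd.DataFrame:
    """Neural response per unit and target configuration.

    response = (trial-averaged mean Go-phase rate) - (baseline mean); may be
    negative.  Returns long-format columns ``unit_id, block_type,
    ipsi_dir_deg, contra_dir_deg, response_hz``.
    """
    base = baseline.set_index("unit_id")["mean_hz"]
    missing = [u for u in rates.unit_ids if u not in base.index]
    if missing:
        raise ValueError(f"units absent from baseline: {missing}")
    go_means = go_phase_means(rates, trials)
    rows = []
    for key, grp in trials.groupby(CONFIG_KEYS, dropna=False):
        block_type, ipsi_dir, contra_dir = key
        mean_go = go_means.loc[grp["trial_id"].to_numpy()].mean(axis=0)
        for u in rates.unit_ids:
            rows.append(
                dict(
                    unit_id=u,
                    block_type=block_type,
                    ipsi_dir_deg=ipsi_dir,
                    contra_dir_deg=contra_dir,
                    response_hz=mean_go[u] - base[u],
                )
            )
    return pd.DataFrame(rows)


def modulation_ratio(response_hz: float, baseline_sd_hz: float) -> float:
    """|response| / baseline SD; +inf sentinel when SD is 0 but response is not."""
    if baseline_sd_hz < 0:
        raise ValueError("baseline_sd_hz must be >= 0")
    if baseline_sd_hz == 0:
        return 0.0 if response_hz == 0 else np.inf
    return abs(response_hz) / baseline_sd_hz


def classify_task_related(responses: pd.DataFrame, baseline: pd.DataFrame) -> pd.DataFrame:
    """Task-relatedness per unit: modulation ratio strictly above 1 for >= 1 configuration.

    Returns one row per unit with boolean flags per task present in
    ``responses``, ``n_task_related``, and a ``category`` label such as
    ``"3-task-related"``.
    """
    sd = baseline.set_index("unit_id")["sd_hz"]
    resp = responses.copy()
    resp["ratio"] = [
        modulation_ratio(r, sd[u]) for r, u in zip(resp["response_hz"], resp["unit_id"])
    ]
    tasks = list(dict.fromkeys(responses["block_type"]))
    rows = []
    for unit, grp in resp.groupby("unit_id", sort=False):
        flags = {}
        for task in tasks:
            ratios = grp.loc[grp["block_type"] == task, "ratio"]
            flags[task] = bool((ratios > 1.0).any())
        n = sum(flags.values())
        rows.append(dict(unit_id=unit, **flags, n_task_related=n, category=f"{n}-task-related"))
    return pd.DataFrame(rows)
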