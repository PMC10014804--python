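"""Generative model of unimanual and bimanual center-out motor-imagery sessions.

The simulator emulates a single-session intracortical recording: a population
of sorted units with known cosine directional tuning emits Poisson spike
trains while an (imagined) center-out reaching task runs through Prepare, Go
and Rest phases.  Unimanual blocks use one arm and 8 target directions;
bimanual blocks cue both arms simultaneously over a 4 x 4 grid of direction
pairs.  During bimanual movements each arm's modulation is attenuated by a
multiplicative gain (more strongly on the ipsilateral side) and the preferred
directions of a subset of units rotate, which is the ground-truth structure
downstream analyses are expected to recover.

Every draw flows from a single :class:`numpy.random.Generator` seeded in
:class:`SimConfig`, so a fixed seed yields bit-identical sessions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TASKS",
    "UNIMANUAL_TASKS",
    "PHASES",
    "PhaseDurations",
    "DirectionGrid",
    "NeuronGroundTruth",
    "GroundTruthDistributions",
    "SimConfig",
    "rate_function",
    "simulate_session",
    "noiseless_binned_rates",
]

TASKS = ("ipsi", "contra", "bimanual")
UNIMANUAL_TASKS = ("ipsi", "contra")
PHASES = ("prepare", "go", "rest")


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseDurations:
    """Trial phase durations in seconds.

    ``prepare_s`` is a (low, high) range sampled uniformly per trial (the cue
    period is jittered); ``go_s`` and ``rest_s`` are fixed.  ``iti_s`` is the
    inter-trial gap.
    """

    prepare_s: tuple[float, float] = (1.0, 1.5)
    go_s: float = 2.0
    rest_s: float = 1.5
    iti_s: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.prepare_s
        if not (0 < lo <= hi):
            raise ValueError(f"prepare_s range must be 0 < low <= high, got {self.prepare_s}")
        if self.go_s <= 0 or self.rest_s <= 0:
            raise ValueError("go_s and rest_s must be strictly positive")
        if self.iti_s < 0:
            raise ValueError("iti_s must be nonnegative")


@dataclass(frozen=True)
class DirectionGrid:
    """Target directions, degrees counterclockwise from screen-right, in [0, 360).

    Unimanual blocks use 8 directions; bimanual blocks pair 4 directions per
    arm (16 configurations).  The bimanual set must be a subset of the
    unimanual set so "unimanual 4-direction" comparisons are well defined.
    """

    unimanual_dirs_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0)
    bimanual_dirs_deg: tuple[float, ...] = (45.0, 135.0, 225.0, 315.0)

    def __post_init__(self) -> None:
        uni, bi = self.unimanual_dirs_deg, self.bimanual_dirs_deg
        if len(set(uni)) != 8:
            raise ValueError("unimanual grid must contain 8 distinct directions")
        if len(set(bi)) != 4:
            raise ValueError("bimanual grid must contain 4 distinct directions")
        if not set(bi) <= set(uni):
            raise ValueError("bimanual directions must be a subset of the unimanual grid")
        for d in uni:
            if not (0 <= d < 360):
                raise ValueError(f"direction {d} outside [0, 360)")


@dataclass(frozen=True)
class NeuronGroundTruth:
    """Generative tuning parameters of one unit.

    ``md_*`` are cosine half-amplitudes in Hz (the noiseless 8-point tuning
    curve then spans max-min = 2*md when the PD lies on the grid); ``pd_*``
    are preferred directions in degrees.  Separate parameters are held for
    the unimanual and bimanual tasks; during bimanual movements each arm's
    modulation is additionally scaled by ``bimanual_gain_*`` in [0, 1].
    """

    unit_id: str
    baseline_hz: float
    md_uni_ipsi_hz: float
    md_uni_contra_hz: float
    pd_uni_ipsi_deg: float
    pd_uni_contra_deg: float
    md_bi_ipsi_hz: float
    md_bi_contra_hz: float
    pd_bi_ipsi_deg: float
    pd_bi_contra_deg: float
    bimanual_gain_ipsi: float = 0.4
    bimanual_gain_contra: float = 0.8

    def __post_init__(self) -> None:
        if self.baseline_hz < 0:
            raise ValueError("baseline_hz must be nonnegative")
        for name in ("md_uni_ipsi_hz", "md_uni_contra_hz", "md_bi_ipsi_hz", "md_bi_contra_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("pd_uni_ipsi_deg", "pd_uni_contra_deg", "pd_bi_ipsi_deg", "pd_bi_contra_deg"):
            v = getattr(self, name)
            if not (0 <= v < 360):
                raise ValueError(f"{name}={v} outside [0, 360)")
        for name in ("bimanual_gain_ipsi", "bimanual_gain_contra"):
            g = getattr(self, name)
            if not (0 <= g <= 1):
                raise ValueError(f"{name}={g} outside [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronGroundTruth":
        return cls(**d)


@dataclass(frozen=True)
class GroundTruthDistributions:
    """Sampling distributions for per-unit ground truth.

    Defaults describe a population with bilaterally correlated unimanual
    tuning (ipsilateral PD jittered around the contralateral one), identical
    bimanual cosine amplitudes attenuated by asymmetric gains (ipsilateral
    suppressed more strongly), and a 90 degree bimanual PD rotation with
    independent random sign per arm on half the units.
    """

    baseline_hz_range: tuple[float, float] = (4.0, 16.0)
    md_hz_range: tuple[float, float] = (2.0, 8.0)
    md_arm_jitter: tuple[float, float] = (0.7, 1.3)
    pd_ipsi_jitter_sd_deg: float = 30.0
    pd_rotation_frac: float = 0.5
    pd_rotation_deg: float = 90.0
    gain_ipsi: float = 0.4
    gain_contra: float = 0.8

    def sample(self, rng: np.random.Generator, n_units: int) -> list[NeuronGroundTruth]:
        width = len(str(max(n_units - 1, 1)))
        out = []
        for i in range(n_units):
            baseline = rng.uniform(*self.baseline_hz_range)
            # shared per-unit amplitude with per-arm jitter: bilateral response
            # magnitudes are positively correlated across arms, as in real M1 data
            amp = rng.uniform(*self.md_hz_range)
            md_i = amp * rng.uniform(*self.md_arm_jitter)
            md_c = amp * rng.uniform(*self.md_arm_jitter)
            pd_c = rng.uniform(0.0, 360.0)
            pd_i = (pd_c + rng.normal(0.0, self.pd_ipsi_jitter_sd_deg)) % 360.0
            rotator = rng.random() < self.pd_rotation_frac
            rot_i = self.pd_rotation_deg * rng.choice((-1.0, 1.0)) if rotator else 0.0
            rot_c = self.pd_rotation_deg * rng.choice((-1.0, 1.0)) if rotator else 0.0
            out.append(
                NeuronGroundTruth(
                    unit_id=f"u{i:0{width}d}",
                    baseline_hz=baseline,
                    md_uni_ipsi_hz=md_i,
                    md_uni_contra_hz=md_c,
                    pd_uni_ipsi_deg=pd_i,
                    pd_uni_contra_deg=pd_c,
                    md_bi_ipsi_hz=md_i,
                    md_bi_contra_hz=md_c,
                    pd_bi_ipsi_deg=(pd_i + rot_i) % 360.0,
                    pd_bi_contra_deg=(pd_c + rot_c) % 360.0,
                    bimanual_gain_ipsi=self.gain_ipsi,
                    bimanual_gain_contra=self.gain_contra,
                )
            )
        return out


@dataclass(frozen=True)
class SimConfig:
    """Full simulation configuration; a fixed ``rng_seed`` makes output bit-identical."""

    n_units: int = 100
    n_reps_per_config: int = 8
    phases: PhaseDurations = field(default_factory=PhaseDurations)
    grid: DirectionGrid = field(default_factory=DirectionGrid)
    distributions: GroundTruthDistributions = field(default_factory=GroundTruthDistributions)
    noise_model: str = "poisson"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.n_reps_per_config < 1:
            raise ValueError("n_reps_per_config must be >= 1")
        if self.noise_model != "poisson":
            raise ValueError(f"unknown noise model {self.noise_model!r}")


# ---------------------------------------------------------------------------
# rate model
# ---------------------------------------------------------------------------

def _check_tags(task: str, phase: str) -> None:
    if task not in TASKS:
        raise ValueError(f"unknown task tag {task!r}; expected one of {TASKS}")
    if phase not in PHASES:
        raise ValueError(f"unknown phase tag {phase!r}; expected one of {PHASES}")


def rate_function(
    gt: NeuronGroundTruth,
    task: str,
    phase: str,
    ipsi_dir_deg: float | None = None,
    contra_dir_deg: float | None = None,
) -> float:
    """Instantaneous firing rate (Hz) of one unit in one task phase.

    Prepare and Rest return the baseline rate regardless of directions.
    During the Go phase a unimanual task adds one arm's cosine modulation,
    ``baseline + md * cos(theta - pd)``; the bimanual task adds both arms'
    bimanual components scaled by their gains.  Negative rates are clipped
    to zero.
    """
    _check_tags(task, phase)
    if phase in ("prepare", "rest"):
        return gt.baseline_hz

    def _cos(theta_deg: float, pd_deg: float) -> float:
        return float(np.cos(np.deg2rad(theta_deg - pd_deg)))

    if task == "ipsi":
        if ipsi_dir_deg is None:
            raise ValueError("ipsi task requires ipsi_dir_deg")
        if contra_dir_deg is not None:
            raise ValueError("ipsi task takes no contra_dir_deg")
        r = gt.baseline_hz + gt.md_uni_ipsi_hz * _cos(ipsi_dir_deg, gt.pd_uni_ipsi_deg)
    elif task == "contra":
        if contra_dir_deg is None:
            raise ValueError("contra task requires contra_dir_deg")
        if ipsi_dir_deg is not None:
            raise ValueError("contra task takes no ipsi_dir_deg")
        r = gt.baseline_hz + gt.md_uni_contra_hz * _cos(contra_dir_deg, gt.pd_uni_contra_deg)
    else:  # bimanual
        if ipsi_dir_deg is None or contra_dir_deg is None:
            raise ValueError("bimanual task requires both ipsi_dir_deg and contra_dir_deg")
        r = (
            gt.baseline_hz
            + gt.bimanual_gain_contra * gt.md_bi_contra_hz * _cos(contra_dir_deg, gt.pd_bi_contra_deg)
            + gt.bimanual_gain_ipsi * gt.md_bi_ipsi_hz * _cos(ipsi_dir_deg, gt.pd_bi_ipsi_deg)
        )
    return max(0.0, r)


def _go_rate_vector(
    gts: Sequence[NeuronGroundTruth],
    task: str,
    ipsi_dir: float | None,
    contra_dir: float | None,
) -> np.ndarray:
    """Vectorized Go-phase rates for the whole population (same model as rate_function)."""
    base = np.array([g.baseline_hz for g in gts])
    if task == "ipsi":
        md = np.array([g.md_uni_ipsi_hz for g in gts])
        pd = np.array([g.pd_uni_ipsi_deg for g in gts])
        r = base + md * np.cos(np.deg2rad(ipsi_dir - pd))
    elif task == "contra":
        md = np.array([g.md_uni_contra_hz for g in gts])
        pd = np.array([g.pd_uni_contra_deg for g in gts])
        r = base + md * np.cos(np.deg2rad(contra_dir - pd))
    else:
        md_c = np.array([g.bimanual_gain_contra * g.md_bi_contra_hz for g in gts])
        pd_c = np.array([g.pd_bi_contra_deg for g in gts])
        md_i = np.array([g.bimanual_gain_ipsi * g.md_bi_ipsi_hz for g in gts])
        pd_i = np.array([g.pd_bi_ipsi_deg for g in gts])
        r = base + md_c * np.cos(np.deg2rad(contra_dir - pd_c)) + md_i * np.cos(np.deg2rad(ipsi_dir - pd_i))
    return np.clip(r, 0.0, None)


# ---------------------------------------------------------------------------
# session simulation
# ---------------------------------------------------------------------------

def _block_configs(task: str, grid: DirectionGrid) -> list[tuple[float | None, float | None]]:
    """(ipsi_dir, contra_dir) target list for one block."""
    if task == "ipsi":
        return [(d, None) for d in grid.unimanual_dirs_deg]
    if task == "contra":
        return [(None, d) for d in grid.unimanual_dirs_deg]
    return [(di, dc) for di in grid.bimanual_dirs_deg for dc in grid.bimanual_dirs_deg]


def simulate_session(
    config: SimConfig, tasks: Sequence[str] = TASKS
) -> tuple[pd.DataFrame, pd.DataFrame, list[NeuronGroundTruth]]:
    """Simulate one recording session.

    Returns ``(spikes, trials, ground_truth)``: a spike table (``unit_id``,
    ``time_s``; sorted by time within unit), a trial table (phase onsets,
    block type, per-arm target directions), and the per-unit generative
    parameters.  One block per requested task, blocks in a seeded
    pseudorandom order; trial order within a block is a seeded permutation
    of ``n_reps_per_config`` repetitions of the block's configuration set.
    Spikes are an inhomogeneous Poisson process, piecewise-constant at the
    phase rate.
    """
    if len(tasks) == 0:
        raise ValueError("task list must not be empty")
    for t in tasks:
        if t not in TASKS:
            raise ValueError(f"unknown task tag {t!r}")
    rng = np.random.default_rng(config.rng_seed)
    gts = config.distributions.sample(rng, config.n_units)
    n_units = len(gts)
    base_rates = np.array([g.baseline_hz for g in gts])

    block_order = [tasks[i] for i in rng.permutation(len(tasks))]

    trial_rows: list[dict] = []
    spike_times: list[np.ndarray] = []
    spike_units: list[np.ndarray] = []
    t_cursor = 0.0
    trial_id = 0
    ph = config.phases

    def _emit(rates: np.ndarray, t0: float, dur: float) -> None:
        counts = rng.poisson(rates * dur)
        total = int(counts.sum())
        if total == 0:
            return
        spike_units.append(np.repeat(np.arange(n_units), counts))
        spike_times.append(t0 + rng.random(total) * dur)

    for block_id, task in enumerate(block_order):
        configs = _block_configs(task, config.grid)
        reps = configs * config.n_reps_per_config
        order = rng.permutation(len(reps))
        for k in order:
            ipsi_dir, contra_dir = reps[k]
            prep_dur = rng.uniform(*ph.prepare_s)
            prepare_onset = t_cursor
            go_onset = prepare_onset + prep_dur
            rest_onset = go_onset + ph.go_s
            end = rest_onset + ph.rest_s

            _emit(base_rates, prepare_onset, prep_dur)
            _emit(_go_rate_vector(gts, task, ipsi_dir, contra_dir), go_onset, ph.go_s)
            _emit(base_rates, rest_onset, ph.rest_s)

            trial_rows.append(
                dict(
                    trial_id=trial_id,
                    block_id=block_id,
                    block_type=task,
                    prepare_onset_s=prepare_onset,
                    go_onset_s=go_onset,
                    rest_onset_s=rest_onset,
                    end_s=end,
                    ipsi_dir_deg=np.nan if ipsi_dir is None else float(ipsi_dir),
                    contra_dir_deg=np.nan if contra_dir is None else float(contra_dir),
                )
            )
            trial_id += 1
            t_cursor = end + ph.iti_s

    trials = pd.DataFrame(trial_rows)
    if spike_times:
        units = np.concatenate(spike_units)
        times = np.concatenate(spike_times)
        order = np.lexsort((times, units))
        unit_ids = np.array([g.unit_id for g in gts])
        spikes = pd.DataFrame({"unit_id": unit_ids[units[order]], "time_s": times[order]})
    else:
        spikes = pd.DataFrame({"unit_id": pd.Series(dtype=str), "time_s": pd.Series(dtype=float)})
    return spikes, trials, gts


def noiseless_binned_rates(
    gts: Sequence[NeuronGroundTruth], trials: pd.DataFrame, bin_s: float = 0.02
):
    """Exact per-bin rates for a trial table, bypassing Poisson sampling.

    Evaluates :func:`rate_function` on each bin of each trial (bins aligned
    to Prepare onset, phase assigned by bin start).  This is the analytic
    oracle for preprocessing: with smoothing disabled and phase boundaries
    aligned to the bin grid, downstream responses must reproduce the cosine
    tuning exactly.
    """
    from .preprocess import BinnedRates  # local import to avoid a cycle

    unit_ids = [g.unit_id for g in gts]
    rates_per_trial = []
    starts_per_trial = []
    for row in trials.itertuples(index=False):
        t0, t1 = row.prepare_onset_s, row.end_s
        n_bins = int(np.floor((t1 - t0) / bin_s + 1e-9))
        starts = t0 + np.arange(n_bins) * bin_s
        ipsi_dir = None if pd.isna(row.ipsi_dir_deg) else float(row.ipsi_dir_deg)
        contra_dir = None if pd.isna(row.contra_dir_deg) else float(row.contra_dir_deg)
        mat = np.empty((len(gts), n_bins))
        go_mask = (starts >= row.go_onset_s - 1e-9) & (starts < row.rest_onset_s - 1e-9)
        for u, g in enumerate(gts):
            base = rate_function(g, row.block_type, "prepare")
            go = rate_function(g, row.block_type, "go", ipsi_dir, contra_dir)
            mat[u] = np.where(go_mask, go, base)
        rates_per_trial.append(mat)
        starts_per_trial.append(starts)
    return BinnedRates(
        bin_s=bin_s,
        unit_ids=list(unit_ids),
        trial_ids=trials["trial_id"].to_numpy(),
        rates=rates_per_trial,
        bin_starts=starts_per_trial,
    )
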