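"""End-to-end driver: simulate (optional) -> preprocess -> tuning -> decode -> stats.

``run_pipeline`` executes every stage on a simulated or on-disk session and
writes all per-unit tables plus a ``summary.json``/``summary.md`` report of
the population quantities: unit counts by task-relatedness, preference-index
statistics and quadrant fractions, bilateral-correlation distributions and
strong-cc fractions, MD and PD-shift summaries, the response scatter fit,
the population response ratio, and decoder Top-N accuracies.  Every number
in the summary is recomputable from the emitted CSVs.  A fixed seed yields a
byte-identical summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decoding import bimanual_per_arm_decode, build_features, loocv_decode
from .io import read_session, write_session
from .preprocess import (
    bin_and_smooth,
    classify_task_related,
    compute_baseline,
    compute_responses,
    select_units,
)
from .simulate import (
    TASKS,
    DirectionGrid,
    GroundTruthDistributions,
    PhaseDurations,
    SimConfig,
    simulate_session,
)
from .stats import fit_response_scatter, one_sample_t, paired_t, population_ratio
from .tuning import (
    classify_quadrants,
    delta_pd_change_stats,
    md_difference_stats,
    pd_shift_stats,
    strong_cc_fraction,
    summarize_tuning,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters in one place; YAML-loadable."""

    session_dir: str | None = None  # read an existing session instead of simulating
    tasks: tuple[str, ...] = TASKS
    sim: SimConfig = field(default_factory=SimConfig)
    bin_ms: float = 20.0
    kernel_sd_ms: float = 300.0
    min_rate_hz: float = 1.0
    restrict_to_all_task_related: bool = True
    cc_strong: float = 0.75
    decode: bool = True
    svm_c: float = 1.0
    standardize: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            sim = dict(sim)
            phases = sim.pop("phases", {})
            grid = sim.pop("grid", {})
            dists = sim.pop("distributions", {})
            for sub in (phases, grid, dists):
                if isinstance(sub, dict):
                    for k, v in sub.items():
                        if isinstance(v, list):
                            sub[k] = tuple(v)
            sim = SimConfig(
                phases=PhaseDurations(**phases) if isinstance(phases, dict) else phases,
                grid=DirectionGrid(**grid) if isinstance(grid, dict) else grid,
                distributions=(
                    GroundTruthDistributions(**dists) if isinstance(dists, dict) else dists
                ),
                **sim,
            )
        if "tasks" in d:
            d["tasks"] = tuple(d["tasks"])
        return cls(sim=sim, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _series_stats(x: pd.Series) -> dict:
    x = x.dropna()
    return dict(
        n=int(len(x)),
        mean=float(x.mean()),
        median=float(x.median()),
        sd=float(x.std(ddof=1)) if len(x) > 1 else 0.0,
    )


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-12s %.2f s", name, t1 - t0)
    return t1


def run_pipeline(config: PipelineConfig, out_dir: str | Path, seed: int | None = None) -> dict:
    """Run every stage and write the report bundle into ``out_dir``.

    ``seed`` overrides the simulation seed in ``config`` (ignored when
    reading a session from disk).  Returns the summary dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    # --- acquire session ---------------------------------------------------
    if config.session_dir is not None:
        spikes, trials = read_session(config.session_dir)
        sim_seed = None
    else:
        sim = config.sim
        if seed is not None:
            sim = dataclasses.replace(sim, rng_seed=seed)
        sim_seed = sim.rng_seed
        spikes, trials, gts = simulate_session(sim, config.tasks)
        write_session(spikes, trials, out / "session", ground_truth=gts)
    t0 = _stage("session", t0)

    # --- preprocessing -----------------------------------------------------
    rates = bin_and_smooth(spikes, trials, bin_ms=config.bin_ms, kernel_sd_ms=config.kernel_sd_ms)
    n_units_total = rates.n_units
    selected = select_units(rates, trials, threshold_hz=config.min_rate_hz)
    n_excluded_rate = n_units_total - len(selected)
    if n_excluded_rate:
        logger.info("excluded %d units below %.3g Hz grand mean", n_excluded_rate, config.min_rate_hz)
    keep = [u in selected for u in rates.unit_ids]
    rates.rates = [m[keep] for m in rates.rates]
    rates.unit_ids = [u for u in rates.unit_ids if u in set(selected)]

    baseline = compute_baseline(rates, trials)
    responses = compute_responses(rates, trials, baseline)
    relatedness = classify_task_related(responses, baseline)
    baseline.to_csv(out / "baseline.csv", index=False)
    resp_out = responses.copy()
    sd = baseline.set_index("unit_id")["sd_hz"]
    resp_out["modulation_ratio"] = [
        abs(r) / sd[u] if sd[u] > 0 else (0.0 if r == 0 else np.inf)
        for r, u in zip(resp_out["response_hz"], resp_out["unit_id"])
    ]
    resp_out.to_csv(out / "responses.csv", index=False)
    relatedness.to_csv(out / "task_relatedness.csv", index=False)
    t0 = _stage("preprocess", t0)

    tasks_present = list(dict.fromkeys(trials["block_type"]))
    n_tasks = len(tasks_present)
    all_related = relatedness.loc[relatedness["n_task_related"] == n_tasks, "unit_id"]
    if config.restrict_to_all_task_related:
        analysis_units = set(all_related)
        n_excluded_rel = len(selected) - len(analysis_units)
        if n_excluded_rel:
            logger.info("excluded %d units not related to every task", n_excluded_rel)
        responses_a = responses[responses["unit_id"].isin(analysis_units)]
    else:
        responses_a = responses

    # --- tuning ------------------------------------------------------------
    summary_t = summarize_tuning(responses_a)
    summary_t.to_csv(out / "tuning_summary.csv", index=False)

    report: dict = {
        "config": config.to_dict(),
        "seed": sim_seed,
        "n_units_total": int(n_units_total),
        "n_units_selected": int(len(selected)),
        "n_units_analyzed": int(responses_a["unit_id"].nunique()),
        "task_related_counts": {
            cat: int(n) for cat, n in relatedness["category"].value_counts().sort_index().items()
        },
    }

    has_uni = {"ipsi", "contra"} <= set(tasks_present)
    has_bi = "bimanual" in tasks_present

    if has_uni:
        uni = summary_t[summary_t["task"] == "unimanual-8"].set_index("unit_id")
        pref: dict = {"unimanual": _series_stats(uni["preference_index"])}
        idx_uni = uni["preference_index"].dropna()
        if len(idx_uni) >= 2 and np.ptp(idx_uni) > 0:
            pref["unimanual_vs_zero"] = one_sample_t(idx_uni).to_dict()
        fit_u = fit_response_scatter(uni["max_abs_ipsi_hz"], uni["max_abs_contra_hz"])
        report["fit_unimanual"] = fit_u.to_dict()
        report["population_ratio_unimanual_pct"] = population_ratio(
            uni["max_abs_ipsi_hz"], uni["max_abs_contra_hz"]
        )
        if has_bi:
            bi = summary_t[summary_t["task"] == "bimanual-4"].set_index("unit_id")
            pref["bimanual"] = _series_stats(bi["preference_index"])
            idx_bi = bi["preference_index"].dropna()
            if len(idx_bi) >= 2 and np.ptp(idx_bi) > 0:
                pref["bimanual_vs_zero"] = one_sample_t(idx_bi).to_dict()
            common = idx_uni.index.intersection(idx_bi.index)
            pref["paired_uni_vs_bi"] = paired_t(idx_uni[common], idx_bi[common]).to_dict()
            per_unit_q, counts_q = classify_quadrants(
                pd.DataFrame(
                    {
                        "unit_id": common,
                        "uni_index": idx_uni[common].to_numpy(),
                        "bi_index": idx_bi[common].to_numpy(),
                    }
                )
            )
            per_unit_q.to_csv(out / "quadrants.csv", index=False)
            report["quadrants"] = {
                r.quadrant: {"n": int(r.n), "fraction": float(r.fraction)}
                for r in counts_q.itertuples()
            }
            fit_b = fit_response_scatter(bi["max_abs_ipsi_hz"], bi["max_abs_contra_hz"])
            report["fit_bimanual"] = fit_b.to_dict()
            report["population_ratio_bimanual_pct"] = population_ratio(
                bi["max_abs_ipsi_hz"], bi["max_abs_contra_hz"]
            )
        report["preference"] = pref

        # bilateral correlations and MDs per task tag
        corr: dict = {}
        mds: dict = {}
        for task in ("unimanual-8", "unimanual-4", "bimanual-4"):
            sub = summary_t[summary_t["task"] == task]
            if len(sub) == 0:
                continue
            cs = _series_stats(sub["bilateral_cc"])
            cs["strong_fraction"] = strong_cc_fraction(sub["bilateral_cc"], config.cc_strong)
            cc_vals = sub["bilateral_cc"].dropna()
            if len(cc_vals) >= 2 and np.ptp(cc_vals) > 0:
                cs["vs_zero"] = one_sample_t(cc_vals).to_dict()
            corr[task] = cs
            mds[task] = {
                "ipsi": _series_stats(sub["md_ipsi_hz"]),
                "contra": _series_stats(sub["md_contra_hz"]),
            }
        if has_bi:
            u4 = summary_t[summary_t["task"] == "unimanual-4"].set_index("unit_id")
            b4 = summary_t[summary_t["task"] == "bimanual-4"].set_index("unit_id")
            common = u4.index.intersection(b4.index)
            if len(common) >= 2:
                cc_pair = pd.DataFrame(
                    {"u": u4.loc[common, "bilateral_cc"], "b": b4.loc[common, "bilateral_cc"]}
                ).dropna()
                if len(cc_pair) >= 2 and np.ptp(cc_pair["u"] - cc_pair["b"]) > 0:
                    corr["paired_uni4_vs_bi"] = paired_t(cc_pair["u"], cc_pair["b"]).to_dict()
                for arm in ("ipsi", "contra"):
                    a = u4.loc[common, f"md_{arm}_hz"]
                    b = b4.loc[common, f"md_{arm}_hz"]
                    if np.ptp(a - b) > 0:
                        mds[f"paired_uni4_vs_bi_{arm}"] = paired_t(a, b).to_dict()
        report["bilateral_correlation"] = corr
        report["modulation_depth"] = mds
        report["md_difference"] = {
            r.task: {
                "n": int(r.n),
                "mean_diff_hz": float(r.mean_diff_hz),
                "median_diff_hz": float(r.median_diff_hz),
                "n_contra_larger": int(r.n_contra_larger),
            }
            for r in md_difference_stats(summary_t).itertuples()
        }
        if has_bi:
            shifts = pd_shift_stats(summary_t)
            shifts.pop("per_unit").to_csv(out / "pd_shifts.csv", index=False)
            report["pd_shifts"] = shifts
            report["delta_pd"] = delta_pd_change_stats(summary_t)
    t0 = _stage("tuning", t0)

    # --- decoding ----------------------------------------------------------
    if config.decode:
        dec: dict = {}
        for block_id, block in trials.groupby("block_id"):
            btype = block["block_type"].iloc[0]
            feats = build_features(rates, trials, baseline, block_id=int(block_id))
            res = loocv_decode(feats, C=config.svm_c, standardize=config.standardize)
            res.write_json(out / f"decode_block{block_id}_{btype}.json")
            res.confusion_frame().to_csv(out / f"confusion_block{block_id}_{btype}.csv")
            entry = {"block_type": btype, "topn_pct": {str(k): v for k, v in res.topn_pct.items()}}
            if btype == "bimanual":
                r_i, r_c = bimanual_per_arm_decode(feats, C=config.svm_c, standardize=config.standardize)
                r_i.write_json(out / f"decode_block{block_id}_bimanual_ipsi_dir.json")
                r_c.write_json(out / f"decode_block{block_id}_bimanual_contra_dir.json")
                entry["per_arm_top1_pct"] = {"ipsi": r_i.top1_pct, "contra": r_c.top1_pct}
                entry["per_arm_topn_pct"] = {
                    "ipsi": {str(k): v for k, v in r_i.topn_pct.items()},
                    "contra": {str(k): v for k, v in r_c.topn_pct.items()},
                }
            dec[f"block{block_id}"] = entry
        report["decoding"] = dec
        t0 = _stage("decode", t0)

    # --- report bundle -----------------------------------------------------
    manifest = {
        "package": "bilat",
        "version": __version__,
        "seed": sim_seed,
        "config": config.to_dict(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    with open(out / "summary.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    _write_markdown(report, out / "summary.md")
    return report


def _write_markdown(report: dict, path: Path) -> None:
    lines = ["# Session summary", ""]
    lines.append(f"- units recorded: {report['n_units_total']}")
    lines.append(f"- units above rate threshold: {report['n_units_selected']}")
    lines.append(f"- units analyzed (task-related): {report['n_units_analyzed']}")
    for cat, n in report.get("task_related_counts", {}).items():
        lines.append(f"  - {cat}: {n}")
    if "preference" in report:
        lines.append("")
        lines.append("## Contralateral preference index")
        for k, v in report["preference"].items():
            if isinstance(v, dict) and "mean" in v and "t" not in v:
                lines.append(f"- {k}: mean {v['mean']:+.3f}, median {v['median']:+.3f} (n={v['n']})")
            elif isinstance(v, dict) and "p" in v:
                lines.append(f"- {k}: t={v['t']:+.2f}, p={v['p']:.3g}")
    if "quadrants" in report:
        lines.append("")
        lines.append("## Preference quadrants (unimanual -> bimanual)")
        for q, v in report["quadrants"].items():
            lines.append(f"- {q}: {v['n']} ({100 * v['fraction']:.1f}%)")
    if "bilateral_correlation" in report:
        lines.append("")
        lines.append("## Bilateral tuning-curve correlation")
        for task, v in report["bilateral_correlation"].items():
            if "strong_fraction" in v:
                lines.append(
                    f"- {task}: mean {v['mean']:+.3f}, median {v['median']:+.3f}, "
                    f"strong (cc>thr) fraction {v['strong_fraction']:.3f}"
                )
    if "decoding" in report:
        lines.append("")
        lines.append("## Decoding (LOOCV linear SVM, top-1 %)")
        for block, v in report["decoding"].items():
            top1 = v["topn_pct"]["1"]
            extra = ""
            if "per_arm_top1_pct" in v:
                pa = v["per_arm_top1_pct"]
                extra = f" | per-arm ipsi {pa['ipsi']:.1f}%, contra {pa['contra']:.1f}%"
            lines.append(f"- {block} ({v['block_type']}): {top1:.1f}%{extra}")
    path.write_text("\n".join(lines) + "\n")
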