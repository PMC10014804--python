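import numpy as np
import pandas as pd
import pytest

from bilat import NeuronGroundTruth, SimConfig, simulate_session


@pytest.fixture(scope="session")
def tiny_session():
    """Small three-block session reused by read-only tests."""
    cfg = SimConfig(n_units=6, n_reps_per_config=2, rng_seed=11)
    return simulate_session(cfg)


@pytest.fixture
def make_trial_table():
    """Factory for hand-built trial tables with bin-aligned phase boundaries."""

    def _make(configs, prepare_s=1.2, go_s=2.0, rest_s=1.4, iti_s=0.5, reps=1):
        rows = []
        t = 0.0
        tid = 0
        block_ids = {}
        for _ in range(reps):
            for block_type, ipsi, contra in configs:
                bid = block_ids.setdefault(block_type, len(block_ids))
                rows.append(
                    dict(
                        trial_id=tid,
                        block_id=bid,
                        block_type=block_type,
                        prepare_onset_s=t,
                        go_onset_s=t + prepare_s,
                        rest_onset_s=t + prepare_s + go_s,
                        end_s=t + prepare_s + go_s + rest_s,
                        ipsi_dir_deg=np.nan if ipsi is None else float(ipsi),
                        contra_dir_deg=np.nan if contra is None else float(contra),
                    )
                )
                t += prepare_s + go_s + rest_s + iti_s
                tid += 1
        return pd.DataFrame(rows)

    return _make


@pytest.fixture
def make_gt():
    """Factory for a ground-truth unit with identical unimanual/bimanual tuning."""

    def _make(
        unit_id="u0",
        baseline=20.0,
        md_ipsi=5.0,
        md_contra=5.0,
        pd_ipsi=90.0,
        pd_contra=90.0,
        md_bi_ipsi=None,
        md_bi_contra=None,
        pd_bi_ipsi=None,
        pd_bi_contra=None,
        gain_ipsi=0.4,
        gain_contra=0.8,
    ):
        return NeuronGroundTruth(
            unit_id=unit_id,
            baseline_hz=baseline,
            md_uni_ipsi_hz=md_ipsi,
            md_uni_contra_hz=md_contra,
            pd_uni_ipsi_deg=pd_ipsi,
            pd_uni_contra_deg=pd_contra,
            md_bi_ipsi_hz=md_ipsi if md_bi_ipsi is None else md_bi_ipsi,
            md_bi_contra_hz=md_contra if md_bi_contra is None else md_bi_contra,
            pd_bi_ipsi_deg=pd_ipsi if pd_bi_ipsi is None else pd_bi_ipsi,
            pd_bi_contra_deg=pd_contra if pd_bi_contra is None else pd_bi_contra,
            bimanual_gain_ipsi=gain_ipsi,
            bimanual_gain_contra=gain_contra,
        )

    return _make
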