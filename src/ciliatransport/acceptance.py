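"""Headline quantities recomputed from scratch on fresh simulations.

Each function simulates the relevant observation campaign with the
packaged preset, runs the full pipeline (register -> kymograph -> trace
detection -> longest-segment scoring -> statistics) and measures the
quantity.  Because a single 34- or 64-minute campaign carries full
Poisson counting noise (sd ~ sqrt(n) events), every headline quantity is
averaged over ``N_REPLICATES`` independent replicate campaigns: counts
are reported as the per-campaign mean, velocities over the pooled
events.  :func:`compute_targets` bundles everything for the acceptance
script and the ``accept`` CLI subcommand.
"""

from __future__ import annotations

import numpy as np

from .pipeline import SessionResult, run_ift_session, run_stack_pair, run_transport_session
from .presets import load_preset
from .stats import compare_groups, velocity_stats

__all__ = ["compute_targets", "replicate_sessions", "N_REPLICATES"]

#: independent repeats of each simulated observation campaign
N_REPLICATES = 3


def replicate_sessions(preset_name: str, seed: int, n_replicates: int = N_REPLICATES
                       ) -> list[SessionResult]:
    """Run ``n_replicates`` independent full-pipeline sessions of a preset."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    preset = load_preset(preset_name)
    return [run_transport_session(preset, seed=int(s)) for s in seeds]


def pooled_events(sessions: list[SessionResult]) -> list:
    return [e for s in sessions for e in s.events]


def mean_count(sessions: list[SessionResult], direction: str) -> float:
    return float(np.mean([s.count(direction) for s in sessions]))


def compute_targets(seed: int) -> dict:
    """Recompute the pipeline's headline quantities.

    Returns a mapping of short target ids to ``{"value", "n"}`` records:

    * ``t1``/``t2`` — wild-type anterograde/retrograde mean velocities
      (um/s), pooled over the replicate 34-minute campaigns;
    * ``t3``/``t4`` — mean anterograde event count per 34-minute
      wild-type campaign and per 64-minute mutant campaign;
    * ``t5``/``t6`` — middle/distal-segment anterograde IFT velocities
      (um/s), pooled over replicate campaigns;
    * ``t7`` — mutant/wild-type total ciliary fluorescence ratio (%),
      averaged over replicate stack pairs.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=4)

    wt_sessions = replicate_sessions("WT", int(seeds[0]))
    chb3_sessions = replicate_sessions("chb3", int(seeds[1]))
    wt_events = pooled_events(wt_sessions)
    chb3_events = pooled_events(chb3_sessions)
    wt_time = sum(s.total_time_min for s in wt_sessions)
    wt_stats = velocity_stats(wt_events, wt_time)

    ift_rng = np.random.default_rng(int(seeds[2]))
    middle_v, distal_v = [], []
    for s in ift_rng.integers(0, 2**31 - 1, size=N_REPLICATES):
        _, middle, distal = run_ift_session(seed=int(s))
        middle_v.append(middle.velocities_um_s)
        distal_v.append(distal.velocities_um_s)
    middle_v = np.concatenate(middle_v)
    distal_v = np.concatenate(distal_v)

    stack_rng = np.random.default_rng(int(seeds[3]))
    ratios = [
        run_stack_pair(seed=int(s))["measured_ratio_percent"]
        for s in stack_rng.integers(0, 2**31 - 1, size=N_REPLICATES)
    ]

    welch = compare_groups(wt_events, chb3_events, "anterograde")

    values = {
        "t1": {"value": wt_stats.anterograde.mean_velocity_um_s,
               "n": wt_stats.anterograde.n},
        "t2": {"value": wt_stats.retrograde.mean_velocity_um_s,
               "n": wt_stats.retrograde.n},
        "t3": {"value": mean_count(wt_sessions, "anterograde"), "n": len(wt_sessions)},
        "t4": {"value": mean_count(chb3_sessions, "anterograde"), "n": len(chb3_sessions)},
        "t5": {"value": float(middle_v.mean()), "n": len(middle_v)},
        "t6": {"value": float(distal_v.mean()), "n": len(distal_v)},
        "t7": {"value": float(np.mean(ratios)), "n": len(ratios)},
        "welch_wt_vs_chb3_p": {"value": welch.p_value,
                               "n": len(wt_events) + len(chb3_events)},
    }
    return {k: {"value": float(v["value"]), "n": int(v["n"])} for k, v in values.items()}
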