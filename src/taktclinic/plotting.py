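"""Optional figures: resource profiles over the day and wait vs reaction time."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .demand import sample_arrivals
from .des_engine import PredictivePolicy, simulate
from .experiments import ClinicBundle, ExperimentResult


def plot_resource_profiles(bundle: ClinicBundle, seed: int,
                           path: str | Path) -> None:
    """Static vs predictive per-slot total resources for one sampled day."""
    clinic = bundle.clinic
    stream = sample_arrivals(bundle.profile, clinic, seed)
    log = simulate(clinic, stream, PredictivePolicy(bundle.profile), seed)
    slots = bundle.static_plan().slot_starts
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.step(slots, bundle.static_plan().total_per_slot(), where="post",
            label="static", color="grey")
    ax.step(slots, log.final_plan.total_per_slot(), where="post",
            label="predictive", color="tab:blue")
    ax.set_xlabel("minutes since opening")
    ax.set_ylabel("total allocated resources")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_wait_vs_reaction(result: ExperimentResult,
                          path: str | Path) -> None:
    """Aggregate mean wait (+/- SE) against reaction time."""
    agg = result.aggregates_dataframe().sort_values("reaction_time")
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.errorbar(agg["reaction_time"], agg["mean_wait"],
                yerr=agg["mean_wait_se"], marker="o")
    ax.set_xlabel("reaction time (min)")
    ax.set_ylabel("mean waiting time (min)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
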