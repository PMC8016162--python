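"""Bundled summary datasets of the TRAAK force-field comparison campaign.

The raw microsecond trajectories behind these summaries are not
distributable, but the run-level bookkeeping is: the design of the
32 x 1 us campaign with recorded conduction-event counts, gating states
and lipid flags, and the relative populations of the recurring
selectivity-filter states per simulation condition.  These tables drive
the bookkeeping analyses (conductance lines, event totals, state-
population sums) without any trajectory input.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import ReplicaMeta, load_replica_registry

__all__ = ["load_campaign_registry", "load_state_populations", "campaign_event_counts"]


def _data_path(name: str):
    return resources.files("k2ptraj.data") / name


def load_campaign_registry() -> list[ReplicaMeta]:
    """The 32-replica campaign registry with recorded event counts."""
    with resources.as_file(_data_path("traak_campaign.yaml")) as path:
        return load_replica_registry(path)


def load_state_populations() -> pd.DataFrame:
    """Relative SF state populations (%) per condition, states I-VII + other."""
    with resources.as_file(_data_path("sf_state_populations.csv")) as path:
        return pd.read_csv(path, index_col="condition")


def campaign_event_counts(
    registry: list[ReplicaMeta],
    force_field: str,
    init_config: str,
    voltage_mV: float,
) -> tuple[list[int], list[float]]:
    """Event counts and durations of one (force field, SF config, voltage) cell."""
    rows = [
        r for r in registry
        if r.force_field == force_field
        and r.init_config == init_config
        and r.voltage_mV == voltage_mV
    ]
    if any(r.n_events is None for r in rows):
        raise ValueError("registry rows lack recorded event counts")
    return [r.n_events for r in rows], [r.duration_us for r in rows]
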