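"""End-to-end convenience: simulate -> filter -> collapse -> usage.

Shared by the acceptance script and the high-level tests so both measure
exactly the same computation.
"""

from __future__ import annotations

import numpy as np

from .repio import collapse_unique, filter_records
from .simulate import SimulationParams, simulate_repertoire
from .stats import UsageProfile, ighj_usage


def simulated_usage(seed: int, n_total: int = 50_000, mode: str = "calibrated") -> UsageProfile:
    """Usage profile of one calibrated simulation run through the full pipeline."""
    table = simulate_repertoire(params=SimulationParams(n_total=n_total, seed=seed, mode=mode))
    unique = collapse_unique(filter_records(table))
    return ighj_usage(unique)


def mean_usage_over_seeds(
    seeds: list[int], n_total: int = 50_000, mode: str = "calibrated"
) -> dict[str, float]:
    """Per-gene usage frequencies averaged over independent simulation seeds."""
    profiles = [simulated_usage(s, n_total=n_total, mode=mode) for s in seeds]
    genes = sorted({g for p in profiles for g in p.frequencies})
    return {g: float(np.mean([p.frequencies.get(g, 0.0) for p in profiles])) for g in genes}
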