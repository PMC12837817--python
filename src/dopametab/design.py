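"""Experimental-design arithmetic for colony-level pharmacological dosing.

Bromocriptine was delivered to whole colonies by fine-mist spray; the
per-bee exposure is the colony dose divided by the worker population.
"""

from __future__ import annotations

__all__ = ["colony_dose_mg", "dose_per_bee_ug"]


def colony_dose_mg(n_tablets: int = 12, mg_per_tablet: float = 2.5) -> float:
    """Total drug mass per colony in mg (tablets dissolved into the spray)."""
    if n_tablets < 0 or mg_per_tablet < 0:
        raise ValueError("tablet count and mass must be non-negative")
    return n_tablets * mg_per_tablet


def dose_per_bee_ug(
    n_tablets: int = 12,
    mg_per_tablet: float = 2.5,
    n_workers: int = 15_000,
) -> float:
    """Estimated exposure per worker bee in µg.

    Default parameters reproduce the colony-level dosing scheme:
    twelve 2.5 mg tablets (30 mg/colony) over ~15,000 workers = 2 µg/bee.
    """
    if n_workers <= 0:
        raise ValueError("n_workers must be positive")
    return colony_dose_mg(n_tablets, mg_per_tablet) * 1000.0 / n_workers
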