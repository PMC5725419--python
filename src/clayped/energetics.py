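"""Interlayer hydration energetics.

The hydration energy per water molecule of an interlayer with N waters is

    dU_H = ( <U(N)> - <U(0)> ) / N

where <U(N)> is the mean potential energy of the equilibrated hydrated system
and <U(0)> that of the fully dehydrated one.  Compared against the mean
potential energy of bulk SPC water (-33.25 kJ/mol): when dU_H is strictly
lower, intercalating water is more favourable than bulk water and the layers
are prone to rehydrate (swell).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EnergySeries

__all__ = ["BULK_WATER_ENERGY", "HydrationEnergyResult", "hydration_energy"]

#: mean potential energy of bulk SPC water, kJ/mol per molecule
BULK_WATER_ENERGY = -33.25


@dataclass
class HydrationEnergyResult:
    """Hydration energy per water with block-averaged uncertainty."""

    delta_u: float
    delta_u_se: float
    n_water: int
    u_n_mean: float
    u_0_mean: float
    reference: float
    will_rehydrate: bool


def _block_se(x: np.ndarray, n_blocks: int = 5) -> float:
    """Standard error of the mean via block averaging (guards short series)."""
    n_blocks = max(1, min(n_blocks, len(x)))
    blocks = np.array_split(x, n_blocks)
    means = np.array([b.mean() for b in blocks])
    if n_blocks == 1:
        return 0.0
    return float(means.std(ddof=1) / np.sqrt(n_blocks))


def hydration_energy(
    series_n: EnergySeries,
    series_0: EnergySeries,
    reference: float = BULK_WATER_ENERGY,
    n_blocks: int = 5,
) -> HydrationEnergyResult:
    """Per-water hydration energy of an interlayer and its swelling verdict.

    ``series_n`` is the equilibrated energy series of the system with
    ``series_n.n_water`` > 0 waters, ``series_0`` that of the dry system.
    The uncertainty combines the two series' block-averaged standard errors.
    ``will_rehydrate`` uses a strict inequality against the reference, so the
    exact boundary value does not classify as swelling.
    """
    if series_0.n_water != 0:
        raise ValueError("series_0 must come from the fully dehydrated system (N = 0)")
    if series_n.n_water <= 0:
        raise ValueError("series_n must have a positive water count")
    u_n = float(series_n.energies.mean())
    u_0 = float(series_0.energies.mean())
    n = series_n.n_water
    delta = (u_n - u_0) / n
    se = float(np.hypot(_block_se(series_n.energies, n_blocks),
                        _block_se(series_0.energies, n_blocks)) / n)
    return HydrationEnergyResult(
        delta_u=delta,
        delta_u_se=se,
        n_water=n,
        u_n_mean=u_n,
        u_0_mean=u_0,
        reference=reference,
        will_rehydrate=delta < reference,
    )
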