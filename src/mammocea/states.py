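"""Health-state space of the screening cohort model.

The model follows a closed cohort of women through breast-cancer onset,
preclinical (undiagnosed) stage progression, diagnosis, treatment,
remission, recurrence, and death.  Preclinical and diagnosed disease are
stratified by stage 0–IV; recurrence is a single stage-invariant state.
"""
from __future__ import annotations

from enum import IntEnum

STAGES: tuple[str, ...] = ("0", "I", "II", "III", "IV")
N_STAGES = len(STAGES)


class HealthState(IntEnum):
    """Markov states.  DEAD_BC and DEAD_OTHER are absorbing."""

    HEALTHY = 0
    UNDX_0 = 1
    UNDX_I = 2
    UNDX_II = 3
    UNDX_III = 4
    UNDX_IV = 5
    DX_0 = 6
    DX_I = 7
    DX_II = 8
    DX_III = 9
    DX_IV = 10
    REM_0 = 11
    REM_I = 12
    REM_II = 13
    REM_III = 14
    REM_IV = 15
    RECURRENCE = 16
    DEAD_BC = 17
    DEAD_OTHER = 18


N_STATES = len(HealthState)

UNDX_SLICE = slice(HealthState.UNDX_0, HealthState.UNDX_IV + 1)
DX_SLICE = slice(HealthState.DX_0, HealthState.DX_IV + 1)
REM_SLICE = slice(HealthState.REM_0, HealthState.REM_IV + 1)

#: stages considered "early" / "late" in outcome tables
EARLY_STAGES: tuple[int, ...] = (0, 1, 2)
LATE_STAGES: tuple[int, ...] = (3, 4)


def undx(stage: int) -> HealthState:
    """Undiagnosed (preclinical) state for ``stage`` in 0..4."""
    return HealthState(HealthState.UNDX_0 + stage)


def dx(stage: int) -> HealthState:
    """Diagnosed (on-treatment) state for ``stage`` in 0..4."""
    return HealthState(HealthState.DX_0 + stage)


def remission(stage: int) -> HealthState:
    """Remission (surveillance) state for ``stage`` in 0..4."""
    return HealthState(HealthState.REM_0 + stage)


def is_alive(state: int) -> bool:
    return state < HealthState.DEAD_BC
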