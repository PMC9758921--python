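"""Value sets: mapping EQ-5D-5L health states to utilities (index values).

A value set encodes population preferences: each of the 3125 health states is
assigned a single utility, anchored at 1 for perfect health (1,1,1,1,1) and 0
for dead; states judged worse than dead carry negative utilities.  Value sets
are stored internally as explicit total mappings over all 3125 states, so
tabulated and additive-decrement sets are interchangeable: an additive set is
expanded once at construction time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from .states import (DIMENSIONS, N_STATES, PERFECT_HEALTH, HealthState,
                     InvalidStateError, enumerate_states)

VALUE_SET_COLUMNS = list(DIMENSIONS) + ["utility"]


class IncompleteValueSetError(ValueError):
    """A value set that does not cover all 3125 states."""


@dataclass(frozen=True)
class ValueSet:
    """A total mapping from health state to utility.

    Parameters
    ----------
    name:
        Identifier for the set (e.g. ``"belgium-synthetic"``).
    utilities:
        Mapping covering every one of the 3125 states.  The perfect-health
        state must map to exactly 1.
    """

    name: str
    utilities: Mapping[HealthState, float] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.utilities) != N_STATES:
            raise IncompleteValueSetError(
                f"value set {self.name!r} covers {len(self.utilities)} states, "
                f"expected {N_STATES}")
        anchor = self.utilities.get(PERFECT_HEALTH)
        if anchor != 1:
            raise ValueError(
                f"value set {self.name!r} must anchor (1,1,1,1,1) at 1, "
                f"got {anchor!r}")

    @property
    def floor(self) -> float:
        """Minimum utility over all states (the worst health state)."""
        return min(self.utilities.values())

    def __call__(self, state: HealthState) -> float:
        return index_value(state, self)

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_decrements(cls, name: str,
                        decrements: Mapping[str, list[float]]) -> "ValueSet":
        """Expand an additive main-effects set to all 3125 states.

        ``decrements[dim][k-1]`` is the utility loss for level *k* on
        dimension *dim*; level 1 must carry decrement 0.  The utility of a
        state is 1 minus the sum of its five decrements.
        """
        for dim in DIMENSIONS:
            decs = decrements[dim]
            if len(decs) != 5 or decs[0] != 0:
                raise ValueError(f"decrements for {dim} must be 5 values "
                                 "with level 1 at 0")
        table = {
            state: 1.0 - sum(decrements[dim][level - 1]
                             for dim, level in zip(DIMENSIONS, state))
            for state in enumerate_states()
        }
        return cls(name=name, utilities=table)

    @classmethod
    def from_frame(cls, name: str, frame: pd.DataFrame) -> "ValueSet":
        missing = [c for c in VALUE_SET_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"value set table missing columns {missing}")
        table: dict[HealthState, float] = {}
        for row in frame.itertuples(index=False):
            state = HealthState(*(int(getattr(row, d)) for d in DIMENSIONS))
            state.validate()
            if state in table:
                raise ValueError(f"duplicate state {state} in value set")
            table[state] = float(row.utility)
        return cls(name=name, utilities=table)

    def to_frame(self) -> pd.DataFrame:
        """Tabulate as a 3125-row DataFrame in lexicographic state order."""
        states = enumerate_states()
        records = [tuple(s) + (self.utilities[s],) for s in states]
        return pd.DataFrame.from_records(records, columns=VALUE_SET_COLUMNS)


def index_value(state: HealthState, vs: ValueSet) -> float:
    """Utility (index value) of a health state under a value set.

    A pure table lookup: additive sets were already expanded at load time.
    """
    state = HealthState(*state).validate()
    try:
        return vs.utilities[state]
    except KeyError:  # unreachable for a validated total set; belt-and-braces
        raise IncompleteValueSetError(
            f"state {state} missing from value set {vs.name!r}") from None


def read_value_set_csv(path: str | Path, name: str | None = None) -> ValueSet:
    """Read a tabulated value set (CSV, one row per state, strict).

    Expected columns: the five dimension names plus ``utility``; exactly
    3125 data rows, one per state.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if len(frame) != N_STATES:
        raise IncompleteValueSetError(
            f"{path}: expected {N_STATES} rows, found {len(frame)}")
    return ValueSet.from_frame(name or path.stem, frame)


def write_value_set_csv(vs: ValueSet, path: str | Path) -> None:
    vs.to_frame().to_csv(path, index=False)


def toy_value_set(step: float = 0.05, name: str = "toy-linear") -> ValueSet:
    """Self-contained additive set for tests: decrement step*(level-1)."""
    decs = {dim: [step * k for k in range(5)] for dim in DIMENSIONS}
    return ValueSet.from_decrements(name, decs)


def belgian_synthetic_value_set() -> ValueSet:
    """The packaged synthetic Belgian-like value set.

    This is a SYNTHETIC stand-in, not the published Belgian set: an additive
    set calibrated to reproduce the Belgian set's published example utilities
    ((1,1,1,1,1) -> 1, (1,1,1,1,3) -> 0.849, (1,1,3,3,3) -> 0.678,
    (5,5,5,5,5) -> -0.532) with the remaining decrements chosen as plausible
    magnitudes.  Suitable for pipeline exercise and testing only.
    """
    raw = resources.files("qale.data").joinpath(
        "be_value_set_synthetic.json").read_text()
    payload = json.loads(raw)
    return ValueSet.from_decrements(payload["name"], payload["decrements"])
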