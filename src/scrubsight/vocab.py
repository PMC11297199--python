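"""Label vocabularies for instruments, phases and actions.

The anticipation label space prepends a reserved ``idle`` class at index 0:
anticipation class ``k`` (k >= 1) corresponds to instrument ``k - 1`` of the
vocabulary.  The default vocabulary mirrors a laparoscopic cholecystectomy
annotation scheme with 12 instruments, 11 phases and 11 actions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

IDLE = 0
"""Index of the reserved idle class in the anticipation label space."""

DEFAULT_INSTRUMENTS = (
    "grasper",
    "irrigator",
    "biopsy_forceps",
    "coagulation_suction_tube",
    "clipper",
    "drain",
    "scissors",
    "retrieval_bag",
    "instrument_09",
    "instrument_10",
    "instrument_11",
    "instrument_12",
)

DEFAULT_PHASES = tuple(f"phase_{i + 1:02d}" for i in range(11))
DEFAULT_ACTIONS = tuple(f"action_{i + 1:02d}" for i in range(11))


class VocabularyError(ValueError):
    """Raised when a vocabulary violates its invariants."""


@dataclass(frozen=True)
class LabelVocabulary:
    """Ordered instrument / phase / action name lists.

    Instrument names must not contain ``"idle"``: idle is not an instrument
    but the reserved no-handover output of the anticipation heads.
    """

    instruments: tuple[str, ...] = DEFAULT_INSTRUMENTS
    phases: tuple[str, ...] = DEFAULT_PHASES
    actions: tuple[str, ...] = DEFAULT_ACTIONS
    idle_name: str = field(default="idle")

    def __post_init__(self):
        object.__setattr__(self, "instruments", tuple(self.instruments))
        object.__setattr__(self, "phases", tuple(self.phases))
        object.__setattr__(self, "actions", tuple(self.actions))
        for kind, names in (
            ("instruments", self.instruments),
            ("phases", self.phases),
            ("actions", self.actions),
        ):
            if len(set(names)) != len(names):
                raise VocabularyError(f"duplicate names in {kind}: {names}")
        if self.idle_name in self.instruments:
            raise VocabularyError("idle is reserved and may not be an instrument name")

    # -- sizes -----------------------------------------------------------
    @property
    def n_instruments(self) -> int:
        return len(self.instruments)

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    @property
    def n_actions(self) -> int:
        return len(self.actions)

    @property
    def n_anticipation_classes(self) -> int:
        """Instrument classes plus the idle class at index 0."""
        return self.n_instruments + 1

    # -- lookups ---------------------------------------------------------
    def instrument_index(self, name: str) -> int:
        return self.instruments.index(name)

    def phase_index(self, name: str) -> int:
        return self.phases.index(name)

    def action_index(self, name: str) -> int:
        return self.actions.index(name)

    def anticipation_index(self, instrument: str) -> int:
        """Index of an instrument in the idle-prefixed anticipation space."""
        return self.instrument_index(instrument) + 1

    def anticipation_names(self) -> tuple[str, ...]:
        return (self.idle_name,) + self.instruments

    def hash(self) -> str:
        """Stable digest used to guard checkpoint/vocabulary mismatches."""
        payload = json.dumps(
            [list(self.instruments), list(self.phases), list(self.actions)],
            ensure_ascii=False,
        )
        return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:16]
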