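"""The six ordered triage actions.

Care urgency is a total order: ``self_care < pharmacy < gp_nonurgent <
gp_urgent < ae < ambulance``.  The integer value of each member is its
urgency rank (1 = least urgent), so actions compare and sort directly.
"""

from __future__ import annotations

import enum


class TriageAction(enum.IntEnum):
    """One of six mutually exclusive triage recommendations, ordered by urgency."""

    self_care = 1
    pharmacy = 2
    gp_nonurgent = 3
    gp_urgent = 4
    ae = 5
    ambulance = 6

    @property
    def urgency(self) -> int:
        return int(self)

    @classmethod
    def from_name(cls, name: str) -> "TriageAction":
        try:
            return cls[name]
        except KeyError:
            valid = ", ".join(a.name for a in cls)
            raise ValueError(f"unknown triage action {name!r}; expected one of: {valid}") from None


#: All actions in increasing order of urgency.
ACTIONS: tuple[TriageAction, ...] = tuple(TriageAction)
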