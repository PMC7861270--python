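"""Displayed differential diagnosis.

Posterior marginals are converted into the user-facing condition list by a
probability-and-severity display policy: disease *d* is shown iff

    P(d | evidence) >= tau_mode(severity_band(d))

with per-band probability floors (lower floors for more severe bands, so
dangerous conditions surface at lower probability).  Switching between
operating modes trades recall against precision: if one mode's thresholds
are coordinatewise >= another's, its differential is always a subset.
"""

from __future__ import annotations

from dataclasses import dataclass

from .inference import PosteriorResult
from .knowledge_base import KnowledgeBase

__all__ = ["Differential", "build_differential"]


@dataclass(frozen=True)
class Differential:
    """Ordered (disease_id, posterior) pairs that passed the display policy."""

    entries: tuple[tuple[str, float], ...]
    mode_id: str

    @property
    def disease_ids(self) -> list[str]:
        return [d for d, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, disease_id: str) -> bool:
        return any(d == disease_id for d, _ in self.entries)


def build_differential(
    posteriors: PosteriorResult,
    kb: KnowledgeBase,
    mode_id: str,
    max_length: int | None = None,
) -> Differential:
    """Apply the display thresholds of ``mode_id`` and rank the survivors.

    Inclusion is at-or-above threshold (boundary included); entries are
    sorted by posterior descending with ties broken by disease id.  An empty
    differential is legal output.  ``max_length`` optionally caps the list
    (off by default).  Unknown modes raise KeyError listing available modes.
    """
    taus = kb.display_policy.thresholds(mode_id)
    kept = []
    for d, p in posteriors.marginals.items():
        band = kb.severity_band(d)
        if p >= taus[band - 1]:
            kept.append((d, p))
    kept.sort(key=lambda e: (-e[1], e[0]))
    if max_length is not None:
        kept = kept[:max_length]
    return Differential(entries=tuple(kept), mode_id=mode_id)
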