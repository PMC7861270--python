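"""Exception hierarchy."""

from __future__ import annotations


class BayesTriageError(Exception):
    """Base class for all package errors."""


class SchemaError(BayesTriageError):
    """A knowledge-base or vignette file violates the documented schema.

    ``path`` names the offending field (dotted, e.g. ``families.d1.links[0].activation``).
    """

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


class InvariantError(BayesTriageError):
    """A structural invariant of a validated object is violated."""


class InferenceError(BayesTriageError):
    """Inference could not be carried out (cap exceeded, impossible evidence...)."""


class EvidenceError(BayesTriageError):
    """Evidence refers to unknown concepts or illegal layers/states."""
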