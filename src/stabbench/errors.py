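"""Exception hierarchy.

``StabbenchError`` is the common base; the CLI maps subclasses to exit
codes (usage 1, data 2, stage failure 3).
"""


class StabbenchError(Exception):
    """Base class for all package errors."""


class SchemaError(StabbenchError):
    """Input table does not match the expected schema (missing column, empty file)."""


class DataConsistencyError(StabbenchError):
    """Records contradict each other (e.g. one protein flagged both natural and de novo)."""


class ConfigError(StabbenchError):
    """Invalid or infeasible configuration."""


class InvalidSequenceError(StabbenchError):
    """One or more sequences contain residues outside the 20-letter alphabet.

    ``errors`` holds ``(index, sequence, reason)`` triples so callers can
    report failures per sequence instead of receiving silent NaNs.
    """

    def __init__(self, errors):
        self.errors = list(errors)
        preview = "; ".join(f"[{i}] {reason}" for i, _, reason in self.errors[:5])
        super().__init__(f"{len(self.errors)} invalid sequence(s): {preview}")


class KeyAlignmentError(StabbenchError):
    """Prediction and label tables do not cover the same record keys."""

    def __init__(self, missing_keys, message="prediction/label key mismatch"):
        self.missing_keys = list(missing_keys)
        shown = ", ".join(map(str, self.missing_keys[:10]))
        super().__init__(f"{message}: {len(self.missing_keys)} key(s) unmatched (first: {shown})")


class StageError(StabbenchError):
    """A pipeline stage failed or its prerequisites are missing."""
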