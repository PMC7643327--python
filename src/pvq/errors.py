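"""Exception hierarchy.

``ValidationError`` marks bad inputs or specs (CLI exit code 2);
``ComputationError`` marks failures during analysis of otherwise valid
inputs, e.g. a kymograph with no detectable lumen (CLI exit code 3).
"""


class PvqError(Exception):
    """Base class for all pvq errors."""


class ValidationError(PvqError, ValueError):
    """An input, spec or configuration violates a stated invariant."""


class ComputationError(PvqError, RuntimeError):
    """An analysis step could not produce a result from valid inputs."""
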