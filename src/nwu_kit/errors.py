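"""Exception hierarchy.

``PipelineError`` marks scans that are valid input but yield no measurable
result (no visible infarct, no identifiable core, region vanished after
exclusions); the CLI maps it to exit code 1, distinct from usage errors (2).
"""


class NWUKitError(Exception):
    """Base class for all package errors."""


class PipelineError(NWUKitError):
    """Valid input, but no measurable result can be produced."""


class InputError(NWUKitError):
    """Malformed or inconsistent input data (bad header, grid mismatch)."""
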