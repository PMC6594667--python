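"""Exception hierarchy shared across the toolkit.

Each CLI subcommand maps these onto distinct exit codes: configuration
problems, validation failures in the data themselves, and missing or
malformed input files are different failure modes for a DQA team.
"""


class DQAError(Exception):
    """Base class for all toolkit errors."""


class ConfigError(DQAError):
    """A configuration document is malformed or self-inconsistent."""


class StructuralError(ConfigError):
    """The reporting-system map violates a structural invariant
    (duplicate ids, orphan sites, parent at a non-higher rank, cycles)."""


class RoutingError(DQAError):
    """No routing path exists from a site to the requested terminal level."""


class RuleError(ConfigError):
    """A register validation rule references undeclared codes or cannot
    be compiled."""


class ValidationError(DQAError):
    """Input data violate a validation contract (e.g. a score of 1 or 2
    without an explanatory note)."""


class TracingError(DQAError):
    """An indicator cannot be traced (e.g. its field is absent from the
    reports at some level)."""


class SamplingError(DQAError):
    """A sampling stage cannot be executed (pool smaller than the number
    requested, or no backup left for a replacement)."""


class DataError(DQAError):
    """An input file is missing or unreadable."""
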