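"""Exception hierarchy.

Every error raised by the package derives from :class:`OroflowError` so
callers (and the CLI) can distinguish pipeline failures from programming
errors.
"""


class OroflowError(Exception):
    """Base class for all package errors."""


class FormatError(OroflowError):
    """A file does not conform to the expected format (EDF header, event table)."""


class ChannelNotFoundError(FormatError):
    """A requested signal role is not present in the recording."""

    def __init__(self, role: str, wanted: str, available) -> None:
        self.role = role
        self.wanted = wanted
        self.available = list(available)
        super().__init__(
            f"channel {wanted!r} for role {role!r} not found; "
            f"available channels: {self.available}"
        )


class ValidationError(OroflowError):
    """Inputs violate an operation's preconditions."""


class DegenerateSignalError(ValidationError):
    """A signal has zero variance where variation is required."""


class EmptyOverlapError(OroflowError):
    """Two recordings share no common time interval after applying the lag."""


class SchedulingError(OroflowError):
    """Requested episode density cannot be realized with the required gaps."""


class StratificationError(ValidationError):
    """A class has too few members to stratify a split."""


class ConfigError(OroflowError):
    """A run configuration failed schema validation."""


class DependencyError(OroflowError):
    """A pipeline stage requires an artifact that an earlier stage has not produced."""
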