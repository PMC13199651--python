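"""Exception hierarchy shared by all pipeline stages."""


class ScreenError(Exception):
    """Base class for all trscreen errors."""


class ConfigError(ScreenError):
    """Invalid configuration value; the message names the offending field."""


class FormatError(ScreenError):
    """Malformed input file (parse failures, duplicate ids, bad labels)."""


class MergeError(ScreenError):
    """Cohort merge impossible (empty gene intersection, sample collisions)."""


class DomainError(ScreenError):
    """Value outside the mathematical domain of an operation."""


class ContractError(ScreenError):
    """Operation precondition violated (degenerate classes, mismatched ids)."""


class BundleError(ScreenError):
    """Model bundle missing, corrupt, or version-incompatible."""
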