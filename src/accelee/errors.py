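"""Exception hierarchy shared across the pipeline stages."""


class AccelEEError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(AccelEEError, ValueError):
    """A file or config does not have the expected layout (missing column, bad header...)."""


class DataError(AccelEEError, ValueError):
    """Data values violate a contract (non-monotone time, wrong length, too short...)."""


class DomainError(AccelEEError, ValueError):
    """An argument is outside an equation's domain (negative counts, bad gender code...)."""


class DegenerateInputError(DataError):
    """A statistic is undefined for this input (zero variance, constant column...)."""


class ConfigError(AccelEEError, ValueError):
    """A pipeline configuration failed validation; ``problems`` lists every violation."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {p}" for p in self.problems))
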