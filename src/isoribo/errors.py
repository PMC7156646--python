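class IsoriboError(Exception):
    """Base class for package errors."""


class DataError(IsoriboError):
    """Inconsistent or unusable input data (CLI exit code 3)."""
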