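"""Exception hierarchy."""


class PhylositesError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PhylositesError):
    """Invalid user configuration (unknown tree name, bad sizes, ...)."""


class FastqParseError(PhylositesError):
    """Malformed FASTQ record; message names the offending record index."""


class AdapterError(PhylositesError):
    """An external assembler/mapper failed or produced unparsable output."""

    def __init__(self, message: str, log: str = ""):
        super().__init__(message)
        self.log = log


class IntegrityError(PhylositesError):
    """Evaluation inputs do not belong to the same run."""
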