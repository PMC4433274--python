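"""Exception hierarchy shared by all pipeline stages."""


class MirpipeError(Exception):
    """Base class for all pipeline errors."""


class FormatError(MirpipeError):
    """A file could not be parsed (malformed FASTA/TSV/YAML)."""


class ValidationError(MirpipeError):
    """Parsed data violates a domain invariant."""


class ConfigError(MirpipeError):
    """A configuration value is out of its allowed range."""


class GenerationError(MirpipeError):
    """The synthetic-data generator could not satisfy its constraints."""
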