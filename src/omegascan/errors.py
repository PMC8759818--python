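"""Exception hierarchy shared across the pipeline."""


class OmegascanError(Exception):
    """Base class for all package errors."""


class FormatError(OmegascanError):
    """An input file violates its format contract (FASTA/newick/TSV)."""


class MalformedGeneError(FormatError):
    """A per-gene alignment file is structurally invalid (e.g. length not a
    multiple of three). Carries the offending file/gene name in the message."""


class ConfigurationError(OmegascanError):
    """A configuration value or required input is missing or inconsistent."""


class ParameterError(OmegascanError):
    """A numeric parameter is outside its admissible range."""
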