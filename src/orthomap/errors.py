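"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: configuration problems exit 2,
input parsing/integrity problems exit 3.
"""


class OrthomapError(Exception):
    """Base class for all orthomap errors."""


class ConfigurationError(OrthomapError):
    """Invalid user-supplied configuration (bad regex, bad thresholds, ...)."""


class ParseError(OrthomapError):
    """A file could not be parsed; message names the file and line."""


class IntegrityError(OrthomapError):
    """Inputs violate a structural invariant (duplicate ids, unknown genes, ...)."""
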