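"""Exceptions shared across the pipeline.

``ConfigurationError`` maps to CLI exit code 2 (bad parameters or design),
``DataError`` to exit code 3 (malformed or insufficient input data).
"""


class ConfigurationError(ValueError):
    """A parameter, design field or config file is invalid."""


class DataError(ValueError):
    """An input file or matrix cannot be used as provided."""
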