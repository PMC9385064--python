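"""Exception hierarchy shared across the pipeline.

``InputError`` maps to exit code 1 on the command line (bad or inconsistent
user input), anything else to exit code 2 (internal failure).
"""


class YchronoError(Exception):
    """Base class for all package errors."""


class InputError(YchronoError):
    """Unreadable, malformed, or internally inconsistent input data."""


class ConfigError(YchronoError):
    """A configuration value outside its documented range."""
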