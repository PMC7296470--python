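"""Exception hierarchy.

Exit-code discipline in the CLI maps :class:`FormatError` (bad input files)
to exit status 2 and every other :class:`ParwelchError` to exit status 1.
"""


class ParwelchError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(ParwelchError, ValueError):
    """Invalid estimator or scheduler configuration."""


class FormatError(ParwelchError):
    """Malformed middle file or PSD table."""


class IntegrityError(ParwelchError):
    """Lost or duplicated worker message detected during the reduce stage."""
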