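"""Exception hierarchy.

All regensig errors derive from :class:`RegensigError` and from
:class:`ValueError`, so callers may catch either.
"""


class RegensigError(ValueError):
    """Base class for all regensig errors."""


class ConfigError(RegensigError):
    """A configuration value violates its contract; the message names the field."""


class ParseError(RegensigError):
    """An input file could not be parsed; the message carries row/column context."""


class InputError(RegensigError):
    """Validated inputs are mutually inconsistent (e.g. disjoint gene universes)."""
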