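"""Exception hierarchy for isletsort."""


class IsletSortError(Exception):
    """Base class for all isletsort errors."""


class ConfigurationError(IsletSortError, ValueError):
    """A simulation or gate configuration is invalid or incomplete."""


class FormatError(IsletSortError, ValueError):
    """An input file violates the expected on-disk format."""
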