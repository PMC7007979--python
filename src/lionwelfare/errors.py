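"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input table or record violates the documented schema."""


class UndefinedIndexError(ValueError):
    """A welfare index is undefined for the given input (e.g. SPI with no scans)."""
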