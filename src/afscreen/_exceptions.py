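"""Exception types shared across the package."""


class FormatError(ValueError):
    """A file or table does not conform to the expected on-disk format."""


class LabelError(ValueError):
    """A raw rhythm label cannot be mapped under the requested collapsing scheme."""


class InsufficientPeaksError(ValueError):
    """Fewer R-peaks than required for the requested computation."""
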