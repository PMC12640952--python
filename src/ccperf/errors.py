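"""Exception types shared across the package."""


class InputError(ValueError):
    """Invalid user-supplied data (shapes, ranges, non-finite values)."""


class DegenerateInputError(InputError):
    """Structurally valid input on which the requested computation is undefined
    (e.g. an identically-zero arterial input function, a single-class ROC)."""


class GeometryError(InputError):
    """Volumes, masks or landmarks that are geometrically inconsistent."""
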