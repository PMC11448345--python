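"""Exception types shared across the package."""


class FormatError(ValueError):
    """A file's on-disk structure is inconsistent or unparsable."""


class AxisError(ValueError):
    """A requested wavenumber is too far from any entry of the band axis."""


class DegenerateGeometryError(ValueError):
    """Landmark geometry does not determine an affine transform."""


class UndefinedOrientationError(ValueError):
    """Structure tensor is zero; orientation is undefined."""


class ProvenanceError(RuntimeError):
    """Training and validation data overlap; evaluation would be circular."""
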