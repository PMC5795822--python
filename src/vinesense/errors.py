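"""Exception taxonomy for the pipeline."""


class VinesenseError(Exception):
    """Base class for all package errors."""


class FormatError(VinesenseError):
    """A file does not conform to its declared format."""


class ValidationError(VinesenseError):
    """Input data violates a domain invariant."""


class CalibrationError(VinesenseError):
    """White-reference or radiance-to-reflectance failure."""


class BandResolutionError(VinesenseError):
    """A requested wavelength cannot be matched within tolerance."""


class CapabilityError(VinesenseError):
    """An index was requested from a sensor that lacks its bands."""


class IntegrityError(VinesenseError):
    """Cross-source join inconsistency (e.g. duplicate plant ids)."""
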