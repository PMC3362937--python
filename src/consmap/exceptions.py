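"""Exception hierarchy for consmap."""


class ConsmapError(Exception):
    """Base class for all consmap errors."""


class ValidationError(ConsmapError, ValueError):
    """Malformed input: bad codes, duplicated markers, invalid parameters."""


class IdentifierError(ConsmapError, KeyError):
    """A marker name was not found where it was required."""


class ConstraintViolationError(ConsmapError):
    """An order does not embed the required shared (anchor) suborder."""


class FeasibilityError(ConsmapError):
    """An exact solver was asked for an instance above its size caps."""
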