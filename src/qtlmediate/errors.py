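"""Exception hierarchy for cross construction, mapping, and pipeline I/O."""


class QtlMediateError(Exception):
    """Base class for all package errors."""


class InvalidDesignError(QtlMediateError, ValueError):
    """A simulation design violates its constraints (negative sd, bad rates, ...)."""


class InvalidArgumentError(QtlMediateError, ValueError):
    """A numeric argument is outside its admissible range."""


class MapError(QtlMediateError, ValueError):
    """A marker map is malformed (non-monotone positions, empty chromosome, ...)."""


class DataError(QtlMediateError, ValueError):
    """Observed data violate the format contract (unknown genotype code, ...)."""


class AlignmentError(QtlMediateError, ValueError):
    """Two containers that must share a mouse index do not overlap."""


class DegenerateTraitError(QtlMediateError, ValueError):
    """A trait is constant or entirely missing and cannot be transformed."""


class ConfigError(QtlMediateError, ValueError):
    """A pipeline configuration is inconsistent."""
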