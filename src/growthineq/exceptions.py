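"""Exception hierarchy shared across the package."""


class GrowthIneqError(Exception):
    """Base class for package-specific errors."""


class SchemaError(GrowthIneqError):
    """Input file does not conform to the expected column schema."""


class ReferenceRangeError(GrowthIneqError):
    """Index value outside the growth-reference grid (no extrapolation)."""


class DesignCoverageError(GrowthIneqError):
    """A record matches no (or more than one) sampling-design stratum."""


class ConvergenceError(GrowthIneqError):
    """A maximum-likelihood fit failed to converge (e.g. complete separation)."""


class FixtureError(GrowthIneqError):
    """Base class for bundled-fixture problems."""


class UnknownFixtureError(FixtureError):
    """Requested fixture name is not registered."""


class ChecksumError(FixtureError):
    """Fixture file content does not match its manifest checksum."""
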