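"""Exception hierarchy for oxbilayer."""


class OxbilayerError(Exception):
    """Base class for all package errors."""


class UnknownSpeciesError(OxbilayerError, ValueError):
    """Requested lipid species label is not recognized."""


class CompositionError(OxbilayerError, ValueError):
    """Invalid or inconsistent system composition."""


class PackingError(OxbilayerError, RuntimeError):
    """Initial-configuration packing could not satisfy its constraints."""


class TrajectoryError(OxbilayerError, ValueError):
    """Malformed trajectory container or empty frame selection."""


class AnalysisError(OxbilayerError, ValueError):
    """An analysis precondition failed (e.g. unresolvable density peaks)."""


class FileFormatError(OxbilayerError, ValueError):
    """A coordinate/trajectory file could not be parsed."""


class ConfigError(OxbilayerError, ValueError):
    """Invalid or incomplete run configuration."""
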