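"""Exception types shared across the package."""


class PolypackError(Exception):
    """Base class for all package errors."""


class InvalidCellError(PolypackError):
    """Simulation cell is geometrically invalid (non-positive volume, ...)."""


class DegenerateGeometryError(PolypackError):
    """Fillers/confinement leave no accessible volume (or a negative one)."""


class TopologyError(PolypackError):
    """Chain topology is inconsistent (not a disjoint union of simple paths)."""


class ConfigError(PolypackError):
    """Run configuration is invalid or contains unknown keys."""


class ParseError(PolypackError):
    """A structured input file could not be parsed."""


class GenerationError(PolypackError):
    """The system generator failed (e.g. placement retries exhausted)."""
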