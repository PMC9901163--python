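"""Exception hierarchy for ffinet."""


class FFiNetError(Exception):
    """Base class for all ffinet errors."""


class ConfigurationError(FFiNetError):
    """Invalid configuration (missing column, bad option value, ...)."""


class ParseError(FFiNetError):
    """Unparseable chemical input (SMILES, structure file)."""


class EmptyStructureError(FFiNetError):
    """A structure file contained zero atoms."""


class EmbeddingError(FFiNetError):
    """Conformer embedding failed even after the random-coordinate fallback."""


class DegenerateGeometryError(FFiNetError):
    """Coincident or collinear atoms make a geometric quantity undefined."""


class AlignmentError(FFiNetError):
    """Row misalignment between a path index and its basis matrix."""
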