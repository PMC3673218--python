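"""Exception hierarchy shared across modules."""


class HmmdriverError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HmmdriverError):
    """A file does not conform to its declared format."""


class ParseError(HmmdriverError):
    """A token or record could not be parsed."""


class RegistryError(HmmdriverError, KeyError):
    """A model identifier could not be resolved."""


class DimensionError(HmmdriverError, ValueError):
    """Mismatched vector/list lengths or alphabets."""


class ValidationError(HmmdriverError, ValueError):
    """An input violates a documented invariant."""


class SynonymousInputError(ValidationError):
    """Wild-type and mutant residues are identical."""


class StratificationError(HmmdriverError, ValueError):
    """A cross-validation fold would contain a single class."""


class ScenarioError(HmmdriverError, ValueError):
    """Synthetic scenario parameters are infeasible."""
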