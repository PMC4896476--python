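"""Exception hierarchy for the skinsense package."""


class SkinSenseError(Exception):
    """Base class for all package-specific errors."""


class ParseError(SkinSenseError):
    """A structure string could not be parsed into a valid molecule."""


class LabelError(SkinSenseError):
    """A potency label outside the allowed vocabulary was supplied."""


class FormatError(SkinSenseError):
    """An input file could not be read in the declared format."""


class DuplicateError(SkinSenseError):
    """Two records share a CAS registry number but differ in structure."""


class DegenerateInputError(SkinSenseError):
    """Input lacks the class structure an operation requires."""


class UnknownClassifierError(SkinSenseError):
    """Variant code names a classifier outside the supported vocabulary."""


class LengthMismatchError(SkinSenseError):
    """Paired sequences (fingerprints, prediction/truth vectors) differ in length."""


class EmptyReferenceError(SkinSenseError):
    """Similarity scoring requested against an empty reference set."""


class InvalidSmartsError(SkinSenseError):
    """An alert entry's SMARTS pattern does not compile."""


class DuplicateIdError(SkinSenseError):
    """Two alert entries share an id."""


class EmptyLibraryError(SkinSenseError):
    """Substructure scoring requested with an empty alert library."""


class IncompleteComponentsError(SkinSenseError):
    """Consensus scoring received an incomplete set of component votes."""


class UnknownSchemeError(SkinSenseError):
    """A weight scheme name is not among the built-ins and no table was given."""


class DegenerateTallyError(SkinSenseError):
    """A confusion tally has a class with zero determinate predictions."""


class GenerationError(SkinSenseError):
    """Synthetic molecule generation failed after bounded retries."""
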