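"""Exception types shared across the package."""


class EqscoreError(Exception):
    """Base class for all package errors."""


class FormatError(EqscoreError):
    """A structure file could not be parsed."""


class EmptyInputError(EqscoreError):
    """An input contained no usable atoms."""


class EmptyPocketError(EqscoreError):
    """No protein atom fell within the pocket radius of the ligand."""


class VocabularyError(EqscoreError):
    """An element symbol is not covered by the type vocabulary."""


class DegenerateGraphError(EqscoreError):
    """The atom set is too small to build a graph."""


class DegenerateLabelError(EqscoreError):
    """A training set does not contain both classes."""


class LabelRangeError(EqscoreError):
    """A label falls outside the range required by the task."""


class GenerationError(EqscoreError):
    """Synthetic-data generation could not satisfy its geometric constraints."""


class DiagnosticError(EqscoreError):
    """An attribution diagnostic cannot be computed on this input."""
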