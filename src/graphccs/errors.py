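"""Exception hierarchy for graphccs.

Every error raised by the public API derives from :class:`GraphCCSError`,
so callers can catch one type at pipeline boundaries.
"""


class GraphCCSError(Exception):
    """Base class for all graphccs errors."""


class InvalidSmilesError(GraphCCSError):
    """The SMILES string could not be parsed into a molecule."""


class UnsupportedElementError(GraphCCSError):
    """The molecule contains an element outside the configured vocabulary."""


class EmbeddingFailedError(GraphCCSError):
    """Distance-geometry embedding produced no 3D conformer."""


class MinimizationFailedError(GraphCCSError):
    """The force field could not be set up for conformer minimization."""


class FormatError(GraphCCSError):
    """A tabular input file is malformed; message carries the line number."""


class UnknownAdductError(GraphCCSError):
    """Adduct label outside the supported set ([M+H]+, [M+Na]+, [M-H]-)."""


class InconsistentInputError(GraphCCSError):
    """Molecule and conformer disagree (e.g. atom counts differ)."""


class UnknownAttributeError(GraphCCSError):
    """Attribute block name not one of the featurizer's blocks."""


class NotARotationError(GraphCCSError):
    """Matrix is not a proper rotation (orthonormal, det +1)."""


class ShapeError(GraphCCSError):
    """Array shapes inconsistent with the configured layer widths."""


class EmptyGraphError(GraphCCSError):
    """Pooling requested on a graph with no nodes."""


class EmptyEvaluationError(GraphCCSError):
    """Evaluation requested on an empty record set."""


class DivergenceError(GraphCCSError):
    """Training loss became non-finite."""


class EmptyLibraryError(GraphCCSError):
    """Candidate filtering against an empty library."""


class MissingTruthError(GraphCCSError):
    """Recall scoring requested but a query lacks its true identifier."""


class GenerationExhaustedError(GraphCCSError):
    """Random molecule generation exceeded its retry budget."""


class ChecksumError(GraphCCSError):
    """Checkpoint file missing or its checksum does not match the manifest."""


class VersionError(GraphCCSError):
    """Checkpoint schema version incompatible with this package version."""
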