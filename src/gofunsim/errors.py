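"""Exception hierarchy shared by all modules.

Every error carries an ``exit_code`` used by the CLI: 2 input-limit,
3 parse error, 4 lookup error, 5 parameter error.
"""

from __future__ import annotations


class GoFunSimError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputLimitError(GoFunSimError):
    """A query exceeds its default size limit (overridable with --force)."""

    exit_code = 2


class ParseError(GoFunSimError):
    exit_code = 3


class OboParseError(ParseError):
    pass


class GafParseError(ParseError):
    pass


class CycleError(OboParseError):
    """The relation graph contains a cycle; the message names one edge."""


class UnknownIdentifierError(GoFunSimError):
    """Identifier (GO id, protein accession or gene symbol) not found."""

    exit_code = 4


class AmbiguousIdentifierError(UnknownIdentifierError):
    """A gene symbol maps to more than one protein accession."""


class ParameterError(GoFunSimError):
    exit_code = 5


class NamespaceMismatchError(ParameterError):
    """Two terms from different GO namespaces were compared."""


class TermUnusedError(ParameterError):
    """An annotation-based model was queried with a term absent from the corpus."""


class UndefinedSimilarityError(ParameterError):
    """A similarity is undefined (empty term sets or zero total IC)."""


class MissingAnnotationError(ParameterError):
    """A protein has no annotation in the requested namespace (CLI prints NA)."""
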