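"""Exception hierarchy shared across the mapping pipeline."""


class MaveAnchorError(Exception):
    """Base class for all package errors."""


class ParseError(MaveAnchorError):
    """A variant string could not be parsed; the message names the token."""


class UnsupportedVariantError(MaveAnchorError):
    """A syntactically valid variant class we do not model (e.g. copy number).

    Consumed downstream by representing the row as a text variation.
    """


class StoreError(MaveAnchorError):
    """Base class for reference-store lookup failures."""


class NotFoundError(StoreError):
    """Unknown accession, symbol, or identifier."""


class NoLinkageError(StoreError):
    """A UniProt accession with no linked protein/gene record."""


class RangeError(StoreError):
    """Coordinates outside the addressed sequence."""


class AlignmentError(MaveAnchorError):
    """PSL format problems or hit-selection failures."""


class NoCompatibleHitError(AlignmentError):
    """Gene context names a chromosome with no alignment hit (whole-set failure)."""


class TranscriptSelectionError(MaveAnchorError):
    """Empty transcript intersection, missing seed, or irreconcilable discordance."""


class LiftError(MaveAnchorError):
    """A position cannot be lifted through the alignment blocks."""


class ScoresetMappingError(MaveAnchorError):
    """A whole score set failed to map (no hit, broken UniProt linkage, ...)."""
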