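"""Exception hierarchy for the pepzone pipeline.

Every stage raises a subclass of :class:`PepzoneError`, so callers can
catch pipeline failures without masking programming errors.
"""


class PepzoneError(Exception):
    """Base class for all pepzone-specific errors."""


# --- sequence / tiling ------------------------------------------------------

class OverlapConflict(PepzoneError):
    """Two overlapping peptides disagree at a shared residue."""


class CoverageGap(PepzoneError):
    """The peptide set leaves a residue in [1, max(end)] uncovered."""


class SequenceTooShort(PepzoneError):
    """Protein shorter than the tiling window."""


class UnmappedSpan(PepzoneError):
    """A peptide extends beyond the last annotated domain end."""


class EmptyMotif(PepzoneError):
    """Zero-length motif passed to the motif search."""


class InconsistentLabels(PepzoneError):
    """No domain boundary is consistent with every peptide label."""


# --- array quantification ---------------------------------------------------

class CircleOutOfBounds(PepzoneError):
    """A layout circle extends outside the image."""


class EmptyCircle(PepzoneError):
    """A circle so small that no pixel center falls inside it."""


class InsufficientNegatives(PepzoneError):
    """Fewer than the required number of negative spots."""


class InsufficientPeptides(PepzoneError):
    """Fewer peptide spots than the requested random sample size."""


# --- antigenicity -----------------------------------------------------------

class EmptyMatrix(PepzoneError):
    """Reactivity matrix with no sera."""


class EmptyZone(PepzoneError):
    """Zone with no resolved residues."""


# --- serology ---------------------------------------------------------------

class UncalibratedAssay(PepzoneError):
    """OD-to-units conversion requested without a fitted calibration."""


class TooFewReference(PepzoneError):
    """Healthy-reference vector too small for a percentile cutoff."""


class MissingAssay(PepzoneError):
    """Panel lacks an assay column required for classification."""


class ConstantInput(PepzoneError):
    """Correlation requested on a constant vector."""


class NoFeasibleSplit(PepzoneError):
    """No two-regime boundary satisfies the minimum group-size constraint."""


class DegenerateTable(PepzoneError):
    """Contingency table or sample unsuitable for the requested test."""


# --- structure --------------------------------------------------------------

class NoSuchChain(PepzoneError):
    """Requested chain id absent from the structure."""


class NoAtoms(PepzoneError):
    """No alpha-carbon atoms found."""


class DegenerateGeometry(PepzoneError):
    """Coordinates collinear or otherwise unsuitable for a plane fit."""


class AnchorsOnPlane(PepzoneError):
    """Anchor residues lie too close to the fitted plane to orient it."""


class InsertionCodesUnsupported(PepzoneError):
    """Structure uses residue insertion codes, which are not supported."""


# --- synthesis / pipeline ---------------------------------------------------

class BadSpec(PepzoneError):
    """Invalid synthetic-data specification."""


class LayoutOverflow(PepzoneError):
    """Spot layout does not fit the requested image."""
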