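"""Exception hierarchy shared across the package."""


class SplicePRMError(Exception):
    """Base class for all package-specific errors."""


class GraphStructureError(SplicePRMError, ValueError):
    """Invalid splice-graph structure (duplicate ids, unknown exons, ...)."""


class SequenceFormatError(SplicePRMError, ValueError):
    """A nucleotide or amino-acid sequence contains illegal characters."""


class TranslationError(SplicePRMError, ValueError):
    """No open reading frame can be read from the requested offset."""


class UndefinedRatioError(SplicePRMError, ZeroDivisionError):
    """A ratio is requested but no informative counts/areas exist."""


class UnknownSegmentError(SplicePRMError, LookupError):
    """A constraint or query names a segment/exon absent from the graph."""


class UnknownModificationError(SplicePRMError, LookupError):
    """A peptide modification name is not in the modification table."""


class AssayDesignError(SplicePRMError, ValueError):
    """Assay construction failed (e.g. no fragments to select from)."""


class MissingStandardError(SplicePRMError, ValueError):
    """The heavy reference channel is absent or zero for a peptide."""


class CalibrationError(SplicePRMError, ValueError):
    """A recombinant calibration run required for inclusion % is missing."""


class ConfigurationError(SplicePRMError, ValueError):
    """Run configuration is inconsistent (missing TIC, no control group, ...)."""


class SchemaError(SplicePRMError, ValueError):
    """An input table or config file violates the expected schema."""
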