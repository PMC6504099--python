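"""Exception types raised across the pipeline."""


class IntsymmError(Exception):
    """Base class for all package errors."""


class FormatError(IntsymmError):
    """Structure file could not be read or parsed."""


class EmptySelectionError(IntsymmError):
    """Chain/residue selector matched no residues."""


class TooShortError(IntsymmError):
    """Trace has too few residues for the requested operation."""


class DegenerateGeometryError(IntsymmError):
    """Point set is degenerate (e.g. collinear) for superposition."""


class RefinementError(IntsymmError):
    """Self-alignment could not be refined into a repeat alignment."""
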