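"""Exception hierarchy for simms2."""


class SimmsError(Exception):
    """Base class for all simms2 data/model errors."""


class GrammarError(SimmsError):
    """Invalid saccharide sequence string or residue combination."""


class FragmentError(SimmsError):
    """Invalid fragment specification."""


class FitError(SimmsError):
    """Peak or line fitting failed (flat trace, non-convergence, bad data)."""


class LibraryError(SimmsError):
    """Malformed, duplicated or inconsistent reference-library data."""


class ConstraintError(SimmsError):
    """Inconsistent composition or disaccharide constraint."""


class CandidateCapError(SimmsError):
    """Candidate enumeration exceeded the configured cap."""


class EmptyLibraryError(SimmsError):
    """Sequencing requested against a library with no CCS entries."""
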