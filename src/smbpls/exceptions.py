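"""Exception hierarchy for smbpls.

All errors derive from :class:`SMBPLSError` so callers can catch the whole
family; each also derives from ``ValueError`` to behave like ordinary
validation errors in scripts.
"""


class SMBPLSError(ValueError):
    """Base class for all smbpls errors."""


class ParameterError(SMBPLSError):
    """A tuning parameter or degree of sparsity is out of its valid range."""


class AlignmentError(SMBPLSError):
    """Blocks do not share identical sample identifiers in identical order."""


class OverFilteredBlockError(SMBPLSError):
    """Variation filtering left a block with fewer than two variables."""


class DegenerateInputError(SMBPLSError):
    """An input is degenerate for the requested computation.

    Examples: an all-zero block, a constant vector passed to a correlation
    test, or a zero latent variable passed to deflation.
    """


class EmptySupportError(DegenerateInputError):
    """Soft thresholding shrank an entire loading vector to zero."""
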