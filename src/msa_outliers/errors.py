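"""Exception hierarchy.

Every error a pipeline stage can raise derives from :class:`MsaOutliersError`
so the CLI can turn any failure into a one-line diagnosis and a nonzero exit.
"""


class MsaOutliersError(Exception):
    """Base class for all errors raised by this package."""


class UnalignedInputError(MsaOutliersError):
    """Rows of an alignment file are not all the same length."""


class DuplicateIdError(MsaOutliersError):
    """Two records in one input share a sequence identifier."""


class DistanceMatrixFormatError(MsaOutliersError):
    """A Phylip distance-matrix file is malformed or inconsistent."""


class ZeroSpreadError(MsaOutliersError):
    """The score distribution has no spread (sigma = 0 or IQR = 0).

    No finite normalised score exists; the message carries the advice on
    which normalisation to switch to.
    """


class ExternalToolError(MsaOutliersError):
    """An external search tool is missing or exited abnormally."""
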