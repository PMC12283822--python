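"""Exception hierarchy.

``InputError`` covers malformed or inconsistent user inputs (CLI exit code 2),
the remaining errors cover model/algorithm failures (CLI exit code 3).
"""


class KMVarError(Exception):
    """Base class for all kmvar errors."""


class InputError(KMVarError, ValueError):
    """Malformed, missing or inconsistent input data."""


class ParameterError(KMVarError, ValueError):
    """Invalid or unsolvable simulation/model parameters."""


class ReconstructionError(KMVarError):
    """The individual-record reconstruction could not match the published counts."""


class FitError(KMVarError):
    """A maximum-likelihood fit failed or is degenerate."""


class SingularDesignError(FitError):
    """The regression design matrix is rank deficient."""
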