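"""Exception hierarchy shared by all pipeline stages."""


class RBCFluidityError(Exception):
    """Base class for all package errors."""


class ParameterError(RBCFluidityError, ValueError):
    """A caller-supplied parameter is out of its valid range."""


class ShapeMismatchError(RBCFluidityError, ValueError):
    """Two rasters that must share a shape do not."""


class DegenerateInputError(RBCFluidityError, ValueError):
    """Input is structurally valid but carries no usable signal (e.g. empty mask)."""


class ConfigurationError(RBCFluidityError, ValueError):
    """A configuration combination the pipeline cannot honour."""
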