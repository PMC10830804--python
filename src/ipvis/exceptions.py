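"""Exception and warning types used across the package."""


class IPVError(Exception):
    """Base class for all package-specific errors."""


class NamingFormatError(IPVError, ValueError):
    """A column name does not follow the ``test_facet_item`` / ``test_item`` convention."""


class DuplicateItemError(NamingFormatError):
    """Two columns resolve to the same (test, facet, item) triple."""


class DegenerateDataError(IPVError, ValueError):
    """Input data are degenerate (e.g., a zero-variance column)."""


class InsufficientDataError(IPVError, ValueError):
    """Too few complete observations to estimate a covariance matrix."""


class StructuralError(IPVError, ValueError):
    """Model results are structurally incompatible (e.g., item sets differ across fits)."""


class NotConvergedError(IPVError, RuntimeError):
    """A model fit did not converge and downstream use was not overridden."""


class ChartConfigError(IPVError, ValueError):
    """Invalid chart configuration (bad zoom window, unsupported format, ...)."""


class IPVWarning(UserWarning):
    """Base class for package-specific warnings."""


class UnderIdentifiedFactorWarning(IPVWarning):
    """A factor has fewer than three items and is identified only through its correlations."""


class HeywoodWarning(IPVWarning):
    """A fit terminated on the admissibility boundary (residual variance ~ 0)."""


class UnboundedCenterDistanceWarning(IPVWarning):
    """A center distance was capped because the general loading is (near) zero."""


class ChartLayoutWarning(IPVWarning):
    """Chart geometry problem (overlapping circles, nested chart overflow, ...)."""


class RelativeScalingWarning(IPVWarning):
    """The nested chart uses a relative scaling other than 1; readers should be told."""
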