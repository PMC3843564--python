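"""Exception hierarchy for ncakit.

Every error raised by the package derives from :class:`NCAError` so callers
can catch domain failures without masking programming errors.
"""


class NCAError(Exception):
    """Base class for all ncakit errors."""


class LabelError(NCAError):
    """Duplicate or conflicting gene/TF labels."""


class EncodingError(NCAError):
    """Connectivity entry outside the ternary {-1, 0, +1} alphabet."""


class EmptyRegulonError(NCAError):
    """A TF column with no targets; names the offending TF."""


class DomainError(NCAError):
    """A value outside its mathematical domain (e.g. nonpositive ratio)."""


class AlignmentError(NCAError):
    """Label sets that cannot be reconciled across inputs."""


class DimensionError(NCAError):
    """Matrix shapes that do not conform."""


class ComplianceError(NCAError):
    """Decomposition requested on a pattern that is not NCA-compliant."""


class RankDeficiencyError(NCAError):
    """A singular least-squares sub-problem; names the gene involved."""


class GaugeError(NCAError):
    """Gauge normalization requested on an all-zero CS column."""


class AggregationError(NCAError):
    """Incompatible results passed to the replicate aggregator."""


class InfeasiblePruneError(NCAError):
    """Pruning exhausted the network without reaching compliance.

    Carries the partial :class:`~ncakit.compliance.PruneTrace` as ``trace``.
    """

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class InfeasibleParametersError(NCAError):
    """Synthetic-pattern rejection sampling failed to find a compliant draw."""


class InsufficientReplicationError(NCAError):
    """Fewer than two samples per condition for a two-sample test."""


class DegenerateVarianceError(NCAError):
    """Zero total variance makes R-squared undefined."""


class ConfigurationError(NCAError):
    """Invalid or missing run configuration."""
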