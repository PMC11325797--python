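"""Exception taxonomy.

Every failure mode surfaced by the public API maps to one of these classes so
callers (and the pipeline's per-stage error recording) can branch on category
rather than parse messages.
"""


class SwitchAllosteryError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(SwitchAllosteryError):
    """A file could not be parsed in its declared format."""


class EmptyInputError(SwitchAllosteryError):
    """An input contained no usable records (zero atoms, zero frames, ...)."""


class TopologyError(SwitchAllosteryError):
    """Trajectory and topology disagree (atom counts, residue resolution)."""


class DegenerateSuperpositionError(SwitchAllosteryError):
    """Superposition selection has <3 atoms or is collinear."""


class NoHydrogensError(SwitchAllosteryError):
    """Topology has no hydrogens; H-bond / proton-contact analysis undefined."""


class ConfigError(SwitchAllosteryError):
    """Invalid configuration (thresholds, YAML schema, processing sizes)."""


class ParameterizationError(SwitchAllosteryError):
    """Nonbonded parameters missing for one or more atoms."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(
            "no nonbonded parameters for atoms: "
            + ", ".join(f"{r}/{a}" for r, a in self.missing)
        )


class NormalizationError(SwitchAllosteryError):
    """Reference value unusable for normalization (absent, zero, negative)."""


class ComparisonError(SwitchAllosteryError):
    """Two results are not comparable (mismatched regions or criteria)."""


class AlignmentError(SwitchAllosteryError):
    """Spectral axes differ; no silent interpolation is performed."""


class WindowError(SwitchAllosteryError):
    """Integration/SNR window does not overlap the data."""


class DomainError(SwitchAllosteryError):
    """Scalar input outside the mathematical domain of an operation."""


class DegenerateNoiseError(SwitchAllosteryError):
    """Noise window has zero variance; SNR undefined."""


class FitFailureError(SwitchAllosteryError):
    """Nonlinear fit failed to converge or produced out-of-range parameters."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NoTransitionError(SwitchAllosteryError):
    """Melt curve shows no resolvable unfolding transition."""


class NoAssociationError(SwitchAllosteryError):
    """Kinetic trace shows no positive-rate association phase."""


class AggregationError(SwitchAllosteryError):
    """Replicate aggregation refused (non-converged members, n too small)."""


class SpecError(SwitchAllosteryError):
    """Synthetic-data specification invalid or self-conflicting."""


class UsageError(SwitchAllosteryError):
    """Operation applied to inputs it was not declared for."""
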