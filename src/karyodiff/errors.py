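"""Typed exceptions raised across the package.

Every reader and analysis stage raises one of these instead of returning a
partial object, so callers (and the pipeline driver) can abort with the stage
name and the offending entity.
"""


class KaryodiffError(Exception):
    """Base class for all package errors."""


class FormatError(KaryodiffError):
    """A file does not conform to its documented dialect."""


class MetadataError(KaryodiffError):
    """A sample is missing required metadata (genotype/batch)."""


class AnnotationError(KaryodiffError):
    """Gene annotation is inconsistent (e.g. duplicate gene ids)."""


class ConfigurationError(KaryodiffError):
    """A simulation or pipeline configuration violates its invariants."""


class NormalizationError(KaryodiffError):
    """Scale-factor estimation is impossible (e.g. an all-zero sample)."""


class DispersionError(KaryodiffError):
    """Dispersion cannot be estimated (no replication anywhere)."""


class DesignError(KaryodiffError):
    """The design matrix or a contrast over it is invalid."""


class ContrastError(KaryodiffError):
    """A contrast weight vector is degenerate (all zeros, wrong length)."""


class AdjustmentError(KaryodiffError):
    """Copy-number adjustment failed (chromosome missing from karyotype)."""


class DegenerateFitError(KaryodiffError):
    """A regression input carries no variance to fit."""


class CombineError(KaryodiffError):
    """Profiles cannot be combined (disjoint gene universes)."""


class CorrelationError(KaryodiffError):
    """Too few paired observations to correlate."""
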