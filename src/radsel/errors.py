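"""Typed exceptions raised across the radsel pipeline.

Every contract violation surfaces as one of these, never as a silent
default or a bare ValueError, so callers (and the CLI) can report which
stage rejected the input and why.
"""


class RadselError(Exception):
    """Base class for all radsel errors."""


class AlignmentError(RadselError):
    """Volume and mask disagree in shape or voxel spacing."""


class EmptyRegionError(RadselError):
    """A mask selects no voxels."""


class FormatError(RadselError):
    """An on-disk image is not a readable 3D volume."""


class SchemaError(RadselError):
    """A feature table violates its schema (duplicate names, unknown columns)."""


class TableParseError(RadselError):
    """A feature-table cell could not be parsed; message reports row/column."""


class ParameterError(RadselError):
    """A numeric parameter is outside its documented domain."""


class DegenerateRegionError(RadselError):
    """A region is too small or too uniform for the requested statistic."""


class DegenerateOutcomeError(RadselError):
    """An outcome vector has a single class or no events."""


class ConfigurationError(RadselError):
    """A configuration object is inconsistent (missing priority entries, bad blocks)."""
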