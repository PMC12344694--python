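"""Exception hierarchy shared across the package."""


class DynpotError(Exception):
    """Base class for all package errors."""


class FormatError(DynpotError):
    """A trajectory file violates the extended-XYZ dialect."""


class ConsistencyError(DynpotError):
    """Frames within one trajectory disagree (atom count, species order, ...)."""


class GeometryError(DynpotError):
    """Invalid geometry: cutoff beyond the half-cell bound, coincident atoms, ..."""


class SizeError(DynpotError):
    """A size precondition is violated (empty batch, S beyond S_max, ...)."""


class ParameterError(DynpotError):
    """A physical or configuration parameter is out of range."""


class VocabularyError(DynpotError):
    """A species is not part of the model's vocabulary."""


class PartitionError(DynpotError):
    """A species partition is inconsistent with the configuration."""


class TrainingFault(DynpotError):
    """Training produced a non-finite quantity."""


class GenerationFault(DynpotError):
    """Synthetic trajectory generation blew up."""
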