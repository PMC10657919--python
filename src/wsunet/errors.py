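"""Exception types shared across modules."""


class ConfigurationError(ValueError):
    """An invalid model, sampling or phantom configuration."""


class InfeasibleGeometryError(ValueError):
    """A lesion cannot be placed inside a lung field at the requested size."""


class NoTumourError(ValueError):
    """A volume contains no tumour voxels, so tumour-centred sampling is impossible."""


class EmptyDatasetError(ValueError):
    """Patch sampling produced no patches at all."""


class UndefinedMetricError(ValueError):
    """A metric is undefined on the given data (e.g. a single-class sample)."""


class DegenerateDataError(ValueError):
    """Bootstrap resampling could not produce enough well-defined replicates."""


class LeakageError(ValueError):
    """Training and validation sets share subjects."""
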