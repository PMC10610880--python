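"""Exception types shared across epiopt modules."""


class EpioptError(Exception):
    """Base class for all epiopt errors."""


class InvalidConfigError(EpioptError, ValueError):
    """A protocol or phantom configuration is inconsistent or incomplete."""


class TimingError(EpioptError, ValueError):
    """A sequence-timing quantity is inconsistent or non-physical."""


class InfeasibleTEError(TimingError):
    """The requested echo time cannot be realized by the echo train.

    Carries the minimum achievable TE so callers can report the deficit.
    """

    def __init__(self, te: float, min_te: float):
        self.te = float(te)
        self.min_te = float(min_te)
        self.deficit = self.min_te - self.te
        super().__init__(
            f"TE = {te:g} ms is below the minimum achievable TE = {min_te:g} ms "
            f"for this echo train; increase TE by at least {self.deficit:g} ms"
        )


class EmptyROIError(EpioptError, ValueError):
    """An ROI contains no valid voxels."""
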