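"""Exception types shared across the package."""


class AlignmentError(ValueError):
    """Two feature views disagree on sample count or label alignment."""


class NumericalRankError(RuntimeError):
    """A covariance block is numerically singular; regularization is needed."""


class StratificationError(ValueError):
    """A class has too few samples to stratify."""


class DegenerateVarianceError(ValueError):
    """A t-test was requested on samples with zero variance."""


class FitnessEvaluationError(RuntimeError):
    """An objective returned a non-finite value during optimization."""
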