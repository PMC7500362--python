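"""Exception hierarchy for mimsflux."""


class MimsError(Exception):
    """Base class for all mimsflux errors."""


class RegistryValidationError(MimsError):
    """A gas registry entry violates an invariant (names species and field)."""


class TraceParseError(MimsError):
    """A trace file could not be parsed (carries a line number when known)."""


class NormalizationError(MimsError):
    """Reference-gas normalization is impossible (non-positive reference)."""


class CalibrationError(MimsError):
    """Calibration cannot be established for a species or segment."""


class TemperatureRangeError(MimsError):
    """Requested temperature lies outside the tabulated solubility range."""


class UnmixingError(MimsError):
    """The mixing matrix is rank-deficient or channels are unusable."""


class AnalysisError(MimsError):
    """An isotope/kinetics analysis precondition failed."""


class SimulationError(MimsError):
    """The forward simulation produced an invalid state."""
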