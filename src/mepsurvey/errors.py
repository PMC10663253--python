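"""Exception hierarchy for the survey pipeline."""


class MepSurveyError(Exception):
    """Base class for all package errors."""


class FormatError(MepSurveyError, ValueError):
    """Malformed input file (FASTA, alignment, matrix TSV)."""


class ConfigError(MepSurveyError, ValueError):
    """Invalid configuration value (genetic code, threshold table, roles)."""


class ModelError(MepSurveyError, ValueError):
    """A profile HMM could not be built from the given alignment."""


class CalibrationError(MepSurveyError, RuntimeError):
    """Threshold or e-value calibration failed (degenerate inputs)."""
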