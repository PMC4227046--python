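"""Exception hierarchy shared across the pipeline."""


class MotophysError(Exception):
    """Base class for all package errors."""


class ValidationError(MotophysError):
    """Malformed input: bad file, bad units, inconsistent spec (exit code 2)."""


class AnalysisError(MotophysError):
    """A measurement could not be made on valid input (exit code 3)."""


class NoSpikeError(AnalysisError):
    """No spike was found where the protocol requires one."""
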