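"""Exception hierarchy; the CLI maps these onto exit codes (2 and 3)."""


class MethylinkError(Exception):
    """Base class for package errors."""


class ConfigurationError(MethylinkError):
    """Invalid parameter values or inconsistent configuration (exit code 2)."""


class DataIntegrityError(MethylinkError):
    """Inputs violate a structural contract, e.g. mismatched probe universes (exit code 3)."""
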