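"""Exception hierarchy shared across the pipeline stages."""


class LaughPDError(Exception):
    """Base class for all package errors."""


class InputError(LaughPDError, ValueError):
    """Malformed or insufficient input data (audio, features, labels)."""


class ConfigError(LaughPDError, ValueError):
    """Invalid analysis configuration (framing, bank, classifier, CV)."""


class DataError(LaughPDError, ValueError):
    """Data unusable for the requested computation (degenerate splits, NaNs)."""
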