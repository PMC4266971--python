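"""Exception hierarchy shared across the package."""


class ChromobinError(Exception):
    """Base class for all errors raised by chromobin."""


class ValidationError(ChromobinError):
    """Input data violates a structural invariant (duplicate ids, bad coordinates...)."""


class UploadError(ChromobinError):
    """A user-supplied upload (expression matrix, DEG list, group map) failed validation."""


class ConfigError(ChromobinError):
    """A genome or run configuration file is malformed or incomplete."""
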