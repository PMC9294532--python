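"""Exception hierarchy shared across the package."""


class KinvarError(Exception):
    """Base class for all package-specific errors."""


class FormatError(KinvarError):
    """A file is structurally unusable (missing columns, duplicate headers)."""


class RecordError(KinvarError):
    """A single record violates an invariant (bad residue code, start > end)."""


class ConsistencyError(KinvarError):
    """Two inputs that must agree do not (e.g. observed exchanges at a residue
    absent from the reference composition)."""


class InputError(KinvarError):
    """An argument is outside the operation's domain."""


class SimConfigError(KinvarError):
    """A simulation configuration field is invalid; message names the field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")
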