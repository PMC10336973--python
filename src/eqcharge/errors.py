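"""Exception hierarchy shared across the package."""


class EqChargeError(Exception):
    """Base class for all package errors."""


class UnsupportedElementError(EqChargeError):
    """An element symbol has no entry in the relevant table or model."""


class FormatError(EqChargeError):
    """A file does not follow its documented dialect."""


class ContractError(EqChargeError):
    """An argument violates a documented precondition."""
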