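"""Exception hierarchy shared across the package."""


class BrapiError(Exception):
    """Base class for all package errors."""


class ContractViolationError(BrapiError):
    """An envelope or pagination block was constructed inconsistently."""


class MalformedResultError(BrapiError):
    """A result object carries a ``data`` key that is not a list."""


class InvalidParameterError(BrapiError):
    """A caller-supplied parameter is outside its domain (maps to HTTP 400)."""


class ConfigurationError(BrapiError):
    """A fixture or server configuration is internally inconsistent."""


class TransportError(BrapiError):
    """The HTTP request could not be completed at all."""


class ProtocolError(BrapiError):
    """The server answered, but not with a valid response envelope."""

    def __init__(self, message, violations=()):
        super().__init__(message)
        self.violations = list(violations)


class StatusError(BrapiError):
    """The server answered with an HTTP error status.

    Carries the envelope's status entries so callers can inspect the
    server-side explanation.
    """

    def __init__(self, http_status, statuses=()):
        self.http_status = http_status
        self.statuses = list(statuses)
        detail = "; ".join(
            "%s: %s" % (s.get("code"), s.get("message")) for s in self.statuses
        )
        super().__init__("HTTP %d%s" % (http_status, (" — " + detail) if detail else ""))
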