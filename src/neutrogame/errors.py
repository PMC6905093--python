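class NeutrogameError(Exception):
    """Base class for errors raised by neutrogame."""


class InvalidParameterError(NeutrogameError, ValueError):
    """A model parameter violates its domain (non-finite, wrong sign, infeasible)."""
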