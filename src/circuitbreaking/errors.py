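class CBAError(Exception):
    """Base class for all package errors."""


class ModelError(CBAError, ValueError):
    """Invalid model description (undeclared identifier, bad bounds, ...)."""


class EngineError(CBAError, RuntimeError):
    """Numerical failure inside the circuit-breaking engine."""


class SingularReducedJacobianError(CBAError, ArithmeticError):
    """The reduced Jacobian is singular; the determinant-ratio slope is undefined.

    This typically happens exactly at a fold, where the characteristic is
    tangent to zero.
    """
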