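"""Exception hierarchy for ecmkit."""


class EcmError(Exception):
    """Base class for all ecmkit errors."""


class ModelFormatError(EcmError):
    """A table or reaction formula could not be parsed."""


class CrossReferenceError(EcmError):
    """A table row references an identifier that does not exist."""


class ParameterConflictError(EcmError):
    """Two parameter rows define the same (quantity, reaction, compound)."""


class MissingParameterError(EcmError):
    """A parameter required by the chosen cost function is absent."""


class UnderdeterminedError(EcmError):
    """The balancing system does not determine all output parameters."""


class ThermodynamicInfeasibilityError(EcmError):
    """The flux directions admit no feasible metabolite profile.

    Carries the irreducible infeasible subset of driving-force
    constraints (reaction identifiers) when one could be computed.
    """

    def __init__(self, message, infeasible_reactions=None):
        super().__init__(message)
        self.infeasible_reactions = list(infeasible_reactions or [])


class InfeasiblePointError(EcmError):
    """A metabolite profile violates a driving-force constraint."""


class ConvergenceError(EcmError):
    """The optimizer failed to converge; carries the last iterate."""

    def __init__(self, message, last_x=None):
        super().__init__(message)
        self.last_x = last_x
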