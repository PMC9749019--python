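"""Exception hierarchy for lrdock."""


class LrdockError(Exception):
    """Base class for all lrdock-specific errors."""


class EmptyStructureError(LrdockError):
    """A structure file parsed to zero atoms."""


class ParameterLookupError(LrdockError, KeyError):
    """Strict parameter assignment met unknown (residue, atom) pairs."""

    def __init__(self, offenders):
        self.offenders = list(offenders)
        names = ", ".join(f"{r}/{a}" for r, a in self.offenders)
        super().__init__(f"no parameters for: {names}")


class UnparameterizedError(LrdockError):
    """A force/collision call received a molecule without assigned parameters."""


class ShapeError(LrdockError, ValueError):
    """Array dimensions inconsistent with the model or structure."""


class MissingHydrogensError(LrdockError):
    """Hydrogen-bond detection requested on a structure without hydrogens."""


class CollisionModeError(LrdockError):
    """Overlap collision mode requested together with a flexible receptor."""


class ValidationError(LrdockError, ValueError):
    """Generic input validation failure (non-finite coordinates etc.)."""
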