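"""Exception hierarchy.

Every rejected input or refused computation raises a distinct, named error so
that callers (and the CLI) can react to the precise violated condition instead
of parsing message strings.
"""


class ValleycrossError(Exception):
    """Base class for all package errors."""


# --- model validation -------------------------------------------------------

class ModelValidationError(ValleycrossError):
    """A trait-graph model document violates the schema or an invariant."""


class SchemaError(ModelValidationError):
    """Structural problem: missing/unknown keys, wrong types, unknown traits."""


class IntegerAlphaError(ModelValidationError):
    """The mutation exponent alpha must be a positive non-integer."""


class NegativeRateError(ModelValidationError):
    """A birth/death/competition/mutation rate is out of range."""


class SelfCompetitionError(ModelValidationError):
    """c(v, v) must be strictly positive for every trait."""


class MutantLawError(ModelValidationError):
    """m(v, .) is not a probability measure on the out-neighbours of v."""


class UnknownTraitError(ValleycrossError):
    """A trait identifier does not belong to the model."""


class PathOverflowError(ValleycrossError):
    """Shortest-path enumeration exceeded the configured cap."""


# --- deterministic ecology --------------------------------------------------

class DegenerateLVError(ValleycrossError):
    """The Lotka-Volterra interaction matrix on a support is singular with
    infinitely many equilibria; the uniqueness assumptions fail."""


class ZeroInvasionFitnessError(ValleycrossError):
    """An invasion fitness is zero within tolerance; the calculus branches on
    sign(f) and cannot proceed."""


class CriticalExcursionError(ValleycrossError):
    """rho = 1/2: the excursion birth-death process is critical and the
    expected birth count diverges."""


class NoUniqueEquilibriumError(ValleycrossError):
    """A Lotka-Volterra phase did not settle on a unique attractor (multi-
    start disagreement, non-convergence, or an uncertifiable equilibrium)."""


class StabilityUnknownError(ValleycrossError):
    """An equilibrium's stability could not be certified and the caller did
    not override."""


class NotAnESCError(ValleycrossError):
    """The proposed resident set does not satisfy the evolutionary-stable-
    condition requirements; carries the violated condition."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class UnreachableTraitError(ValleycrossError):
    """A trait inside the mutation-spreading neighbourhood is not reachable
    from the residents, so the mutation-fed profile is ill-defined."""


class InvasionTerminatedError(ValleycrossError):
    """The ln K invasion dynamics hit a termination criterion; carries the
    reason and the mutant that triggered it."""

    def __init__(self, reason: str, mutant=None):
        super().__init__(f"ln K dynamics terminated ({reason})"
                         + (f" for mutant {mutant!r}" if mutant is not None else ""))
        self.reason = reason
        self.mutant = mutant


class FinitePassageError(ValleycrossError):
    """The jump chain can get stuck below the requested time scale; carries a
    witness set of states from which no sufficiently stable state is
    reachable."""

    def __init__(self, L, witness):
        super().__init__(
            f"finite-passage assumption fails at L={L}; witness states: "
            + ", ".join(sorted(map(str, witness))))
        self.L = L
        self.witness = witness
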