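"""Exception hierarchy shared across the package."""


class ModelError(ValueError):
    """Base class for model-specification problems."""


class ModelSyntaxError(ModelError):
    """Malformed model syntax (bad line, duplicate outcome, unknown name)."""


class CycleError(ModelError):
    """The equation graph is not acyclic."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__(
            "model is not recursive; cycle detected: "
            + " -> ".join(self.cycle + [self.cycle[0]])
        )


class PathError(ModelError):
    """Base class for path-query problems."""


class PathNotFoundError(PathError):
    """A requested path does not exist in the model."""


class PathDirectionError(PathError):
    """A requested path runs against the direction of the model's edges."""


class DisconnectedModelError(ModelError):
    """The equations do not form a single connected model."""

    def __init__(self, components):
        self.components = [frozenset(c) for c in components]
        parts = "; ".join(
            "{" + ", ".join(sorted(c)) + "}" for c in self.components
        )
        super().__init__(f"model variables are not connected: components {parts}")


class EstimationError(ValueError):
    """Base class for estimation problems."""


class SameCasesError(EstimationError):
    """Equations would be fitted on different complete-case sets."""


class RankDeficiencyError(EstimationError):
    """A design matrix is rank deficient."""


class ProductMismatchError(EstimationError):
    """A registered product column disagrees with moderator x focal."""


class EffectError(ValueError):
    """Invalid effect computation (mixed signs, mismatched flags, ...)."""


class ReplicationError(RuntimeError):
    """Replicate generation failed (too many degenerate resamples, ...)."""
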