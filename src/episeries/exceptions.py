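"""Exception hierarchy for episeries."""


class EpiseriesError(Exception):
    """Base class for all episeries errors."""


class SchemaError(EpiseriesError):
    """Input table is missing a required column or has a malformed header."""


class DataValueError(EpiseriesError):
    """A cell value violates a type invariant (e.g. non-positive locule count)."""


class DuplicateKeyError(EpiseriesError):
    """Duplicated (trial, genotype, plant, fruit) key in a phenotype table."""


class DesignError(EpiseriesError):
    """Experiment design inconsistent with the observed genotypes."""


class NotNestedError(EpiseriesError):
    """Likelihood-ratio test requested for a non-nested model pair."""


class OptimizationFailureError(EpiseriesError):
    """Nested-model likelihoods are inconsistent beyond tolerance."""


class NotConvergedError(EpiseriesError):
    """Operation requires a converged fit."""


class DegenerateVarianceError(EpiseriesError):
    """Variance decomposition undefined (no epistatic variance)."""
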