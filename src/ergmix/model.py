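"""Model specifications: which sufficient-statistic terms are active.

Four nested specifications are supported.  ``base`` holds an edges term and
the full set of selective-mixing (label-pair) terms; ``structural`` adds the
three structural nodal covariates and a latent-cluster homophily term;
``gwesp`` adds a fixed-decay geometrically weighted edgewise-shared-partner
term to the base; ``complete`` contains everything.
"""

from __future__ import annotations

from dataclasses import dataclass, field

SPEC_NAMES = ("base", "structural", "gwesp", "complete")

#: structural nodal covariate columns, in term order
STRUCT_COVARIATES = ("struct_degree", "struct_efficiency", "struct_clustering")

DEFAULT_GWESP_DECAY = 0.5


@dataclass(frozen=True)
class ModelSpec:
    """A named term set plus the GWESP decay (fixed, not estimated).

    ``standardize_covariates`` z-scores the structural nodal covariates
    before they enter the statistic vector (the default; raw degree and
    clustering live on incomparable scales).
    """

    name: str
    gwesp_decay: float = DEFAULT_GWESP_DECAY
    standardize_covariates: bool = True

    def __post_init__(self) -> None:
        if self.name not in SPEC_NAMES:
            raise ValueError(
                f"unknown spec {self.name!r}; expected one of {SPEC_NAMES}"
            )
        if self.gwesp_decay < 0:
            raise ValueError("gwesp_decay must be >= 0")

    @property
    def has_structural(self) -> bool:
        return self.name in ("structural", "complete")

    @property
    def has_gwesp(self) -> bool:
        return self.name in ("gwesp", "complete")

    @property
    def dyad_independent(self) -> bool:
        """True when the likelihood factorizes over dyads (no GWESP term)."""
        return not self.has_gwesp

    def term_names(self, labels) -> list[str]:
        """Ordered term identifiers given the per-node label sequence.

        One mixing cell -- the lexicographically first within-category cell
        -- is dropped as the reference to avoid collinearity with ``edges``.
        """
        cells = mixing_cells(labels)
        names = ["edges"]
        names += [f"mix.{a}.{b}" for a, b in cells[1:]]
        if self.has_structural:
            names += [f"nodecov.{c}" for c in STRUCT_COVARIATES]
            names += ["nodematch.latent"]
        if self.has_gwesp:
            names += [f"gwesp({self.gwesp_decay})"]
        return names


def mixing_cells(labels) -> list[tuple[str, str]]:
    """Estimable unordered label pairs; the reference cell leads the list.

    ``labels`` is the per-node label sequence (repeats carry multiplicity)
    or, when already unique, each label is treated as having at least two
    nodes.  Within-category cells for labels carried by a single node have
    no dyads and are dropped.  The reference -- excluded from model terms
    to avoid collinearity with ``edges`` -- is the within-category cell of
    the label with the most nodes (ties broken lexicographically): every
    mixing contrast inherits the reference cell's sampling noise, so the
    best-populated cell gives the best-conditioned contrasts.
    """
    labels = list(labels)
    counts = {lab: labels.count(lab) for lab in labels}
    labs = sorted(counts)
    if len(labs) == len(labels):  # bare label universe, no multiplicities
        counts = {lab: 2 for lab in labs}
    cells = [
        (labs[i], labs[j])
        for i in range(len(labs))
        for j in range(i, len(labs))
        if labs[i] != labs[j] or counts[labs[i]] >= 2
    ]
    within = [c for c in cells if c[0] == c[1]]
    if within:
        ref = sorted(within, key=lambda c: (-counts[c[0]], c[0]))[0]
    else:
        ref = cells[0]
    cells.remove(ref)
    return [ref] + cells


@dataclass(frozen=True)
class ComparisonSpec:
    """A full-vs-partial model pair used by the misspecification audit."""

    name: str
    full_model: ModelSpec
    partial_model: ModelSpec = field(default_factory=lambda: ModelSpec("base"))

    _VALID = {
        "structural_effect": "structural",
        "gwesp_effect": "gwesp",
        "interaction_effect": "complete",
    }

    def __post_init__(self) -> None:
        expected = self._VALID.get(self.name)
        if expected is None:
            raise ValueError(f"unknown comparison {self.name!r}")
        if self.full_model.name != expected or self.partial_model.name != "base":
            raise ValueError(
                f"comparison {self.name!r} must pair full={expected!r} "
                "with partial='base'"
            )


def standard_comparisons(gwesp_decay: float = DEFAULT_GWESP_DECAY) -> list[ComparisonSpec]:
    """The three audited comparisons, each against the base model."""
    return [
        ComparisonSpec("structural_effect", ModelSpec("structural", gwesp_decay)),
        ComparisonSpec("gwesp_effect", ModelSpec("gwesp", gwesp_decay)),
        ComparisonSpec("interaction_effect", ModelSpec("complete", gwesp_decay)),
    ]
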