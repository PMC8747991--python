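"""Synthetic evidence-matrix generator.

Emulates the data substrate of a multi-compendium interaction comparison:
a fixed universe of psychotropic x COVID-19 drug pairs, per-resource
coverage (scope), per-component documentation probabilities (completeness),
and a latent true severity per pair observed through a per-resource
confusion process whose single ``agreement`` parameter alpha controls
inter-resource concordance: with probability alpha a resource reports the
latent category, otherwise it draws uniformly from the whole category set.
alpha = 1 is the noiseless limit (kappa = 1); alpha = 0 makes ratings
independent of the latent state (kappa = 0 in expectation), so estimated
agreement is monotone in alpha across its whole range.

Resources are sampled independently given the latent severity; real
compendia overlap non-randomly, so synthetic coverage joint structure is
simpler than reality (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .core import (
    COMPONENT_FLAGS,
    COVID_DRUGS,
    CANONICAL_RESOURCES,
    ActionCategory,
    DrugPair,
    EvidenceMatrix,
    PSYCHOTROPIC_DRUGS,
    ResourceEntry,
    SeverityCategory,
)

__all__ = ["ResourceSpec", "SyntheticConfig", "generate_matrix", "study_marginal_config"]

_SEVERITIES = (
    SeverityCategory.MINOR,
    SeverityCategory.MODERATE,
    SeverityCategory.MAJOR_CONTRAINDICATED,
)

#: latent severity -> management recommendation
_LATENT_ACTION = {
    SeverityCategory.MINOR: ActionCategory.NO_ACTION,
    SeverityCategory.MODERATE: ActionCategory.MONITOR,
    SeverityCategory.MAJOR_CONTRAINDICATED: ActionCategory.AVOID,
}

_ACTIONS = (
    ActionCategory.NO_ACTION,
    ActionCategory.MONITOR,
    ActionCategory.MODIFY_DOSAGE,
    ActionCategory.AVOID,
)

#: native severity labels written into severity_raw, per canonical resource
_SEVERITY_LABELS: dict[str, dict[SeverityCategory, str]] = {
    "pepid": {
        SeverityCategory.MINOR: "2",
        SeverityCategory.MODERATE: "3",
        SeverityCategory.MAJOR_CONTRAINDICATED: "5",
    },
    "micromedex": {
        SeverityCategory.MINOR: "Minor",
        SeverityCategory.MODERATE: "Moderate",
        SeverityCategory.MAJOR_CONTRAINDICATED: "Major",
    },
    "uptodate": {
        SeverityCategory.MINOR: "B",
        SeverityCategory.MODERATE: "C",
        SeverityCategory.MAJOR_CONTRAINDICATED: "X",
    },
    "drugscom": {
        SeverityCategory.MINOR: "Minor",
        SeverityCategory.MODERATE: "Moderate",
        SeverityCategory.MAJOR_CONTRAINDICATED: "Major",
    },
    "medscape": {
        SeverityCategory.MINOR: "Minor",
        SeverityCategory.MODERATE: "Monitor closely",
        SeverityCategory.MAJOR_CONTRAINDICATED: "Serious",
    },
    "webmd": {
        SeverityCategory.MINOR: "Minor",
        SeverityCategory.MODERATE: "Monitor closely",
        SeverityCategory.MAJOR_CONTRAINDICATED: "Serious",
    },
}

_ACTION_LABELS = {
    ActionCategory.NO_ACTION: "No action required",
    ActionCategory.MONITOR: "Monitor",
    ActionCategory.MODIFY_DOSAGE: "Modify dosage",
    ActionCategory.AVOID: "Avoid combination",
}


@dataclass
class ResourceSpec:
    """Per-resource sampling parameters."""

    resource_id: str
    coverage: float  # P(resource has an entry for a pair)
    doc_probs: dict[str, float]  # per component flag, conditional on presence

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must lie in [0, 1]")
        missing = set(COMPONENT_FLAGS) - set(self.doc_probs)
        if missing:
            raise ValueError(f"doc_probs missing {sorted(missing)}")
        for flag, p in self.doc_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"doc_probs[{flag}] must lie in [0, 1]")


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults emulate the study conditions."""

    n_pairs: int = 181
    resources: list[ResourceSpec] = field(default_factory=list)
    severity_dist: tuple[float, float, float] = (0.05, 0.55, 0.40)  # minor/moderate/major
    agreement: float = 0.8  # alpha: P(resource reports the latent category)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if not 0.0 <= self.agreement <= 1.0:
            raise ValueError("agreement must lie in [0, 1]")
        if len(self.severity_dist) != 3 or not np.isclose(sum(self.severity_dist), 1.0):
            raise ValueError("severity_dist must be 3 probabilities summing to 1")

    def to_dict(self) -> dict:
        return asdict(self)


def _uniform_spec(resource_id: str) -> ResourceSpec:
    return ResourceSpec(resource_id, 1.0, {flag: 1.0 for flag in COMPONENT_FLAGS})


def study_marginal_config(seed: int = 0, agreement: float = 0.8) -> SyntheticConfig:
    """Configuration whose coverage and documentation probabilities equal the
    marginal rates observed in the six-resource psychotropic x COVID-19
    comparison (181 pairs): e.g. PEPID covers 143/181 pairs and documents
    clinical effects for 114/143 of them."""
    marginals = {
        #             coverage   mech      clin      sev       doc       action
        "pepid": (143, 143, 114, 143, 139, 143),
        "micromedex": (85, 83, 81, 85, 85, 85),
        "uptodate": (71, 68, 26, 71, 71, 66),
        "drugscom": (115, 115, 23, 115, 45, 115),
        "medscape": (95, 71, 36, 94, 16, 94),
        "webmd": (81, 52, 21, 81, 16, 81),
    }
    resources = []
    for rid in CANONICAL_RESOURCES:
        n, *components = marginals[rid]
        resources.append(
            ResourceSpec(
                resource_id=rid,
                coverage=n / 181,
                doc_probs={
                    flag: c / n for flag, c in zip(COMPONENT_FLAGS, components)
                },
            )
        )
    return SyntheticConfig(
        n_pairs=181, resources=resources, agreement=agreement, seed=seed
    )


def _severity_label(resource_id: str, cat: SeverityCategory) -> str:
    try:
        return _SEVERITY_LABELS[resource_id][cat]
    except KeyError:
        return cat.value  # non-canonical resources use identity labels


def generate_matrix(config: SyntheticConfig) -> EvidenceMatrix:
    """Sample a fully reproducible evidence matrix.

    Pairs are drawn without replacement from the psychotropic x COVID-19
    cross-product; each resource then independently covers each pair with
    its coverage probability, documents each component conditionally on
    presence, and reports severity / action through the confusion model.
    Per-resource substreams are spawned from the root seed so the draw for
    one resource does not depend on how many others are configured.
    """
    resources = config.resources or [_uniform_spec(r) for r in CANONICAL_RESOURCES]

    universe = [
        (drug, cls, covid)
        for cls, drugs in PSYCHOTROPIC_DRUGS.items()
        for drug in drugs
        for covid in COVID_DRUGS
    ]
    if config.n_pairs > len(universe):
        raise ValueError(
            f"n_pairs={config.n_pairs} exceeds the {len(universe)}-pair drug universe"
        )

    root = np.random.SeedSequence(config.seed)
    ss_pairs, ss_latent, *ss_resources = root.spawn(2 + len(resources))
    rng_pairs = np.random.default_rng(ss_pairs)
    rng_latent = np.random.default_rng(ss_latent)

    idx = np.sort(
        rng_pairs.choice(len(universe), size=config.n_pairs, replace=False)
    )
    width = len(str(config.n_pairs))
    pairs = [
        DrugPair(
            pair_id=f"P{k + 1:0{width}d}",
            psychotropic=universe[i][0],
            covid_drug=universe[i][2],
            psychotropic_class=universe[i][1],
        )
        for k, i in enumerate(idx)
    ]
    latent = rng_latent.choice(3, size=config.n_pairs, p=list(config.severity_dist))

    entries: list[ResourceEntry] = []
    alpha = config.agreement
    for spec, ss in zip(resources, ss_resources):
        rng = np.random.default_rng(ss)
        for k, pair in enumerate(pairs):
            if rng.random() >= spec.coverage:
                entries.append(ResourceEntry(pair.pair_id, spec.resource_id, present=False))
                continue
            flags = {
                flag: bool(rng.random() < spec.doc_probs[flag])
                for flag in COMPONENT_FLAGS
            }
            latent_sev = _SEVERITIES[latent[k]]
            sev_raw, sev_std = "", SeverityCategory.UNRATED
            if flags["has_severity"]:
                if rng.random() < alpha:
                    sev_std = latent_sev
                else:
                    sev_std = _SEVERITIES[rng.integers(len(_SEVERITIES))]
                sev_raw = _severity_label(spec.resource_id, sev_std)
            act_raw, act_std = "", ActionCategory.UNRATED
            if flags["has_course_of_action"]:
                latent_act = _LATENT_ACTION[latent_sev]
                if rng.random() < alpha:
                    act_std = latent_act
                else:
                    act_std = _ACTIONS[rng.integers(len(_ACTIONS))]
                act_raw = _ACTION_LABELS[act_std]
            entries.append(
                ResourceEntry(
                    pair_id=pair.pair_id,
                    resource_id=spec.resource_id,
                    present=True,
                    **flags,
                    severity_raw=sev_raw,
                    severity_std=sev_std,
                    action_raw=act_raw,
                    action_std=act_std,
                )
            )
    return EvidenceMatrix(pairs, [s.resource_id for s in resources], entries)
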