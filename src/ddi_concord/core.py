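"""Domain types and the evidence-matrix container.

The unit of analysis is a *drug pair* (one psychotropic drug combined with
one COVID-19 drug) evaluated against several drug-information resources
(compendia).  For each (pair, resource) combination there is exactly one
:class:`ResourceEntry` recording whether the resource lists the interaction
at all (*scope*), which of five documentation components it covers
(*completeness*), and its severity / course-of-action ratings both in the
resource's native vocabulary and after harmonization (*consistency*).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "SeverityCategory",
    "ActionCategory",
    "DrugPair",
    "ResourceEntry",
    "EvidenceMatrix",
    "SeverityMap",
    "COMPONENT_FLAGS",
    "CANONICAL_RESOURCES",
    "PSYCHOTROPIC_DRUGS",
    "COVID_DRUGS",
    "validate_matrix",
    "read_matrix_csv",
    "write_matrix_csv",
    "MatrixSchemaError",
]

#: The five documentation components that make up the 0-5 completeness score.
COMPONENT_FLAGS = (
    "has_mechanism",
    "has_clinical_effects",
    "has_severity",
    "has_documentation_level",
    "has_course_of_action",
)

#: Canonical report ordering for the six compendia under comparison.
CANONICAL_RESOURCES = (
    "pepid",
    "micromedex",
    "uptodate",
    "drugscom",
    "medscape",
    "webmd",
)

#: Psychotropic drug universe, keyed by pharmacological class.
PSYCHOTROPIC_DRUGS: Mapping[str, tuple[str, ...]] = {
    "SSRI": (
        "fluvoxamine",
        "fluoxetine",
        "sertraline",
        "citalopram",
        "escitalopram",
        "paroxetine",
    ),
    "SNRI": ("duloxetine", "venlafaxine"),
    "TCA": (
        "amitriptyline",
        "nortriptyline",
        "imipramine",
        "clomipramine",
        "doxepin",
    ),
    "MAOI": ("isocarboxazid", "phenelzine", "tranylcypromine"),
    "other-antidepressant": (
        "bupropion",
        "mirtazapine",
        "trazodone",
        "vilazodone",
        "vortioxetine",
    ),
    "antipsychotic": (
        "chlorpromazine",
        "haloperidol",
        "trifluoperazine",
        "quetiapine",
        "risperidone",
        "olanzapine",
        "aripiprazole",
        "ziprasidone",
        "clozapine",
    ),
    "mood-stabilizer": ("carbamazepine", "valproic acid", "lamotrigine", "lithium"),
    "anxiolytic": ("diazepam", "midazolam", "alprazolam"),
}

#: Repurposed / investigational COVID-19 medications screened against the
#: psychotropic list.
COVID_DRUGS = (
    "hydroxychloroquine",
    "lopinavir",
    "ritonavir",
    "azithromycin",
    "dexamethasone",
    "ivermectin",
    "remdesivir",
    "interferon",
    "tocilizumab",
)

PSYCHOTROPIC_CLASSES = tuple(PSYCHOTROPIC_DRUGS)


class SeverityCategory(str, enum.Enum):
    """Harmonized interaction-severity scale.

    ``minor`` is retained as a distinct category even though the study
    sample contains only moderate-or-worse interactions: a resource that
    rates a sampled pair *minor* disagrees with the inclusion criteria and
    is, by construction, never consistent with the majority.
    """

    MINOR = "minor"
    MODERATE = "moderate"
    MAJOR_CONTRAINDICATED = "major_contraindicated"
    UNRATED = "unrated"


class ActionCategory(str, enum.Enum):
    """Harmonized course-of-action (management) recommendation."""

    NO_ACTION = "no_action"
    MONITOR = "monitor"
    MODIFY_DOSAGE = "modify_dosage"
    AVOID = "avoid"
    UNRATED = "unrated"


@dataclass(frozen=True)
class DrugPair:
    """One psychotropic x COVID-19 drug combination under evaluation."""

    pair_id: str
    psychotropic: str
    covid_drug: str
    psychotropic_class: str


@dataclass(frozen=True)
class ResourceEntry:
    """One resource's record for one drug pair.

    ``present=False`` means the resource has no entry for the pair at all
    (a scope miss); all component flags are then false and both
    standardized ratings ``unrated``.
    """

    pair_id: str
    resource_id: str
    present: bool
    has_mechanism: bool = False
    has_clinical_effects: bool = False
    has_severity: bool = False
    has_documentation_level: bool = False
    has_course_of_action: bool = False
    severity_raw: str = ""
    severity_std: SeverityCategory = SeverityCategory.UNRATED
    action_raw: str = ""
    action_std: ActionCategory = ActionCategory.UNRATED

    @property
    def completeness_score(self) -> int:
        """Number of documented components, 0-5."""
        return sum(int(getattr(self, flag)) for flag in COMPONENT_FLAGS)


@dataclass
class SeverityMap:
    """Per-resource severity vocabulary plus a shared action vocabulary.

    Lookups are case-insensitive after whitespace trimming; keys are stored
    casefolded.  An unknown label is a loud error, never a silent coercion.
    """

    severity: dict[str, dict[str, SeverityCategory]]
    action: dict[str, ActionCategory]

    def __post_init__(self) -> None:
        self.severity = {
            rid: {_norm(k): SeverityCategory(v) for k, v in table.items()}
            for rid, table in self.severity.items()
        }
        self.action = {_norm(k): ActionCategory(v) for k, v in self.action.items()}

    def resources(self) -> tuple[str, ...]:
        return tuple(self.severity)


def _norm(label: str) -> str:
    return label.strip().casefold()


@dataclass
class EvidenceMatrix:
    """The pair x resource evidence collection — the pipeline's sole input."""

    pairs: list[DrugPair]
    resources: list[str]
    entries: list[ResourceEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: dict[tuple[str, str], ResourceEntry] = {
            (e.pair_id, e.resource_id): e for e in self.entries
        }

    def entry(self, pair_id: str, resource_id: str) -> ResourceEntry:
        return self._index[(pair_id, resource_id)]

    def entries_for_resource(self, resource_id: str) -> list[ResourceEntry]:
        return [e for e in self.entries if e.resource_id == resource_id]

    def entries_for_pair(self, pair_id: str) -> list[ResourceEntry]:
        return [e for e in self.entries if e.pair_id == pair_id]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def replace_entries(self, entries: Iterable[ResourceEntry]) -> "EvidenceMatrix":
        return EvidenceMatrix(list(self.pairs), list(self.resources), list(entries))


class MatrixSchemaError(ValueError):
    """Raised when an evidence-matrix CSV violates the expected schema."""


def validate_matrix(matrix: EvidenceMatrix) -> list[str]:
    """Check every structural invariant; return human-readable violations.

    Returns an empty list iff the matrix is valid.  Reporting-only: the
    matrix is never modified.
    """
    violations: list[str] = []
    pair_ids = [p.pair_id for p in matrix.pairs]
    seen_pairs = set()
    for pid in pair_ids:
        if pid in seen_pairs:
            violations.append(f"pair {pid}: duplicate pair_id")
        seen_pairs.add(pid)

    psychotropic_universe = {d for drugs in PSYCHOTROPIC_DRUGS.values() for d in drugs}
    for p in matrix.pairs:
        if p.psychotropic not in psychotropic_universe:
            violations.append(
                f"pair {p.pair_id}: psychotropic '{p.psychotropic}' not in drug universe"
            )
        if p.covid_drug not in COVID_DRUGS:
            violations.append(
                f"pair {p.pair_id}: covid_drug '{p.covid_drug}' not in drug universe"
            )
        if p.psychotropic_class not in PSYCHOTROPIC_CLASSES:
            violations.append(
                f"pair {p.pair_id}: unknown psychotropic_class '{p.psychotropic_class}'"
            )

    if len(matrix.resources) < 2:
        violations.append("matrix: fewer than 2 resources")

    expected = {(pid, rid) for pid in pair_ids for rid in matrix.resources}
    seen: set[tuple[str, str]] = set()
    for e in matrix.entries:
        key = (e.pair_id, e.resource_id)
        if key in seen:
            violations.append(
                f"pair {e.pair_id}, resource {e.resource_id}: duplicate entry"
            )
        seen.add(key)
        if key not in expected:
            violations.append(
                f"pair {e.pair_id}, resource {e.resource_id}: entry outside pair/resource grid"
            )
        if not e.present:
            if any(getattr(e, flag) for flag in COMPONENT_FLAGS):
                violations.append(
                    f"pair {e.pair_id}, resource {e.resource_id}: "
                    "absent entry has component flags set"
                )
            if e.severity_std is not SeverityCategory.UNRATED:
                violations.append(
                    f"pair {e.pair_id}, resource {e.resource_id}: "
                    "absent entry has a severity rating"
                )
            if e.action_std is not ActionCategory.UNRATED:
                violations.append(
                    f"pair {e.pair_id}, resource {e.resource_id}: "
                    "absent entry has an action rating"
                )
        else:
            if not e.has_severity and e.severity_std is not SeverityCategory.UNRATED:
                violations.append(
                    f"pair {e.pair_id}, resource {e.resource_id}: "
                    "severity rated but has_severity is false"
                )
            if (
                not e.has_course_of_action
                and e.action_std is not ActionCategory.UNRATED
            ):
                violations.append(
                    f"pair {e.pair_id}, resource {e.resource_id}: "
                    "action rated but has_course_of_action is false"
                )
    missing = expected - seen
    for pid, rid in sorted(missing):
        violations.append(f"pair {pid}, resource {rid}: missing entry")
    return violations


CSV_COLUMNS = [
    "pair_id",
    "psychotropic",
    "covid_drug",
    "psychotropic_class",
    "resource_id",
    "present",
    "has_mechanism",
    "has_clinical_effects",
    "has_severity",
    "has_documentation_level",
    "has_course_of_action",
    "severity_raw",
    "action_raw",
]

_BOOL_COLUMNS = ["present", *COMPONENT_FLAGS]


def write_matrix_csv(matrix: EvidenceMatrix, path) -> None:
    """Write the evidence matrix as a flat UTF-8 CSV (booleans as 0/1)."""
    pair_by_id = {p.pair_id: p for p in matrix.pairs}
    rows = []
    for e in matrix.entries:
        p = pair_by_id[e.pair_id]
        rows.append(
            {
                "pair_id": e.pair_id,
                "psychotropic": p.psychotropic,
                "covid_drug": p.covid_drug,
                "psychotropic_class": p.psychotropic_class,
                "resource_id": e.resource_id,
                "present": int(e.present),
                **{flag: int(getattr(e, flag)) for flag in COMPONENT_FLAGS},
                "severity_raw": e.severity_raw,
                "action_raw": e.action_raw,
            }
        )
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df.to_csv(path, index=False, encoding="utf-8")


def read_matrix_csv(path, resources: Iterable[str] | None = None) -> EvidenceMatrix:
    """Read an evidence-matrix CSV.

    An absent row for a (pair, resource) combination is materialized as
    ``present=False`` with all flags false: a missing row means the
    resource has no entry for that pair, not missing data.

    Parameters
    ----------
    path : path-like
        CSV file with header; see :data:`CSV_COLUMNS`.
    resources : iterable of str, optional
        Resource universe.  Defaults to the distinct ``resource_id`` values
        in the file, in canonical-then-alphabetical order.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise MatrixSchemaError(f"missing column(s): {', '.join(missing_cols)}")
    for col in _BOOL_COLUMNS:
        bad = ~df[col].isin(["0", "1"])
        if bad.any():
            row = int(df.index[bad][0]) + 2  # header is row 1
            raise MatrixSchemaError(
                f"column {col}: non-0/1 value at file row {row}"
            )

    pairs: list[DrugPair] = []
    seen_pairs: dict[str, DrugPair] = {}
    for _, r in df.iterrows():
        pid = r["pair_id"]
        if pid not in seen_pairs:
            pair = DrugPair(pid, r["psychotropic"], r["covid_drug"], r["psychotropic_class"])
            seen_pairs[pid] = pair
            pairs.append(pair)

    if resources is None:
        found = list(dict.fromkeys(df["resource_id"]))
        canonical = [r for r in CANONICAL_RESOURCES if r in found]
        extra = sorted(set(found) - set(canonical))
        resources = canonical + extra
    resources = list(resources)

    entries: list[ResourceEntry] = []
    seen_entries: set[tuple[str, str]] = set()
    for _, r in df.iterrows():
        key = (r["pair_id"], r["resource_id"])
        seen_entries.add(key)
        entries.append(
            ResourceEntry(
                pair_id=r["pair_id"],
                resource_id=r["resource_id"],
                present=r["present"] == "1",
                **{flag: r[flag] == "1" for flag in COMPONENT_FLAGS},
                severity_raw=r["severity_raw"],
                action_raw=r["action_raw"],
            )
        )
    # materialize scope misses for combinations absent from the file
    for p in pairs:
        for rid in resources:
            if (p.pair_id, rid) not in seen_entries:
                entries.append(ResourceEntry(p.pair_id, rid, present=False))

    return EvidenceMatrix(pairs, resources, entries)


def entry_with(entry: ResourceEntry, **changes) -> ResourceEntry:
    """Functional update helper for frozen entries."""
    return replace(entry, **changes)
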