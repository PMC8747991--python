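"""Severity / course-of-action vocabulary harmonization.

Every compendium grades interaction severity on its own scale (numeric
levels, letter risk ratings, verbal labels).  This module maps each raw
label onto the shared three-level severity scale and four-level action
taxonomy via a :class:`~ddi_concord.core.SeverityMap`.  Matching is exact
after trimming and case-folding — a label outside the map raises
:class:`StandardizationError` rather than being coerced silently.
"""

from __future__ import annotations

from importlib import resources as importlib_resources

import yaml

from .core import (
    ActionCategory,
    EvidenceMatrix,
    ResourceEntry,
    SeverityCategory,
    SeverityMap,
    entry_with,
)

__all__ = [
    "StandardizationError",
    "load_severity_map",
    "default_severity_map",
    "standardize_severity",
    "standardize_action",
    "apply_standardization",
]


class StandardizationError(ValueError):
    """An unknown raw label for a given resource."""


def load_severity_map(path) -> SeverityMap:
    """Load a severity/action map from a YAML file (see shipped default)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return SeverityMap(severity=raw["severity"], action=raw["action"])


def default_severity_map() -> SeverityMap:
    """The package's built-in map covering the six canonical resources."""
    ref = importlib_resources.files("ddi_concord") / "data" / "severity_map.yaml"
    with importlib_resources.as_file(ref) as path:
        return load_severity_map(path)


def standardize_severity(
    raw: str, resource_id: str, smap: SeverityMap
) -> SeverityCategory:
    """Map a resource's native severity label to the harmonized scale.

    Empty input (no usable rating) maps to ``unrated``.
    """
    label = raw.strip()
    if not label:
        return SeverityCategory.UNRATED
    if resource_id not in smap.severity:
        raise StandardizationError(f"no severity vocabulary for resource '{resource_id}'")
    try:
        return smap.severity[resource_id][label.casefold()]
    except KeyError:
        raise StandardizationError(
            f"unknown severity label '{raw}' for resource '{resource_id}'"
        ) from None


def standardize_action(raw: str, smap: SeverityMap) -> ActionCategory:
    """Map a raw course-of-action label to the four-level action taxonomy."""
    label = raw.strip()
    if not label:
        return ActionCategory.UNRATED
    try:
        return smap.action[label.casefold()]
    except KeyError:
        raise StandardizationError(f"unknown action label '{raw}'") from None


def _standardize_entry(entry: ResourceEntry, smap: SeverityMap) -> ResourceEntry:
    severity = SeverityCategory.UNRATED
    action = ActionCategory.UNRATED
    if entry.present and entry.has_severity:
        severity = standardize_severity(entry.severity_raw, entry.resource_id, smap)
    if entry.present and entry.has_course_of_action:
        action = standardize_action(entry.action_raw, smap)
    if severity is entry.severity_std and action is entry.action_std:
        return entry
    return entry_with(entry, severity_std=severity, action_std=action)


def apply_standardization(matrix: EvidenceMatrix, smap: SeverityMap) -> EvidenceMatrix:
    """Populate ``severity_std`` / ``action_std`` across the whole matrix.

    Idempotent; all other fields are left unchanged.  Raises
    :class:`StandardizationError` with the offending (pair, resource)
    coordinates on the first unknown label.
    """
    out = []
    for e in matrix.entries:
        try:
            out.append(_standardize_entry(e, smap))
        except StandardizationError as exc:
            raise StandardizationError(
                f"pair {e.pair_id}, resource {e.resource_id}: {exc}"
            ) from None
    return matrix.replace_entries(out)
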