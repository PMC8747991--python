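"""Harmonize native severity/action labels onto the shared scales.

Each compendium grades interaction severity in its own vocabulary (PEPID
numeric levels, UpToDate letter ratings, verbal labels elsewhere).  The
default map collapses them to {minor, moderate, major_contraindicated} and
the four-level action taxonomy.
"""

from ddi_concord import default_severity_map, standardize_action, standardize_severity

smap = default_severity_map()

examples = [
    ("pepid", "5"),
    ("pepid", "3"),
    ("uptodate", "C"),
    ("uptodate", "X"),
    ("micromedex", "Contraindicated"),
    ("webmd", "Don't use together"),
    ("medscape", "Monitor closely"),
]
print("native severity label -> harmonized category")
for resource, raw in examples:
    cat = standardize_severity(raw, resource, smap)
    print(f"  {resource:<11} {raw!r:<22} -> {cat.value}")

print("\ncourse-of-action label -> harmonized category")
for raw in ("Avoid combination", "Monitor therapy", "Consider therapy modification"):
    print(f"  {raw!r:<35} -> {standardize_action(raw, smap).value}")

# Unknown labels fail loudly: silent mis-mapping would corrupt every
# downstream consistency and agreement score.
try:
    standardize_severity("catastrophic", "micromedex", smap)
except Exception as exc:
    print(f"\nunknown label raises: {exc}")
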