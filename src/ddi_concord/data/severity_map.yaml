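# Default harmonization of each resource's native severity vocabulary onto
# {minor, moderate, major_contraindicated}, plus a shared course-of-action
# vocabulary.  Lookups are case-insensitive after whitespace trimming.
#
# PEPID uses numeric severity levels: 3 = moderate, 4 = significant and
# 5 = life-threatening collapse to major/contraindicated; levels 1-2, when
# encountered, are sub-moderate (minor).  UpToDate uses letter risk ratings
# (B = no action needed, C = monitor therapy, D = consider modification,
# X = avoid combination).
severity:
  pepid:
    "1": minor
    "2": minor
    "3": moderate
    "4": major_contraindicated
    "5": major_contraindicated
  micromedex:
    "Minor": minor
    "Moderate": moderate
    "Major": major_contraindicated
    "Contraindicated": major_contraindicated
  uptodate:
    "B": minor
    "C": moderate
    "D": major_contraindicated
    "X": major_contraindicated
  drugscom:
    "Minor": minor
    "Moderate": moderate
    "Major": major_contraindicated
  medscape:
    "Minor": minor
    "Monitor closely": moderate
    "Serious": major_contraindicated
    "Serious - Use Alternative": major_contraindicated
  webmd:
    "Minor": minor
    "Monitor closely": moderate
    "Serious": major_contraindicated
    "Don't use together": major_contraindicated
    "Don’t use together": major_contraindicated
action:
  "No action required": no_action
  "No action needed": no_action
  "Monitor": monitor
  "Monitoring": monitor
  "Monitor therapy": monitor
  "Monitor closely": monitor
  "Modify dosage": modify_dosage
  "Modifying the dosage": modify_dosage
  "Consider therapy modification": modify_dosage
  "Adjust dose": modify_dosage
  "Avoid": avoid
  "Avoid combination": avoid
  "Do not use together": avoid
  "Don't use together": avoid
  "Don’t use together": avoid
  "Use alternative": avoid
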