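"""Score a single respondent's two diagrams by hand.

Builds one participant who placed five figures on the emotional canvas and
the same five on the physical canvas, then prints the composition scores
(attachment strengths, clear-cut figures, primary set) and morphology
(hierarchy class, centralities, density).
"""

import math

from whmt import (
    DiagramCalibration,
    ParticipantRecord,
    Placement,
    Thresholds,
    score_composition,
    score_morphology,
)

cal_e = DiagramCalibration.emotional_default()
cal_p = DiagramCalibration.physical_default()
th = Thresholds()


def at(role, r_px, kind, angle=0.0):
    return Placement(role, r_px * math.cos(angle), r_px * math.sin(angle), kind)


rec = ParticipantRecord(
    participant_id="demo",
    age=36,
    gender="female",
    romantic_status="married_engaged",
    parental_status="child",
    emotional=[
        at("romantic_partner", 20, "emotional"),   # well inside the inner circle
        at("mother", 55, "emotional"),             # also clear-cut (<= 60 px)
        at("friend", 140, "emotional"),
        at("sibling", 300, "emotional"),
        at("father", 420, "emotional"),
    ],
    physical=[
        at("romantic_partner", 30, "physical"),              # ~1 mile away
        at("mother", 233, "physical", angle=math.pi / 2),    # 10 miles due south
        at("friend", 350, "physical", angle=-math.pi / 2),   # ~130 miles north
        at("sibling", 466, "physical", angle=math.pi),       # 250 miles west
        at("father", 600, "physical"),                       # ~393 miles east
    ],
)

comp = score_composition(rec, cal_e, th)
morph = score_morphology(rec, cal_e, cal_p, th)

print("strengths (px, lower = stronger):")
for role, s in sorted(comp.strengths.items(), key=lambda kv: kv[1]):
    print(f"  {role:17s} {s:6.1f}")
print(f"clear-cut figures : {comp.n_clear_cut} {comp.clear_cut_roles}")
print(f"primary set       : {comp.primary_set}")
print(f"hierarchy class   : {morph.hierarchy_class} (binary {morph.hierarchy_binary})")
print(f"attachment centrality : {morph.attachment_centrality:7.1f} px")
print(f"physical centrality   : {morph.physical_centrality:7.1f} miles")
print(f"physical density      : {morph.physical_density:7.1f} miles")

# The partner and mother sit at/inside the 60 px inner circle, so two
# figures are clear-cut.  The partner-mother gap (35 px) exceeds the 15 px
# primary tolerance, so only the partner is primary, and exceeds the 18 px
# icon radius, so the network is monotropic.  Physical centrality averages
# home-to-figure miles; density averages the 10 between-figure distances.
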