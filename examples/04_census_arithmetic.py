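"""Cohort census on a fixture with the published survey composition.

Builds presence rows for 4,400 genomes (3,411 MEP-only; 541 MVA-only; 83
with both pathways; 136 with neither; 229 non-canonical-MEP candidates),
classifies them, and prints the class percentages, the candidate
missing-gene breakdown, and the MTA-shunt fractions.
"""

from mepsurvey import (
    ALL_ROLES,
    candidate_breakdown,
    class_census,
    classify,
    shunt_census,
)

MEP = ("Dxs", "DxrI", "IspD", "IspE", "IspF", "IspG", "IspH")
no_dxs = tuple(r for r in MEP if r != "Dxs")

composition = [
    (3411, MEP),
    (541, ("HMGS", "MVK", "IspE")),
    (83, MEP + ("HMGS", "MVK")),
    (136, ()),
    (172, no_dxs),
    (4, no_dxs + ("MTXu5P_methylsulfurase",)),
    (5, no_dxs + ("MTXu5P_methylsulfurase", "MTRu1P_isomerase")),
    (1, tuple(r for r in MEP if r != "IspG")),
    (2, tuple(r for r in MEP if r != "IspH")),
    (45, tuple(r for r in MEP if r not in ("Dxs", "IspE"))),
]

statuses = []
for n, present in composition:
    for _ in range(n):
        i = len(statuses)
        statuses.append(classify(f"g{i}", {r: r in present for r in ALL_ROLES}))

print(f"cohort of {len(statuses)} genomes\n")
print("genotype class census:")
for cls, d in class_census(statuses).items():
    print(f"  {cls:10s} {d['count']:5d}  {d['percent']}%")

print("\ncandidate missing-gene breakdown:")
for name, d in candidate_breakdown(statuses).items():
    print(f"  {name:10s} {d['count']:4d}  {d['percent']}%")

print("\nMTA-shunt carriage among Dxs-only candidates:")
sc = shunt_census(statuses)
print(f"  methylsulfurase only: {sc['methylsulfurase_only_count']} "
      f"({sc['methylsulfurase_only_percent']}% of {sc['denominator']})")
print(f"  both shunt enzymes:   {sc['both_shunt_count']} "
      f"({sc['both_shunt_percent']}% of {sc['denominator']})")
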