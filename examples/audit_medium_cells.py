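"""Audit the fixture's medium-positivity resolutions exhaustively.

Six marker scores in the 25-tumor cohort fall in the ambiguous 21–50%
bin. Their binary high/low resolutions are not derivable from the bin
alone, so the fixture carries them explicitly; this script re-derives
them by enumerating all 2^6 = 64 assignments and keeping those that
reproduce every occurrence pair (n(A), n(A∧B)) of the published
14-rule panel. Exactly one assignment survives.
"""

from hyporules import load_fixture, medium_cells, resolve_by_consistency
from hyporules.reference import reference_count_pairs

cohort = load_fixture()
cells = medium_cells(cohort)
matches = resolve_by_consistency(cohort, reference_count_pairs())

print(f"medium cells: {len(cells)}; assignments searched: {2 ** len(cells)}; "
      f"consistent: {len(matches)}")
for assignment in matches:
    for (tumor_id, marker), state in sorted(assignment.items()):
        print(f"  tumor {tumor_id:>2}  {marker:<6} -> {state}")
print(
    "\nA unique consistent assignment means the published occurrence counts\n"
    "pin down the binary state of every ambiguous score, so the packaged\n"
    "fixture's resolutions are forced, not guessed."
)
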