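"""Rank compounds by the composite drug activity score.

Combines on-target spheroid DSS3, off-target DSS3, 2D toxicities and binding
affinity into score = DSS_t^2/DSS_o * tox_o/tox_t * 1/Kd[uM], then ranks
within each chemical series.
"""

from covscreen.scoring import composite_score, rank_compounds

panel = [
    # compound, DSS3 on-target, DSS3 off-target, tox off, tox on, Kd uM, series
    ("1", 22.0, 11.0, 4.0, 9.0, 0.87, "formyl"),
    ("2", 18.0, 14.0, 7.0, 12.0, 0.23, "formyl"),
    ("3", 15.0, 12.0, 6.0, 10.0, 0.25, "formyl"),
    ("8", 16.0, 13.0, 5.0, 7.0, 3.1, "plain"),
    ("9", 17.0, 14.0, 6.0, 8.0, 1.44, "plain"),
    ("11", 19.0, 21.0, 5.0, 6.0, 0.81, "plain"),
]

scores = [composite_score(c, dt, do, to, tt, kd, series=s)
          for c, dt, do, to, tt, kd, s in panel]
print(f"{'cmpd':>5} {'series':>7} {'score':>8}")
for s in rank_compounds(scores, top_n=3):
    print(f"{s.compound:>5} {s.series:>7} {s.score:>8.1f}")
print()
print("Higher scores favour potent, on-target-selective, low-toxicity, high-")
print("affinity compounds; ties break toward lower Kd, then compound id.")
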