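"""Candidate-gene prioritization on the bundled evidence fixture.

Each gene is scored additively over variant-consequence flags (a deleterious
missense in a functional domain weighs most), per-tissue differential
expression between the founder lines, and pathway membership. The packaged
default weights reproduce the published candidate ordering for the two
body-weight QTLs (Gpt > Cbx6 > Apol6 = Apol8 on chr15; Trap1 = Rrn3 > Mapk1
on chr16).
"""

from ailqtl import cards_from_fixture

cards = cards_from_fixture()
print(f"{'rank':>4} {'gene':8} {'score':>5}  evidence")
for c in cards:
    evidence = [k for k, v in c.flags.items() if v]
    if c.de_adipose:
        evidence.append("DE adipose")
    if c.de_liver:
        evidence.append("DE liver")
    if not (c.expr_measured_adipose or c.expr_measured_liver):
        evidence.append("expression not determined")
    print(f"{c.rank:>4} {c.gene_id:8} {c.score:>5.1f}  {', '.join(evidence)}")
print("\nTied scores share a rank; ties order alphabetically for "
      "determinism. Weights are configurable via ScoringConfig.")
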