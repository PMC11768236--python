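"""Clinical-priority scoring of the published canakinumab signal list.

Scores each of the 71 bundled signal PTs on the five-item rubric
(case count, ROR, mortality proportion, EMA DME/IME listing, evidence
grade) and prints the weak/moderate/strong band totals plus a few rows.
"""

from faersignal.datasets import canakinumab_pt_signals
from faersignal.priority import PTAttributes, band_counts, score_pt

df = canakinumab_pt_signals()
scores = [
    score_pt(PTAttributes(
        r["pt"], int(r["cases"]), float(r["ror"]), int(r["deaths"]),
        dme=bool(r["dme"]), ime=bool(r["ime"]), evidence=r["evidence"],
    ))
    for r in df.to_dict("records")
]

weak, moderate, strong = band_counts(scores)
print(f"{len(scores)} signal PTs -> {weak} weak, {moderate} moderate, {strong} strong")

print("\nexample scores (items: cases, ROR, mortality, DME/IME, evidence):")
for s in scores:
    if s.pt in {"Deafness", "Pneumonia", "Brain oedema", "Blood fibrinogen decreased"}:
        print(f"  {s.pt:28s} items={s.item_scores} total={s.total} band={s.band}")
# A total of 0-4 is a weak priority, 5-7 moderate, 8-10 strong; e.g.
# pneumonia reaches 6 (many cases, ROR in [2,5), IME-listed, strong
# clinical evidence) while deafness stays weak at 4 despite its DME listing.
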