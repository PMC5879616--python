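"""Summary arithmetic over published gene tallies.

Printed per-type counts from a repeated-dehydration study of switchgrass are
used as inputs; the summary operations derive every percentage with its
explicit denominator, and the Venn arithmetic recovers the union sizes
behind the printed overlap percentages.
"""

from memtype.memory_classify import SummaryTable, percent, venn_from_sizes

# memory genes by type, plus the two non-memory types (counts as printed)
summary = SummaryTable({"[+/+]": 93, "[-/-]": 113, "[+/-]": 381, "[-/+]": 154,
                        "[+/=]": 337, "[-/=]": 488})
print(f"memory genes: {summary.total_memory}")
print(f"response genes (non-'=' first call): {summary.total_response}")
print("memory-type shares (%):", summary.memory_type_shares())
print(f"memory / response: {summary.memory_of_response_percent()}%")

# up-regulated gene sets of the two stresses: 811 (D1), 3679 (D2), 356 common
up = venn_from_sizes(811, 3679, 356)
print(f"\nup-regulated union: {up['union']}")
print(f"[+/+] of common up-set: {percent(93, up['common'], 2)}%")
print(f"[+/+] of all up-regulated: {percent(93, up['union'], 1)}%")
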