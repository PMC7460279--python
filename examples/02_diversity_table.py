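"""Per-breed diversity panel: MAF, observed/expected heterozygosity, F_HOM.

F_HOM compares each animal's observed homozygote count with its
Hardy-Weinberg expectation from within-breed allele frequencies; breeds
kept at small census sizes show strongly positive values, outbred
commercial stocks sit near (or just below) zero.
"""

from galdiv import apply_qc, diversity_table, make_study_fixture

ds, _ = make_study_fixture(seed=7)
ds, _ = apply_qc(ds)

table = diversity_table(ds)
show = table.sort_values("fhom_mean", ascending=False)
print(show.head(5).round(3).to_string(index=False))
print("...")
print(show.tail(4).round(3).to_string(index=False))
# Highest rows: the Siciliana-like breed (configured autozygosity 0.6).
# Lowest rows: the four commercial stocks, with He/Ho near 0.3 and F_HOM
# near zero.
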