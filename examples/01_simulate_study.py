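"""Generate a synthetic five-treatment fertilization study.

Builds the default design (CK, N, NS, NSM, NB x 3 replicate plots):
nematode genus counts, a 16S OTU table with taxonomy, qPCR copy
numbers, soil chemistry and raw incubation/titration records, together
with the serialized ground truth used by the recovery tests.
"""

from soilfoodweb import generate_dataset

ds = generate_dataset(seed=42)

print("samples:", list(ds.nematode_counts.index))
print("\nnematode counts (first 3 samples, first 5 genera):")
print(ds.nematode_counts.iloc[:3, :5])
print("\nOTU table shape:", ds.otu_table.shape,
      "| row depth:", int(ds.otu_table.iloc[0].sum()))
print("\nground truth (first rows):")
print(ds.truth.per_sample[["treatment", "p_Ba", "growth", "respiration",
                           "cue", "cm"]].head(3).round(3))
# p_Ba is the true bacterivore share of the community; growth/respiration
# are the true microbial rates (ng C per g soil per h) the incubation
# records were back-solved from, and cue = growth/(growth+respiration).

ds.write("scratch/example_study")
print("\nwrote all tables to scratch/example_study/")
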