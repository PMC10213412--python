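"""OTU-table community metrics: rarefaction, phylum profiles, Bray-Curtis.

Rarefies every sample to a common depth (multivariate hypergeometric
subsampling), aggregates to phylum relative abundances and computes the
Bray-Curtis dissimilarity matrix that feeds ordination.
"""

import numpy as np

from soilfoodweb import (
    bray_curtis, generate_dataset, phylum_relative_abundance, rarefy,
)

ds = generate_dataset(seed=42)
depth = int(ds.otu_table.sum(axis=1).min())
rare = rarefy(ds.otu_table, depth, seed=0)
print(f"rarefied {len(rare)} samples to depth {depth}")

phyla = phylum_relative_abundance(rare, ds.otu_taxonomy)
print("\nmean phylum relative abundance (top 5):")
print((100 * phyla.mean().sort_values(ascending=False).head(5)).round(1))
# percentages of reads per phylum, averaged over samples

bc = bray_curtis(rare)
off = bc.to_numpy()[np.triu_indices(len(bc), k=1)]
print("\nBray-Curtis dissimilarities: mean %.3f, range %.3f-%.3f"
      % (off.mean(), off.min(), off.max()))
# 0 = identical composition, 1 = no shared OTUs
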