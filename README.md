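# soilfoodweb

Quantitative analysis of soil food webs and microbial carbon cycling for
fertilization/amendment experiments: nematode faunal-analysis indices from
guild-classified genus counts, microbial growth–respiration physiology from
¹⁸O-water incubations, carbon mineralization from alkali-trap titrations,
16S amplicon community metrics, and the statistics that link them. A
synthetic-data generator produces complete studies with exactly recoverable
ground truth, so every step of the chain can be verified end to end.

The package is written for soil ecologists and microbiologists who have a
nematode count table (individuals per 100 g dry soil), an OTU table with
qPCR 16S copy numbers, raw incubation/titration records, and soil chemistry
— and want the standard indicator chain computed reproducibly.

## The quantities computed

**Nematode faunal analysis.** Genera are classified into trophic guilds —
bacterivores (Ba), fungivores (Fu), plant parasites (Pp) and
omnivores–predators (OP, split into Om/Ca) — each with a colonizer–persister
score c-p ∈ {1..5}. With functional guilds Ba1, Fu2, … and the weighted
components e = 3.2·Ba1 + 0.8·Fu2, b = 0.8·(Ba2 + Fu2), s = Σ w(cp)·count
over the structural guilds (w = 0.8/1.8/3.2/5.0 for cp 2/3/4/5):

- Shannon–Wiener H = −Σ pᵢ ln pᵢ (nats)
- maturity index MI = Σ cpᵢ pᵢ over free-living taxa
- channel index CI = 100·0.8·Fu2 / (3.2·Ba1 + 0.8·Fu2)
- enrichment index EI = 100·e/(e+b); structure index SI = 100·s/(s+b)
- functional dispersion FDis (abundance-weighted mean Gower distance to the
  community trait centroid)
- predation pressure = bacterivores / 16S copies (common per-g basis)
- optional per-guild metabolic footprints Σ Nₜ(0.1·Wₜ/cpₜ + 0.273·Wₜ^0.75)

Zero-denominator indices are reported as missing values, never 0.

**¹⁸O physiology.** From one incubation record (oxygen in extracted DNA
O_total, atom% label and excess, dry weight DW, time t, headspace ΔCO₂ and
volume V, MBC, preculture DNA):

    DNA_produced = O_total·(at%ₑ/100)·(100/at%ₗ)·(100/31.21)        [µg]
    Growth      = fDNA·DNA_produced·1000/(DW·t),  fDNA = MBC/DNA    [ng C g⁻¹ h⁻¹]
    Respiration = ΔCO₂/(22.4·DW·t)·12.01·V·1000                      [ng C g⁻¹ h⁻¹]
    qCO₂ = Respiration/MBC,  CUE = Growth/(Growth+Respiration)

**Carbon mineralization** from NaOH-trap back titration:
CM = c_HCl·(V₀−V₁)·22/0.1 mg CO₂ per kg soil (0.1 kg = the standard 100 g jar).

**Community metrics.** Seeded rarefaction without replacement, phylum
relative abundances, Bray–Curtis dissimilarity BC = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ).

**Statistics.** One-way ANOVA with Tukey-HSD compact letter displays;
Spearman correlation matrices; adjusted-R² variance partitioning of a
response table between two predictor sets (fractions a/b/c/d, Ezekiel
adjustment); permutation-based environmental-vector fitting (envfit) onto
ordination scores with p = (1+#{r²_perm ≥ r²})/(n_perm+1).

## Worked example

```python
from soilfoodweb import IncubationRecord, process_incubation

rec = IncubationRecord(
    O_total=20.0, at_label=20.0, at_excess=0.05, DW=1.0, t=24.0,
    dCO2=90.0, V=0.05, MBC=300.0, DNA_preculture=8.0,
)
print(process_incubation(rec))
```

prints (rounded)

```
DNA_produced 0.1602   fDNA 37.5000
growth       250.3204 respiration 100.5301
qCO2         0.3351   CUE 0.7135
```

i.e. 0.16 µg of new DNA over 24 h converts (via fDNA = 300/8 µg MBC per µg
DNA) to a growth rate of 250 ng C g⁻¹ h⁻¹; the 90 ppm CO₂ rise in the 50 mL
headspace gives 101 ng C g⁻¹ h⁻¹ respiration, hence CUE ≈ 0.71 — the
community retains ~71 % of the carbon it processes — and a metabolic
quotient of 0.34 ng C per µg biomass C per hour.

The scripts in `examples/` walk through each capability (simulation,
indices, physiology, community metrics, statistics, full pipeline) and
print annotated output; `soilfoodweb --help` exposes the same stages as
shell subcommands (`simulate`, `indices`, `physiology`, `community`,
`stats`, `run-all`).

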