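"""Synthetic soil food-web study datasets with exactly recoverable truth.

Emulates a five-treatment fertilization field trial (CK unfertilized; N
mineral fertilizer; NS +straw; NSM +straw and manure; NB +straw biochar),
three replicate plots each: nematode genus counts, a 16S OTU table with
phylum taxonomy, qPCR 16S copy numbers, soil chemistry, and raw
18O-incubation plus alkali-titration records.

Every record is constructed by algebraic inversion of the analysis
formulas from drawn true rates, so the downstream pipeline recovers the
ground truth exactly in noise-free mode and to sampling error otherwise.
Community counts follow a Dirichlet-multinomial: a per-sample composition
is drawn from a Dirichlet centred on the expected proportions (the
``dispersion`` concentration scales the compositional noise; ``inf``
means the expectation is used exactly), and counts are multinomial at the
drawn depth.  Default treatment effects encode the qualitative ordering
reported for such amendments (total nematodes, bacterivores and 16S copy
numbers highest under straw+manure; mineral-only fertilizer lowest among
the fertilized treatments; a relatively fungal-dominated channel under CK
and N) without asserting any particular field's numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .physiology import (
    CARBON_MOLAR_MASS,
    CO2_EQUIVALENT_MASS,
    DNA_OXYGEN_PERCENT,
    MOLAR_VOLUME_STP,
)
from .traits import TraitReference, load_default_traits

DEFAULT_TREATMENTS = ("CK", "N", "NS", "NSM", "NB")

#: Mean guild shares of the simulated baseline community.
DEFAULT_GUILD_PROPORTIONS = {"Ba": 0.476, "Fu": 0.257, "Pp": 0.133, "OP": 0.134}

#: Phylum pool and baseline relative abundances for the OTU generator.
DEFAULT_PHYLUM_PROPORTIONS = {
    "Chloroflexi": 0.305,
    "Proteobacteria": 0.238,
    "Acidobacteria": 0.151,
    "Actinobacteria": 0.140,
    "Firmicutes": 0.050,
    "Bacteroidetes": 0.040,
    "Gemmatimonadetes": 0.030,
    "Planctomycetes": 0.025,
    "Verrucomicrobia": 0.021,
    "Myxococcota": 0.000,
}


@dataclass
class TreatmentEffect:
    """Multiplicative effects of one treatment on the baseline."""

    guild: dict = field(default_factory=dict)  # per-guild abundance
    phylum: dict = field(default_factory=dict)  # per-phylum abundance
    total: float = 1.0  # total nematode count
    copies: float = 1.0  # 16S copies per g
    growth: float = 1.0  # true growth rate
    respiration: float = 1.0  # true respiration rate
    cm: float = 1.0  # true C mineralization
    mbc: float = 1.0  # microbial biomass C

    def __post_init__(self):
        for m in (self.total, self.copies, self.growth,
                  self.respiration, self.cm, self.mbc,
                  *self.guild.values(), *self.phylum.values()):
            if m <= 0:
                raise ValueError("effect multipliers must be positive")


def default_treatment_effects() -> dict:
    return {
        "CK": TreatmentEffect(),
        "N": TreatmentEffect(
            guild={"Ba": 0.90, "Fu": 1.20, "Pp": 1.10, "OP": 0.80},
            phylum={"Proteobacteria": 0.95},
            total=1.10, copies=0.95, growth=1.10,
            respiration=0.95, cm=0.95, mbc=0.95,
        ),
        "NS": TreatmentEffect(
            guild={"Ba": 1.20, "Fu": 0.90, "Pp": 0.95, "OP": 1.10},
            phylum={"Proteobacteria": 1.25, "Actinobacteria": 1.20},
            total=1.35, copies=1.25, growth=1.10,
            respiration=1.10, cm=1.10, mbc=1.20,
        ),
        "NSM": TreatmentEffect(
            guild={"Ba": 1.45, "Fu": 0.80, "Pp": 0.90, "OP": 1.30},
            phylum={"Proteobacteria": 1.35, "Actinobacteria": 1.25},
            total=1.80, copies=1.50, growth=1.45,
            respiration=1.15, cm=1.35, mbc=1.40,
        ),
        "NB": TreatmentEffect(
            guild={"Ba": 1.10, "Fu": 1.00, "Pp": 0.95, "OP": 1.05},
            phylum={"Chloroflexi": 1.20, "Acidobacteria": 1.15},
            total=1.25, copies=1.30, growth=1.05,
            respiration=0.90, cm=1.05, mbc=1.25,
        ),
    }


def default_chemistry_means() -> dict:
    """Per-treatment soil-property means (units in comments)."""
    return {
        #        pH    SOC    TN   TP   TK    CEC   MBC
        # units: -     g/kg  g/kg g/kg g/kg cmol/kg ug/g
        "CK": {"pH": 4.5, "SOC": 9.5, "TN": 1.05, "TP": 0.52,
               "TK": 13.0, "CEC": 10.5, "MBC": 280.0},
        "N": {"pH": 4.4, "SOC": 10.0, "TN": 1.20, "TP": 0.60,
              "TK": 13.2, "CEC": 10.4, "MBC": 266.0},
        "NS": {"pH": 4.5, "SOC": 13.5, "TN": 1.45, "TP": 0.72,
               "TK": 13.1, "CEC": 10.8, "MBC": 336.0},
        "NSM": {"pH": 4.6, "SOC": 14.5, "TN": 1.70, "TP": 0.88,
                "TK": 13.3, "CEC": 11.0, "MBC": 392.0},
        "NB": {"pH": 4.8, "SOC": 14.0, "TN": 1.40, "TP": 0.68,
               "TK": 13.2, "CEC": 11.2, "MBC": 350.0},
    }


DEFAULT_CHEMISTRY_SDS = {
    "pH": 0.08, "SOC": 0.8, "TN": 0.08, "TP": 0.05,
    "TK": 0.5, "CEC": 0.5, "MBC": 20.0,
}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study generator.

    ``dispersion`` is the Dirichlet concentration of the compositional
    noise (``math.inf`` = compositions equal their expectation);
    ``noise_free`` additionally zeroes every measurement noise term and
    replaces count draws by exact expected counts, making the whole
    pipeline an exact round trip.
    """

    seed: int = 0
    treatments: tuple = DEFAULT_TREATMENTS
    replicates_per_treatment: int = 3
    guild_base_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_GUILD_PROPORTIONS)
    )
    treatment_effects: dict = field(default_factory=default_treatment_effects)
    taxa_per_guild: int = 4
    nematode_depth: float = 300.0  # expected individuals per 100 g soil
    otu_count: int = 150
    otu_depth: int = 30000
    dispersion: float = 200.0
    noise_free: bool = False
    phylum_base_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_PHYLUM_PROPORTIONS)
    )
    chemistry_means: dict = field(default_factory=default_chemistry_means)
    chemistry_sds: dict = field(
        default_factory=lambda: dict(DEFAULT_CHEMISTRY_SDS)
    )
    copies_base: float = 1.2e8  # 16S copies per g dry soil
    copies_cv: float = 0.10
    growth_base: float = 60.0  # ng C / g / h
    respiration_base: float = 90.0  # ng C / g / h
    rate_cv: float = 0.08
    cm_base: float = 800.0  # mg CO2 / kg soil / incubation

    def __post_init__(self):
        s = sum(self.guild_base_proportions.values())
        if abs(s - 1.0) > 1e-12:
            raise ValueError("guild_base_proportions must sum to 1")
        if set(self.guild_base_proportions) != {"Ba", "Fu", "Pp", "OP"}:
            raise ValueError("guild proportions must cover Ba, Fu, Pp, OP")
        if self.replicates_per_treatment < 2:
            raise ValueError("need >= 2 replicates per treatment")
        if self.taxa_per_guild < 1:
            raise ValueError("taxa_per_guild must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive (inf allowed)")
        missing = [t for t in self.treatments if t not in self.treatment_effects]
        if missing:
            raise ValueError(f"treatment effects missing for: {missing}")

    @property
    def sample_ids(self) -> list:
        return [
            f"{t}-{r + 1}"
            for t in self.treatments
            for r in range(self.replicates_per_treatment)
        ]

    @property
    def sample_treatments(self) -> list:
        return [
            t
            for t in self.treatments
            for _ in range(self.replicates_per_treatment)
        ]

    def noise_free_copy(self) -> "GeneratorConfig":
        return replace(self, noise_free=True, dispersion=math.inf)


# ---------------------------------------------------------------------------
# Trait reference
# ---------------------------------------------------------------------------

def generate_trait_reference(config: GeneratorConfig) -> TraitReference:
    """Draw a study trait reference from the shipped genus pool.

    Picks ``taxa_per_guild`` genera per trophic guild (Om and Ca pooled
    as OP), always keeping Ba c-p 1, Ba c-p 2 and Fu c-p 2 representatives
    so the enrichment/channel indices are well defined.
    """
    pool = load_default_traits().table.reset_index()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    trophic = pool["guild"].replace({"Om": "OP", "Ca": "OP"})

    chosen: list[str] = []
    # Guaranteed anchors for index definedness.
    anchors = {
        ("Ba", 1): None, ("Ba", 2): None, ("Fu", 2): None,
    }
    for (g, cp) in list(anchors):
        cand = pool[(pool["guild"] == g) & (pool["cp"] == cp)]
        anchors[(g, cp)] = cand.iloc[rng.integers(len(cand))]["genus"]

    for guild in ("Ba", "Fu", "Pp", "OP"):
        cand = pool.loc[trophic == guild, "genus"].tolist()
        pre = [a for (g, _), a in anchors.items() if g == guild]
        pre = list(dict.fromkeys(pre))[: config.taxa_per_guild]
        remaining = [g for g in cand if g not in pre]
        k = min(config.taxa_per_guild - len(pre), len(remaining))
        extra = (
            list(rng.choice(remaining, size=k, replace=False)) if k > 0 else []
        )
        chosen.extend(pre + extra)
    return load_default_traits().subset(chosen)


# ---------------------------------------------------------------------------
# Community tables
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Ground truth serialized alongside generated data.

    ``per_sample`` has one row per sample: treatment, true guild
    proportions, expected total nematode abundance, true growth and
    respiration rates (ng C/g/h), true CUE and qCO2, true 16S copies per
    g, true MBC and true C mineralization.
    """

    per_sample: pd.DataFrame

    def to_csv(self, path) -> None:
        self.per_sample.to_csv(path, index=True, index_label="sample")

    @classmethod
    def from_csv(cls, path) -> "SyntheticTruth":
        return cls(pd.read_csv(path, index_col="sample"))


def _expected_guild_proportions(config: GeneratorConfig, treatment: str) -> dict:
    eff = config.treatment_effects[treatment]
    raw = {
        g: config.guild_base_proportions[g] * eff.guild.get(g, 1.0)
        for g in ("Ba", "Fu", "Pp", "OP")
    }
    s = sum(raw.values())
    return {g: v / s for g, v in raw.items()}


def generate_community_tables(
    config: GeneratorConfig, traits: TraitReference
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series, SyntheticTruth]:
    """Nematode counts, OTU table, taxonomy, 16S copies, and the truth.

    Returns ``(nematode_counts, otu_table, otu_taxonomy, copy_numbers,
    truth)``.  In noise-free mode count tables hold exact expected counts
    (real-valued) instead of draws.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    genera = list(traits.genera)
    trophic = np.array([traits.trophic_guild(g) for g in genera])

    # Fixed within-guild genus weights, drawn once per dataset so the
    # guild-level truth is unambiguous.
    within: dict[str, np.ndarray] = {}
    for g in ("Ba", "Fu", "Pp", "OP"):
        k = int((trophic == g).sum())
        if k == 0:
            raise ValueError(f"trait reference has no genus for guild {g}")
        if config.noise_free:
            w = np.ones(k) / k
        else:
            w = rng.dirichlet(np.full(k, 5.0))
        within[g] = w

    phyla = list(config.phylum_base_proportions)
    base_ph = np.array(
        [config.phylum_base_proportions[p] for p in phyla], dtype=float
    )
    base_ph = np.clip(base_ph, 1e-4, None)
    base_ph = base_ph / base_ph.sum()
    otu_ids = [f"OTU{i + 1:04d}" for i in range(config.otu_count)]
    otu_phyla = np.array(
        [phyla[i % len(phyla)] for i in range(config.otu_count)]
    )
    # Within-phylum OTU weights, fixed per dataset.
    otu_w = np.empty(config.otu_count)
    for p in phyla:
        mask = otu_phyla == p
        k = int(mask.sum())
        if k == 0:
            continue
        otu_w[mask] = (
            np.ones(k) / k if config.noise_free else rng.dirichlet(np.full(k, 2.0))
        )

    nem_rows, otu_rows, copies_out, truth_rows = [], [], [], []
    for sample, treatment in zip(config.sample_ids, config.sample_treatments):
        eff = config.treatment_effects[treatment]
        p_guild = _expected_guild_proportions(config, treatment)
        p_taxa = np.empty(len(genera))
        for g in ("Ba", "Fu", "Pp", "OP"):
            p_taxa[trophic == g] = p_guild[g] * within[g]

        depth_mean = config.nematode_depth * eff.total
        if config.noise_free:
            counts = p_taxa * depth_mean
        else:
            depth = rng.poisson(depth_mean)
            if math.isinf(config.dispersion):
                comp = p_taxa
            else:
                comp = rng.dirichlet(config.dispersion * p_taxa)
            counts = rng.multinomial(depth, comp).astype(float)
        nem_rows.append(counts)

        # OTU table with per-treatment phylum shifts
        ph_shift = np.array([eff.phylum.get(p, 1.0) for p in phyla])
        p_ph = base_ph * ph_shift
        p_ph = p_ph / p_ph.sum()
        p_otu = otu_w * p_ph[[phyla.index(p) for p in otu_phyla]]
        p_otu = p_otu / p_otu.sum()
        if config.noise_free:
            otu_counts = p_otu * config.otu_depth
        else:
            if math.isinf(config.dispersion):
                comp = p_otu
            else:
                comp = rng.dirichlet(config.dispersion * p_otu)
            otu_counts = rng.multinomial(config.otu_depth, comp).astype(float)
        otu_rows.append(otu_counts)

        copies_mean = config.copies_base * eff.copies
        if config.noise_free:
            copies = copies_mean
        else:
            sigma = math.sqrt(math.log(1 + config.copies_cv**2))
            copies = copies_mean * math.exp(
                rng.normal(-sigma**2 / 2, sigma)
            )
        copies_out.append(copies)

        # True physiology rates
        g_mean = config.growth_base * eff.growth
        r_mean = config.respiration_base * eff.respiration
        cm_mean = config.cm_base * eff.cm
        mbc_mean = config.chemistry_means[treatment]["MBC"]
        if config.noise_free:
            g_true, r_true, cm_true, mbc_true = g_mean, r_mean, cm_mean, mbc_mean
        else:
            g_true = g_mean * math.exp(rng.normal(0, config.rate_cv))
            r_true = r_mean * math.exp(rng.normal(0, config.rate_cv))
            cm_true = cm_mean * math.exp(rng.normal(0, config.rate_cv))
            mbc_true = max(
                50.0, rng.normal(mbc_mean, config.chemistry_sds["MBC"])
            )
        truth_rows.append(
            {
                "treatment": treatment,
                **{f"p_{g}": p_guild[g] for g in ("Ba", "Fu", "Pp", "OP")},
                "total_abundance": depth_mean,
                "growth": g_true,
                "respiration": r_true,
                "cue": g_true / (g_true + r_true),
                "qco2": r_true / mbc_true,
                "copies": copies_mean if config.noise_free else copies,
                "mbc": mbc_true,
                "cm": cm_true,
            }
        )

    index = pd.Index(config.sample_ids, name="sample")
    nem = pd.DataFrame(np.array(nem_rows), index=index, columns=genera)
    otu = pd.DataFrame(np.array(otu_rows), index=index, columns=otu_ids)
    if not config.noise_free:
        nem = nem.astype(np.int64)
        otu = otu.astype(np.int64)
    taxonomy = pd.Series(otu_phyla, index=pd.Index(otu_ids, name="OTU"),
                         name="phylum")
    copies = pd.Series(copies_out, index=index, name="copies_16S")
    truth = SyntheticTruth(pd.DataFrame(truth_rows, index=index))
    return nem, otu, taxonomy, copies, truth


# ---------------------------------------------------------------------------
# Physiology records by algebraic inversion
# ---------------------------------------------------------------------------

#: Fixed assay constants of the simulated incubations.
ASSAY = {
    "O_total": 20.0,  # ug O in dried DNA
    "at_label": 20.0,  # atom% 18O of labelled soil water
    "DW": 1.0,  # g dry soil
    "t": 24.0,  # h
    "V": 0.05,  # L headspace
    "DNA_preculture": 8.0,  # ug DNA per g precultured soil
    "c_HCl": 0.4,  # mol/L
    "V0": 50.0,  # mL blank titration
    "soil_mass": 100.0,  # g per mineralization jar
}


def generate_physiology_records(
    config: GeneratorConfig, truth: SyntheticTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Incubation and titration record tables inverting the true rates.

    Given the fixed assay constants, atom% excess and headspace CO2 are
    back-solved so that the physiology formulas return exactly the true
    growth and respiration rates; titration volumes are back-solved from
    the true C mineralization.  Raises if a truth value would require an
    unphysical record (atom% excess above the label, negative volume).
    """
    a = ASSAY
    ts = truth.per_sample
    if (ts[["growth", "respiration", "cm"]] < 0).to_numpy().any():
        raise ValueError("true rates must be non-negative")

    fdna = ts["mbc"] / a["DNA_preculture"]
    dna_prod = ts["growth"] * a["DW"] * a["t"] / (fdna * 1000.0)
    at_excess = (
        dna_prod * DNA_OXYGEN_PERCENT * a["at_label"]
        / (a["O_total"] * 100.0)
    )
    if (at_excess > a["at_label"]).any():
        raise ValueError(
            "true growth implies atom% excess above the label strength"
        )
    dco2 = (
        ts["respiration"] * MOLAR_VOLUME_STP * a["DW"] * a["t"]
        / (CARBON_MOLAR_MASS * a["V"] * 1000.0)
    )
    incubation = pd.DataFrame(
        {
            "O_total": a["O_total"],
            "at_label": a["at_label"],
            "at_excess": at_excess,
            "DW": a["DW"],
            "t": a["t"],
            "dCO2": dco2,
            "V": a["V"],
            "MBC": ts["mbc"],
            "DNA_preculture": a["DNA_preculture"],
        },
        index=ts.index,
    )

    v1 = a["V0"] - ts["cm"] * (a["soil_mass"] / 1000.0) / (
        a["c_HCl"] * CO2_EQUIVALENT_MASS
    )
    if (v1 < 0).any():
        raise ValueError("true CM implies negative titration volume")
    titration = pd.DataFrame(
        {
            "c_HCl": a["c_HCl"],
            "V0": a["V0"],
            "V1": v1,
            "soil_mass": a["soil_mass"],
        },
        index=ts.index,
    )
    return incubation, titration


# ---------------------------------------------------------------------------
# Chemistry and the full dataset
# ---------------------------------------------------------------------------

def generate_chemistry(config: GeneratorConfig,
                       truth: Optional[SyntheticTruth] = None) -> pd.DataFrame:
    """Per-sample soil chemistry table (pH, SOC, TN, TP, TK, CEC, MBC).

    When a truth table is supplied its MBC column is reused so chemistry
    and physiology agree sample by sample.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    rows = []
    for sample, treatment in zip(config.sample_ids, config.sample_treatments):
        means = config.chemistry_means[treatment]
        row = {}
        for var, mu in means.items():
            sd = 0.0 if config.noise_free else config.chemistry_sds[var]
            row[var] = rng.normal(mu, sd) if sd > 0 else float(mu)
        rows.append(row)
    chem = pd.DataFrame(rows, index=pd.Index(config.sample_ids, name="sample"))
    chem["treatment"] = config.sample_treatments
    if truth is not None:
        chem["MBC"] = truth.per_sample["mbc"]
    return chem[["treatment", "pH", "SOC", "TN", "TP", "TK", "CEC", "MBC"]]


@dataclass
class SyntheticDataset:
    """One complete generated study."""

    config: GeneratorConfig
    traits: TraitReference
    nematode_counts: pd.DataFrame
    otu_table: pd.DataFrame
    otu_taxonomy: pd.Series
    copy_numbers: pd.Series
    chemistry: pd.DataFrame
    incubation: pd.DataFrame
    titration: pd.DataFrame
    truth: SyntheticTruth

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.traits.to_csv(outdir / "traits.csv")
        self.nematode_counts.to_csv(outdir / "nematode_counts.csv")
        self.otu_table.to_csv(outdir / "otu_table.csv")
        self.otu_taxonomy.rename("phylum").to_csv(outdir / "otu_taxonomy.csv")
        self.copy_numbers.rename("copies_16S").to_csv(outdir / "copy_numbers.csv")
        self.chemistry.to_csv(outdir / "chemistry.csv")
        self.incubation.to_csv(outdir / "incubation.csv", index_label="sample")
        self.titration.to_csv(outdir / "titration.csv", index_label="sample")
        self.truth.to_csv(outdir / "truth.csv")


def generate_dataset(config: Optional[GeneratorConfig] = None,
                     **kwargs) -> SyntheticDataset:
    """Generate a complete synthetic study.

    ``kwargs`` override :class:`GeneratorConfig` fields when no config is
    passed.
    """
    if config is None:
        config = GeneratorConfig(**kwargs)
    traits = generate_trait_reference(config)
    nem, otu, taxonomy, copies, truth = generate_community_tables(
        config, traits
    )
    incubation, titration = generate_physiology_records(config, truth)
    chemistry = generate_chemistry(config, truth)
    return SyntheticDataset(
        config=config,
        traits=traits,
        nematode_counts=nem,
        otu_table=otu,
        otu_taxonomy=taxonomy,
        copy_numbers=copies,
        chemistry=chemistry,
        incubation=incubation,
        titration=titration,
        truth=truth,
    )
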