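"""End-to-end orchestration: simulate -> indices -> physiology -> community -> stats.

A single :class:`RunConfig` drives every stage; all randomness flows from
named seeds so reruns with the same config reproduce byte-identical
output tables.  Each run directory receives the stage outputs plus a
``manifest.json`` recording package version, a config hash, the seeds and
per-stage row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.manifold import MDS

from . import __version__, community, ecostats, io as sfw_io, nematodes
from .physiology import physiology_table
from .synthetic import GeneratorConfig, SyntheticDataset, generate_dataset
from .traits import TraitReference

log = logging.getLogger("soilfoodweb")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    simulate: dict = field(default_factory=dict)  # GeneratorConfig overrides
    rarefaction_depth: int = 28883
    alpha: float = 0.05
    n_perm: int = 999
    noise_free: bool = False
    footprints: bool = True
    cm_as_carbon: bool = False
    # Optional existing-input paths; when unset the simulate stage provides them.
    inputs: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise annotated
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done", name)
            return out
        return wrapper
    return deco


@_stage("simulate")
def _simulate(cfg: RunConfig) -> SyntheticDataset:
    gc_kwargs = dict(cfg.simulate)
    gc_kwargs.setdefault("seed", cfg.seed)
    gen = GeneratorConfig(**gc_kwargs)
    if cfg.noise_free:
        gen = gen.noise_free_copy()
    return generate_dataset(gen)


def _load_inputs(cfg: RunConfig) -> SyntheticDataset | dict:
    """Either simulate or read user-supplied tables."""
    if not cfg.inputs:
        return _simulate(cfg)
    paths = cfg.inputs
    for key, p in paths.items():
        if not Path(p).exists():
            raise PipelineError(f"stage 'inputs' failed: missing file {p}")
    data = {
        "traits": TraitReference(pd.read_csv(paths["traits"])),
        "nematode_counts": sfw_io.read_table(
            paths["nematode_counts"], sfw_io.NEMATODE_COUNTS
        ),
        "otu_table": sfw_io.read_table(paths["otu_table"], sfw_io.OTU_TABLE),
        "otu_taxonomy": pd.read_csv(paths["otu_taxonomy"], index_col=0)[
            "phylum"
        ],
        "copy_numbers": sfw_io.read_table(
            paths["copy_numbers"], sfw_io.COPY_NUMBERS
        )["copies_16S"],
        "chemistry": sfw_io.read_table(paths["chemistry"], sfw_io.CHEMISTRY),
        "incubation": sfw_io.read_table(paths["incubation"], sfw_io.INCUBATION),
        "titration": sfw_io.read_table(paths["titration"], sfw_io.TITRATION),
    }
    return data


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage in dependency order; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setLevel(logging.INFO)
    log.addHandler(handler)
    try:
        return _run(cfg, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(cfg: RunConfig, out: Path) -> Path:
    data = _load_inputs(cfg)
    if isinstance(data, SyntheticDataset):
        data.write(out / "data")
        traits = data.traits
        nem = data.nematode_counts
        otu = data.otu_table
        taxonomy = data.otu_taxonomy
        copies = data.copy_numbers
        chemistry = data.chemistry
        incubation = data.incubation
        titration = data.titration
        treatments = pd.Series(
            data.config.sample_treatments, index=nem.index, name="treatment"
        )
    else:
        traits, nem, otu = (
            data["traits"], data["nematode_counts"], data["otu_table"]
        )
        taxonomy, copies = data["otu_taxonomy"], data["copy_numbers"]
        chemistry = data["chemistry"]
        incubation, titration = data["incubation"], data["titration"]
        treatments = chemistry["treatment"]

    rows = {}

    # --- nematode indices -------------------------------------------------
    indices = _indices_stage(nem, traits, copies, cfg)
    sfw_io.write_table(indices, out / "nematode_indices.csv")
    rows["nematode_indices"] = len(indices)

    # --- physiology -------------------------------------------------------
    physio = _physiology_stage(incubation, titration, cfg)
    sfw_io.write_table(physio, out / "physiology.csv")
    rows["physiology"] = len(physio)

    # --- community --------------------------------------------------------
    rarefied, phylum_ra, bc, bac_shannon = _community_stage(
        otu, taxonomy, cfg
    )
    sfw_io.write_table(rarefied, out / "otu_rarefied.csv")
    sfw_io.write_table(phylum_ra, out / "phylum_relative_abundance.csv")
    sfw_io.write_table(bc, out / "bray_curtis.csv")
    sfw_io.write_table(bac_shannon.to_frame(), out / "bacterial_diversity.csv")
    rows["community"] = len(rarefied)

    # --- statistics -------------------------------------------------------
    stats_out = _stats_stage(
        indices, physio, chemistry, bc, treatments, bac_shannon, cfg
    )
    for name, df in stats_out.items():
        sfw_io.write_table(df, out / f"stats_{name}.csv",
                           index_label=df.index.name or "row")
        rows[f"stats_{name}"] = len(df)

    manifest = {
        "package_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "rows": rows,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


@_stage("indices")
def _indices_stage(nem, traits, copies, cfg):
    return nematodes.compute_index_table(
        nem, traits, copies=copies, footprints=cfg.footprints
    )


@_stage("physiology")
def _physiology_stage(incubation, titration, cfg):
    return physiology_table(
        incubation, titration, cm_as_carbon=cfg.cm_as_carbon
    )


@_stage("community")
def _community_stage(otu, taxonomy, cfg):
    counts = otu.round().astype(np.int64)
    depth = min(cfg.rarefaction_depth, int(counts.sum(axis=1).min()))
    rarefied = community.rarefy(counts, depth, seed=cfg.seed)
    phylum_ra = community.phylum_relative_abundance(rarefied, taxonomy)
    bc = community.bray_curtis(rarefied)
    shannon = nematodes.shannon_table(rarefied).rename("H_bacteria")
    return rarefied, phylum_ra, bc, shannon


@_stage("stats")
def _stats_stage(indices, physio, chemistry, bc, treatments, bac_shannon, cfg):
    out: dict[str, pd.DataFrame] = {}

    # Tukey letters for every index and physiology response
    responses = indices[["H", "MI", "CI", "EI", "SI", "FDis"]].join(
        physio[["growth", "respiration", "qCO2", "CUE"]]
    )
    if "CM" in physio.columns:
        responses["CM"] = physio["CM"]
    anova_rows = []
    for col in responses.columns:
        vals = responses[col].dropna()
        if vals.empty:
            continue
        grp = treatments.loc[vals.index]
        if grp.value_counts().min() < 2 or grp.nunique() < 2:
            continue
        try:
            res = ecostats.anova_tukey_letters(
                vals.to_numpy(), grp.to_numpy(), alpha=cfg.alpha
            )
        except ValueError:
            continue
        for g in res.means:
            anova_rows.append(
                {
                    "response": col,
                    "treatment": g,
                    "mean": res.means[g],
                    "letters": res.letters[g],
                    "F": res.F,
                    "p": res.p,
                }
            )
    out["anova"] = pd.DataFrame(anova_rows)

    # Spearman: chemistry vs indices + physiology
    chem_num = chemistry.drop(columns=["treatment"])
    rho, pval = ecostats.spearman_matrix(chem_num, responses)
    out["spearman_rho"] = rho
    out["spearman_p"] = pval

    # NMDS on Bray-Curtis (established implementation, treated as opaque)
    D = bc.to_numpy()
    try:
        mds = MDS(
            n_components=2,
            metric="precomputed",
            metric_mds=False,
            random_state=cfg.seed,
            n_init=4,
            init="random",
            normalized_stress="auto",
        )
    except TypeError:  # older scikit-learn API
        mds = MDS(
            n_components=2,
            metric=False,
            dissimilarity="precomputed",
            random_state=cfg.seed,
            n_init=4,
            normalized_stress="auto",
        )
    scores = pd.DataFrame(
        mds.fit_transform(D), index=bc.index, columns=["NMDS1", "NMDS2"]
    )
    out["nmds_scores"] = scores

    # envfit of chemistry + nematode indices on the ordination
    env = chem_num.join(indices[["H", "MI", "CI", "EI", "SI", "FDis"]])
    env = env.loc[scores.index].dropna(axis=1)
    out["envfit"] = ecostats.envfit_permutation(
        scores, env, n_perm=cfg.n_perm, seed=cfg.seed
    )

    # Variance partition of the community (ordination scores) between
    # soil chemistry and the nematode indices; small predictor subsets
    # keep residual degrees of freedom at the 15-sample design size
    idx_tab = indices[["EI", "SI", "CI", "MI"]].dropna()
    chem_sub = chem_num[["pH", "SOC", "TN", "TP"]]
    common = chem_sub.index.intersection(idx_tab.index)
    part = ecostats.variance_partition(
        scores.loc[common], chem_sub.loc[common], idx_tab.loc[common]
    )
    out["varpart"] = pd.DataFrame(
        {
            "fraction": ["a_chemistry", "b_shared", "c_indices", "d_residual"],
            "adj_r2_share": [part.a, part.b, part.c, part.d],
        }
    )
    return out
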