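"""Nematode community ecological indices from genus count tables.

All functions take a count table (rows = samples, columns = genera,
individuals per 100 g dry soil) plus a :class:`~soilfoodweb.traits.TraitReference`
and return per-sample results.  Indices with a zero denominator are
reported as missing (NaN), never as 0 and never as an exception, so they
propagate cleanly through downstream statistics.

Faunal-analysis weighting
-------------------------
The enrichment (e), basal (b) and structure (s) components are weighted
functional-guild counts:

    e = 3.2*Ba1 + 0.8*Fu2
    b = 0.8*(Ba2 + Fu2)
    s = sum over structural guilds (Ba3-Ba5, Fu3-Fu5, Om3-Om5, Ca2-Ca5)
        of w(cp)*count,  w = {2: 0.8, 3: 1.8, 4: 3.2, 5: 5.0}

and the indices are

    EI = 100*e/(e+b)         enrichment index
    SI = 100*s/(s+b)         structure index
    CI = 100*(0.8*Fu2)/(3.2*Ba1 + 0.8*Fu2)   channel index
    MI = sum cp_i * p_i over free-living taxa  maturity index
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .traits import FREE_LIVING, TROPHIC_GUILDS, TraitReference

#: Weight of a functional guild by c-p value in the e/b/s components.
CP_WEIGHTS = {1: 3.2, 2: 0.8, 3: 1.8, 4: 3.2, 5: 5.0}

#: Structural functional guilds entering the s component.
STRUCTURAL_GUILDS = (
    ["Ba3", "Ba4", "Ba5", "Fu3", "Fu4", "Fu5"]
    + ["Om3", "Om4", "Om5"]
    + ["Ca2", "Ca3", "Ca4", "Ca5"]
)


def _validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    if counts.columns.duplicated().any():
        raise ValueError("duplicate genus columns in count table")
    if counts.index.duplicated().any():
        raise ValueError("duplicate sample names in count table")
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("negative entries in count table")
    return counts


def tabulate_guilds(
    counts: pd.DataFrame, traits: TraitReference
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample trophic-guild and functional-guild totals.

    Returns
    -------
    guild_totals:
        samples x (Ba, Fu, Pp, OP, total) table; conserves counts.
    functional_totals:
        samples x functional-guild (e.g. Ba1, Fu2, Om4) table covering
        every functional guild present in the trait reference.
    """
    _validate_counts(counts)
    traits.require(counts.columns)
    fine = np.array([traits.guild(g) for g in counts.columns])
    trophic = np.where(np.isin(fine, ("Om", "Ca")), "OP", fine)
    cp = np.array([traits.cp(g) for g in counts.columns])

    guild_totals = pd.DataFrame(
        {g: counts.loc[:, trophic == g].sum(axis=1) for g in TROPHIC_GUILDS}
    )
    guild_totals["total"] = counts.sum(axis=1)

    func_labels = np.array([f"{f}{c}" for f, c in zip(fine, cp)])
    functional = pd.DataFrame(
        {
            lab: counts.loc[:, func_labels == lab].sum(axis=1)
            for lab in sorted(set(func_labels))
        }
    )
    return guild_totals, functional


def shannon_index(abundances) -> float:
    """Shannon-Wiener diversity H = -sum p_i ln p_i, in nats.

    Zero-abundance taxa contribute nothing; an all-zero vector is
    undefined and returns NaN.
    """
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("negative abundances")
    total = a.sum()
    if total == 0:
        return float("nan")
    p = a[a > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_table(counts: pd.DataFrame) -> pd.Series:
    """Shannon index per sample (row)."""
    return counts.apply(lambda row: shannon_index(row.to_numpy()), axis=1).rename("H")


def maturity_index(counts: pd.DataFrame, traits: TraitReference) -> pd.Series:
    """Free-living maturity index MI = sum cp_i * p_i.

    Proportions are renormalized over free-living taxa only (plant
    parasites excluded); samples with no free-living individuals give NaN.
    """
    _validate_counts(counts)
    traits.require(counts.columns)
    fine = np.array([traits.guild(g) for g in counts.columns])
    free = np.isin(fine, FREE_LIVING)
    cp = np.array([traits.cp(g) for g in counts.columns], dtype=float)
    sub = counts.loc[:, free].to_numpy(dtype=float)
    totals = sub.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mi = (sub * cp[free]).sum(axis=1) / totals
    mi[totals == 0] = np.nan
    return pd.Series(mi, index=counts.index, name="MI")


def faunal_components(functional: pd.DataFrame) -> pd.DataFrame:
    """Enrichment/basal/structure components from functional-guild totals.

    Input is the ``functional_totals`` table of :func:`tabulate_guilds`;
    absent functional-guild columns count as zero.
    """

    def col(name: str) -> pd.Series:
        if name in functional.columns:
            return functional[name].astype(float)
        return pd.Series(0.0, index=functional.index)

    ba1, ba2, fu2 = col("Ba1"), col("Ba2"), col("Fu2")
    e = 3.2 * ba1 + 0.8 * fu2
    b = 0.8 * (ba2 + fu2)
    s = pd.Series(0.0, index=functional.index)
    for lab in STRUCTURAL_GUILDS:
        s = s + CP_WEIGHTS[int(lab[-1])] * col(lab)
    return pd.DataFrame(
        {"e": e, "b": b, "s": s, "Ba1": ba1, "Ba2": ba2, "Fu2": fu2}
    )


def faunal_indices(components: pd.DataFrame) -> pd.DataFrame:
    """Channel, enrichment and structure indices (CI, EI, SI), 0-100.

    Each index is NaN where its denominator is zero.
    """
    e = components["e"].to_numpy(dtype=float)
    b = components["b"].to_numpy(dtype=float)
    s = components["s"].to_numpy(dtype=float)
    ba1 = components["Ba1"].to_numpy(dtype=float)
    fu2 = components["Fu2"].to_numpy(dtype=float)

    with np.errstate(invalid="ignore", divide="ignore"):
        ci = 100.0 * (0.8 * fu2) / (3.2 * ba1 + 0.8 * fu2)
        ei = 100.0 * e / (e + b)
        si = 100.0 * s / (s + b)
    ci[(3.2 * ba1 + 0.8 * fu2) == 0] = np.nan
    ei[(e + b) == 0] = np.nan
    si[(s + b) == 0] = np.nan
    return pd.DataFrame({"CI": ci, "EI": ei, "SI": si}, index=components.index)


# ---------------------------------------------------------------------------
# Functional dispersion (FDis)
# ---------------------------------------------------------------------------

def gower_distance(traits: TraitReference, genera) -> pd.DataFrame:
    """Gower dissimilarity between taxa over mixed trait types.

    Variables: guild (categorical, 0/1 mismatch), c-p value (quantitative,
    range-scaled) and log body mass (quantitative, range-scaled; skipped
    entirely when any genus lacks a mass).  Each variable contributes
    equally; distances lie in [0, 1].
    """
    genera = list(genera)
    traits.require(genera)
    guild = np.array([traits.guild(g) for g in genera])
    cp = np.array([traits.cp(g) for g in genera], dtype=float)
    mass = np.array([traits.body_mass(g) for g in genera], dtype=float)

    parts = []
    parts.append((guild[:, None] != guild[None, :]).astype(float))
    rng_cp = cp.max() - cp.min()
    if rng_cp > 0:
        parts.append(np.abs(cp[:, None] - cp[None, :]) / rng_cp)
    else:
        parts.append(np.zeros((len(genera), len(genera))))
    if np.isfinite(mass).all() and (mass > 0).all():
        lm = np.log(mass)
        rng_m = lm.max() - lm.min()
        d = (
            np.abs(lm[:, None] - lm[None, :]) / rng_m
            if rng_m > 0
            else np.zeros((len(genera), len(genera)))
        )
        parts.append(d)
    D = np.mean(parts, axis=0)
    return pd.DataFrame(D, index=genera, columns=genera)


def _pcoa_embed(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate embedding of a dissimilarity matrix.

    Returns real-axis and imaginary-axis coordinates; negative eigenvalues
    (Gower matrices need not be Euclidean-embeddable) go to the imaginary
    block and are handled with the standard corrected squared distance
    ||x_pos||^2 - ||x_neg||^2.
    """
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh((G + G.T) / 2)
    tol = 1e-10 * max(1.0, np.abs(vals).max())
    pos = vals > tol
    neg = vals < -tol
    X_pos = vecs[:, pos] * np.sqrt(vals[pos])
    X_neg = vecs[:, neg] * np.sqrt(-vals[neg])
    return X_pos, X_neg


def functional_dispersion(
    counts: pd.DataFrame, traits: TraitReference
) -> pd.Series:
    """Functional dispersion (FDis) per sample.

    FDis = sum_j a_j z_j / sum_j a_j, where z_j is the distance of taxon j
    to the abundance-weighted community centroid in the principal-coordinate
    space of the Gower trait dissimilarity (the Laliberte & Legendre
    construction).  Samples with one taxon, or with all taxa sharing
    identical traits, give 0; empty samples give NaN.
    """
    _validate_counts(counts)
    D = gower_distance(traits, counts.columns).to_numpy()
    X_pos, X_neg = _pcoa_embed(D)

    out = np.empty(len(counts))
    A = counts.to_numpy(dtype=float)
    for i, a in enumerate(A):
        total = a.sum()
        if total == 0:
            out[i] = np.nan
            continue
        w = a / total
        c_pos = w @ X_pos
        c_neg = w @ X_neg
        z2 = ((X_pos - c_pos) ** 2).sum(axis=1) - ((X_neg - c_neg) ** 2).sum(
            axis=1
        )
        z = np.sqrt(np.clip(z2, 0.0, None))
        out[i] = float(w @ z)
    return pd.Series(out, index=counts.index, name="FDis")


# ---------------------------------------------------------------------------
# Predation pressure and metabolic footprints
# ---------------------------------------------------------------------------

def predation_pressure(
    ba_per_100g, copies_per_g, *, counts_basis_g: float = 100.0
) -> pd.Series:
    """Bacterivore predation pressure on bacteria: Ba / 16S copies.

    Nematode counts (per ``counts_basis_g`` g dry soil, default 100 g) and
    copy numbers (per g dry soil) are put on a common per-gram basis
    before division.
    """
    ba = np.asarray(ba_per_100g, dtype=float)
    copies = np.asarray(copies_per_g, dtype=float)
    if (copies <= 0).any():
        raise ValueError("16S copy numbers must be positive")
    pp = (ba / counts_basis_g) / copies
    index = (
        ba_per_100g.index if isinstance(ba_per_100g, pd.Series) else None
    )
    return pd.Series(pp, index=index, name="predation_pressure")


def metabolic_footprints(
    counts: pd.DataFrame, traits: TraitReference
) -> pd.DataFrame:
    """Per-guild metabolic footprints (production + respiration terms).

    F_guild = sum_t N_t * (0.1 * W_t / cp_t + 0.273 * W_t^0.75) over taxa t
    of the guild, with W the body fresh weight (ug).  Requires body mass
    for every genus with nonzero counts.
    """
    _validate_counts(counts)
    traits.require(counts.columns)
    used = counts.columns[(counts != 0).any(axis=0)]
    missing = [g for g in used if not np.isfinite(traits.body_mass(g))]
    if missing:
        raise ValueError(f"body mass missing for genera: {missing}")

    mass = np.array([traits.body_mass(g) for g in counts.columns])
    cp = np.array([traits.cp(g) for g in counts.columns], dtype=float)
    per_ind = 0.1 * mass / cp + 0.273 * mass**0.75
    per_ind = np.where(np.isfinite(per_ind), per_ind, 0.0)
    trophic = np.array([traits.trophic_guild(g) for g in counts.columns])

    F = counts.to_numpy(dtype=float) * per_ind
    out = {
        f"footprint_{g}": F[:, trophic == g].sum(axis=1)
        for g in TROPHIC_GUILDS
    }
    return pd.DataFrame(out, index=counts.index)


def compute_index_table(
    counts: pd.DataFrame,
    traits: TraitReference,
    copies: Optional[pd.Series] = None,
    *,
    footprints: bool = True,
) -> pd.DataFrame:
    """The full per-sample index table.

    Columns: H, MI, CI, EI, SI, FDis, guild totals (TA, Ba, Fu, Pp, OP),
    optionally predation_pressure (needs 16S ``copies`` per g soil,
    row-aligned) and per-guild metabolic footprints (needs body masses).
    """
    guild_totals, functional = tabulate_guilds(counts, traits)
    comp = faunal_components(functional)
    idx = faunal_indices(comp)

    table = pd.DataFrame(
        {
            "H": shannon_table(counts),
            "MI": maturity_index(counts, traits),
            "CI": idx["CI"],
            "EI": idx["EI"],
            "SI": idx["SI"],
            "FDis": functional_dispersion(counts, traits),
            "TA": guild_totals["total"],
            "Ba": guild_totals["Ba"],
            "Fu": guild_totals["Fu"],
            "Pp": guild_totals["Pp"],
            "OP": guild_totals["OP"],
        }
    )
    if copies is not None:
        table["predation_pressure"] = predation_pressure(
            guild_totals["Ba"], copies.loc[counts.index]
        )
    if footprints:
        has_mass = all(
            np.isfinite(traits.body_mass(g))
            for g in counts.columns[(counts != 0).any(axis=0)]
        )
        if has_mass:
            table = table.join(metabolic_footprints(counts, traits))
        else:
            warnings.warn(
                "body masses incomplete; metabolic footprints skipped"
            )
    return table
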