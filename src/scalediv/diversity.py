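"""Detection-corrected diversity metrics and temporal beta-diversity partition.

Taxonomic diversity (TD) of an assemblage is the sum of occupancy
probabilities over species.  Temporal change in composition between a later
year m and the baseline year is decomposed with a probabilistic
persistence/colonization/extinction calculus:

    a_i = psi_{i,m} * psi_{i,base}                       (persistence)
    b_i = sum_{t=base+1}^{m} psi_{i,t} (1 - psi_{i,t-1}) (first colonizations)
    c_i = sum_{t=base+1}^{m} psi_{i,t-1} (1 - psi_{i,t}) (unrecovered losses)

b counts only species whose psi never exceeded a threshold (default 0.8)
between the baseline and m-1 ("first colonizations only"); c only species
whose psi never exceeded the threshold between m+1 and the final year ("never
recolonized").  Sorensen temporal dissimilarity and its partition into
nestedness and turnover are

    DIS = (b + c) / (2a + b + c)
    NES = [(max(b,c) - min(b,c)) / (2a + b + c)] * [a / (a + min(b,c))]
    TUR = min(b,c) / (a + min(b,c))        with NES + TUR = DIS.

The functional analogues replace a, b, c by d, e, f — the functional
diversity of the persisting/colonizing/lost sets, computed by feeding the
per-species component magnitudes (clipped to [0, 1]) into the
occupancy-weighted FD of the master dendrogram.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .functional import FunctionalDendrogram, functional_diversity

COLONIZATION_THRESHOLD = 0.8


def taxonomic_diversity(psi_vector) -> float:
    """TD = sum of occupancy probabilities."""
    psi = np.asarray(psi_vector, dtype=float)
    if np.any((psi < 0) | (psi > 1)):
        raise ValueError("psi must lie in [0, 1]")
    return float(psi.sum())


def persistence_component(psi_base, psi_m):
    """a_i = psi_m * psi_base per species; returns (a, a_i)."""
    ai = np.asarray(psi_m, dtype=float) * np.asarray(psi_base, dtype=float)
    return float(ai.sum()), ai


def colonization_component(psi_series: np.ndarray, m_index: int, threshold=COLONIZATION_THRESHOLD):
    """First-colonization mass b up to year index ``m_index``.

    ``psi_series`` is (species x years) from the baseline year onward.
    A species is eligible only if its psi never exceeded ``threshold`` in
    years [base, m-1]; eligible species accumulate
    ``sum_{t=1..m} psi_t (1 - psi_{t-1})``.  Returns (b, b_i).
    """
    psi = np.asarray(psi_series, dtype=float)
    if m_index < 1 or m_index >= psi.shape[1]:
        raise ValueError("m_index must be in [1, n_years)")
    eligible = (psi[:, :m_index] <= threshold).all(axis=1)
    terms = psi[:, 1 : m_index + 1] * (1.0 - psi[:, :m_index])
    bi = np.where(eligible, terms.sum(axis=1), 0.0)
    return float(bi.sum()), bi


def extinction_component(
    psi_series: np.ndarray, m_index: int, threshold=COLONIZATION_THRESHOLD
):
    """Unrecovered-loss mass c up to year index ``m_index``.

    Eligibility: psi never exceeded ``threshold`` in years [m+1, last]
    (vacuously true when m is the last year).  Eligible species accumulate
    ``sum_{t=1..m} psi_{t-1} (1 - psi_t)``.  Returns (c, c_i).
    """
    psi = np.asarray(psi_series, dtype=float)
    if m_index < 1 or m_index >= psi.shape[1]:
        raise ValueError("m_index must be in [1, n_years)")
    eligible = (psi[:, m_index + 1 :] <= threshold).all(axis=1)
    terms = psi[:, :m_index] * (1.0 - psi[:, 1 : m_index + 1])
    ci = np.where(eligible, terms.sum(axis=1), 0.0)
    return float(ci.sum()), ci


def sorensen_dissimilarity(a, b, c) -> float:
    """DIS = (b + c) / (2a + b + c); NaN when a = b = c = 0."""
    denom = 2 * a + b + c
    if denom == 0:
        warnings.warn("Sorensen dissimilarity undefined (a = b = c = 0)")
        return float("nan")
    return (b + c) / denom


def nestedness_component(a, b, c) -> float:
    """Nestedness-resultant component of Sorensen temporal dissimilarity."""
    denom = 2 * a + b + c
    if denom == 0:
        warnings.warn("nestedness undefined (a = b = c = 0)")
        return float("nan")
    lo = min(b, c)
    # a + min = 0 (no persistence, one-sided change): turnover is 0 by
    # convention, so the nestedness factor must be 1 to keep NES + TUR = DIS
    second = a / (a + lo) if (a + lo) > 0 else 1.0
    return (max(b, c) - lo) / denom * second


def turnover_component(a, b, c) -> float:
    """TUR = min(b, c) / (a + min(b, c)); 0 by convention when a + min = 0."""
    lo = min(b, c)
    if a + lo == 0:
        return 0.0
    return lo / (a + lo)


def component_contributions(dis, nes, tur):
    """(NESc, TURc) = (NES, TUR) / DIS; NaN when DIS = 0."""
    if not dis or np.isnan(dis):
        warnings.warn("contributions undefined (DIS = 0)")
        return float("nan"), float("nan")
    return nes / dis, tur / dis


def functional_components(tree: FunctionalDendrogram, a_i, b_i, c_i):
    """FD of the persisting/colonizing/lost sets: (d, e, f).

    Component magnitudes act as the occupancy-style weight vector; values are
    clipped into [0, 1] (multi-year colonization/loss sums can exceed 1) with
    clipping logged.
    """
    out = []
    for name, vec in (("a", a_i), ("b", b_i), ("c", c_i)):
        v = np.asarray(vec, dtype=float)
        if np.any(v > 1.0) or np.any(v < 0.0):
            warnings.warn(f"component {name} clipped into [0, 1] for FD weighting")
            v = np.clip(v, 0.0, 1.0)
        if np.all(v == 0):
            out.append(0.0)
            continue
        out.append(functional_diversity(tree, v))
    return tuple(out)


def dissimilarity_series(
    psi_panel: dict,
    tree: FunctionalDendrogram | None = None,
    threshold=COLONIZATION_THRESHOLD,
) -> pd.DataFrame:
    """Full temporal-dissimilarity table for one assemblage (cell).

    ``psi_panel`` maps year -> psi vector (aligned across years; pandas
    Series aligned on index or plain arrays of equal length).  Returns one
    row per year after the baseline with the a/b/c (and d/e/f if a tree is
    given) components and the DIS/NES/TUR/NESc/TURc quantities for TD and,
    when a tree is supplied, FD.
    """
    years = sorted(psi_panel)
    if len(years) < 2:
        raise ValueError("need at least two years")
    mat = np.column_stack([np.asarray(psi_panel[t], dtype=float) for t in years])
    rows = []
    for m_idx in range(1, len(years)):
        a, ai = persistence_component(mat[:, 0], mat[:, m_idx])
        b, bi = colonization_component(mat, m_idx, threshold)
        c, ci = extinction_component(mat, m_idx, threshold)
        row = {"year": years[m_idx], "a": a, "b": b, "c": c}
        row["TD_DIS"] = sorensen_dissimilarity(a, b, c)
        row["TD_NES"] = nestedness_component(a, b, c)
        row["TD_TUR"] = turnover_component(a, b, c)
        row["TD_NESc"], row["TD_TURc"] = component_contributions(
            row["TD_DIS"], row["TD_NES"], row["TD_TUR"]
        )
        if tree is not None:
            d, e, f = functional_components(tree, ai, bi, ci)
            row.update({"d": d, "e": e, "f": f})
            row["FD_DIS"] = sorensen_dissimilarity(d, e, f)
            row["FD_NES"] = nestedness_component(d, e, f)
            row["FD_TUR"] = turnover_component(d, e, f)
            row["FD_NESc"], row["FD_TURc"] = component_contributions(
                row["FD_DIS"], row["FD_NES"], row["FD_TUR"]
            )
        rows.append(row)
    return pd.DataFrame(rows)


def weighted_mean_body_mass(psi_vector, masses) -> float:
    """Occupancy-weighted mean body mass of the assemblage."""
    psi = np.asarray(psi_vector, dtype=float)
    m = np.asarray(masses, dtype=float)
    tot = psi.sum()
    if tot == 0:
        warnings.warn("mean body mass undefined (sum of psi = 0)")
        return float("nan")
    return float((psi * m).sum() / tot)


def guild_prevalence(psi_vector, trait_block) -> np.ndarray:
    """Occupancy-weighted prevalence of each guild axis; sums to 1.

    ``trait_block`` is species x axes with rows on the simplex (e.g. the diet
    or foraging-niche proportions).
    """
    psi = np.asarray(psi_vector, dtype=float)
    T = np.asarray(trait_block, dtype=float)
    tot = psi.sum()
    if tot == 0:
        warnings.warn("guild prevalence undefined (sum of psi = 0)")
        return np.full(T.shape[1], np.nan)
    return (psi[:, None] * T).sum(axis=0) / tot


def global_td_series(extinctions: pd.DataFrame, species_pool_size: int, years) -> pd.DataFrame:
    """Global-scale TD: pool size minus cumulative extinctions.

    A species with extinction year t is absent from year t onward.  At the
    global scale colonization is identically zero, so the series is
    non-increasing.
    """
    years = sorted(int(t) for t in years)
    ext_years = np.sort(extinctions["extinction_year"].to_numpy()) if len(extinctions) else np.array([])
    td = [species_pool_size - int((ext_years <= t).sum()) for t in years]
    out = pd.DataFrame({"year": years, "TD": td})
    out["TD_rel"] = out["TD"] / out["TD"].iloc[0] if out["TD"].iloc[0] else np.nan
    return out


def diversity_series(
    psi_by_year: dict,
    tree: FunctionalDendrogram | None = None,
    traits: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-year TD (and FD / trait summaries) for one assemblage.

    ``psi_by_year`` maps year -> psi vector aligned with the master species
    order (and tree leaves / trait rows when those are supplied).
    """
    from .synthetic import DIET_AXES, FORAGING_AXES

    years = sorted(psi_by_year)
    rows = []
    for t in years:
        psi = np.asarray(psi_by_year[t], dtype=float)
        row = {"year": t, "TD": taxonomic_diversity(psi)}
        if tree is not None:
            row["FD"] = functional_diversity(tree, psi) if psi.sum() > 0 else 0.0
        if traits is not None:
            row["mean_mass"] = weighted_mean_body_mass(psi, traits["body_mass_g"])
            for axes in (DIET_AXES, FORAGING_AXES):
                prev = guild_prevalence(psi, traits[list(axes)])
                row.update(dict(zip(axes, prev)))
        rows.append(row)
    df = pd.DataFrame(rows)
    df["TD_rel"] = df["TD"] / df["TD"].iloc[0] if df["TD"].iloc[0] else np.nan
    if tree is not None and df["FD"].iloc[0]:
        df["FD_rel"] = df["FD"] / df["FD"].iloc[0]
    return df
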