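"""Derived community statistics computed from posterior draws of z.

Every reported summary is a function of the latent occupancy draws:
species richness and its treatment contrasts, pairwise Dice similarity
of site assemblages, species turnover, local extinction, and species
local survival. Each statistic is computed per MCMC draw and then
summarised by its posterior median and central 95% interval. Undefined
0/0 cases (empty communities) propagate as missing values and are
excluded from summaries, never imputed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .design import StudyDesign

_Q = (0.025, 0.975)


def _z_stack(draws) -> np.ndarray:
    """Pool z draws over chains into (N, S, K, T)."""
    if hasattr(draws, "z_flat"):
        return draws.z_flat().astype(np.int64)
    z = np.asarray(draws)
    if z.ndim == 3:
        z = z[None]
    return z.astype(np.int64)


def _summary(values: np.ndarray) -> tuple:
    """(median, lo, hi) over the draw axis, ignoring missing draws."""
    values = np.asarray(values, dtype=float)
    if np.all(np.isnan(values)):
        return (np.nan, np.nan, np.nan)
    return (float(np.nanmedian(values)),
            float(np.nanquantile(values, _Q[0])),
            float(np.nanquantile(values, _Q[1])))


# ---------------------------------------------------------------------------
# per-draw statistics


def richness(z_draw: np.ndarray, site: int, year: int) -> int:
    """Number of species occupying a site in a year: sum_i z[i, k, t]."""
    z_draw = np.asarray(z_draw)
    return int(z_draw[:, site, year].sum())


def similarity(z_draw: np.ndarray, site_a: int, site_b: int, year: int,
               method: str = "dice") -> float:
    """Compositional similarity of two sites' assemblages in one year.

    Dice (default): 2 |A & B| / (|A| + |B|); Jaccard available as an
    alternative. Returns nan when both assemblages are empty.
    """
    if site_a == site_b:
        raise ValueError("sites must be distinct")
    za = np.asarray(z_draw)[:, site_a, year]
    zb = np.asarray(z_draw)[:, site_b, year]
    both = int((za & zb).sum())
    na, nb = int(za.sum()), int(zb.sum())
    if method == "dice":
        denom = na + nb
        return 2.0 * both / denom if denom > 0 else np.nan
    if method == "jaccard":
        union = na + nb - both
        return both / union if union > 0 else np.nan
    raise ValueError(f"unknown similarity method {method!r}")


def turnover(z_draw: np.ndarray, site: int, year_t: int) -> float:
    """Probability that a species drawn from the year-t community was
    absent the previous year: sum z_t (1 - z_{t-1}) / sum z_t."""
    if year_t < 1:
        raise ValueError("turnover is defined for years after the first")
    z = np.asarray(z_draw)
    now = z[:, site, year_t]
    before = z[:, site, year_t - 1]
    denom = int(now.sum())
    return float((now & (1 - before)).sum() / denom) if denom > 0 else np.nan


def extinction(z_draw: np.ndarray, site: int, year_t: int) -> float:
    """Probability that a species occupying the site at year t is absent
    at year t+1: sum z_t (1 - z_{t+1}) / sum z_t."""
    z = np.asarray(z_draw)
    if year_t >= z.shape[2] - 1:
        raise ValueError("extinction is defined for years before the last")
    now = z[:, site, year_t]
    nxt = z[:, site, year_t + 1]
    denom = int(now.sum())
    return float((now & (1 - nxt)).sum() / denom) if denom > 0 else np.nan


# ---------------------------------------------------------------------------
# draw-level tables


def richness_draws(draws) -> np.ndarray:
    """(N, K, T) per-draw site-year richness."""
    return _z_stack(draws).sum(axis=1)


def richness_contrasts(draws, design: StudyDesign) -> pd.DataFrame:
    """Treated-minus-control mean richness per district and year.

    For each draw and district x year cell: the mean richness over
    treated sites minus the mean over control sites; summarised by the
    posterior median and 95% interval (6 rows for the default 2-district
    3-year design).
    """
    rich = richness_draws(draws)  # (N, K, T)
    trt = np.asarray(design.treatment)
    dist = np.asarray(design.district)
    rows = []
    for g in np.unique(dist):
        sel_t = (dist == g) & (trt == 1)
        sel_c = (dist == g) & (trt == 0)
        if not sel_t.any() or not sel_c.any():
            raise ValueError(
                f"district {g}: contrast undefined (empty treatment or control cell)"
            )
        contrast = rich[:, sel_t, :].mean(axis=1) - rich[:, sel_c, :].mean(axis=1)
        for t in range(design.n_years):
            med, lo, hi = _summary(contrast[:, t])
            rows.append({
                "district": int(g) + 1,
                "year": design.year_labels[t],
                "median": med, "lo": lo, "hi": hi,
            })
    return pd.DataFrame(rows)


def similarity_draws(draws, site_a: int, site_b: int, year: int,
                     method: str = "dice") -> np.ndarray:
    """(N,) per-draw similarity for one site pair and year."""
    z = _z_stack(draws)
    za, zb = z[:, :, site_a, year], z[:, :, site_b, year]
    both = (za & zb).sum(axis=1).astype(float)
    na, nb = za.sum(axis=1), zb.sum(axis=1)
    if method == "dice":
        denom = (na + nb).astype(float)
        num = 2.0 * both
    elif method == "jaccard":
        denom = (na + nb - both).astype(float)
        num = both
    else:
        raise ValueError(f"unknown similarity method {method!r}")
    with np.errstate(invalid="ignore"):
        return np.where(denom > 0, num / denom, np.nan)


def _pair_class(trt_a: int, trt_b: int) -> str:
    return {0: "control-control", 1: "control-treatment",
            2: "treatment-treatment"}[trt_a + trt_b]


def similarity_summary(draws, design: StudyDesign,
                       method: str = "dice") -> pd.DataFrame:
    """Posterior summary of median pairwise similarity by year and pair
    class (control-control, control-treatment, treatment-treatment).

    The per-draw statistic is the median similarity over all site pairs
    in the class (pairs with undefined similarity are dropped in that
    draw).
    """
    z = _z_stack(draws)
    K = design.n_sites
    trt = np.asarray(design.treatment)
    classes = {}
    for a in range(K):
        for b in range(a + 1, K):
            classes.setdefault(_pair_class(trt[a], trt[b]), []).append((a, b))
    rows = []
    for t in range(design.n_years):
        for cls, pairs in sorted(classes.items()):
            sims = np.column_stack(
                [similarity_draws(z, a, b, t, method) for a, b in pairs]
            )  # (N, n_pairs)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                per_draw = np.nanmedian(sims, axis=1)
            med, lo, hi = _summary(per_draw)
            rows.append({"year": design.year_labels[t], "pair_class": cls,
                         "n_pairs": len(pairs), "median": med,
                         "lo": lo, "hi": hi})
    return pd.DataFrame(rows)


def turnover_extinction_summary(draws, design: StudyDesign) -> pd.DataFrame:
    """Mean turnover and extinction over sites, per treatment group and
    year, summarised over draws (the boxplot-style output)."""
    z = _z_stack(draws)
    trt = np.asarray(design.treatment)
    rows = []
    with np.errstate(invalid="ignore"):
        for grp, label in ((0, "control"), (1, "treatment")):
            sel = trt == grp
            zs = z[:, :, sel, :]
            now = zs[:, :, :, 1:]
            prev = zs[:, :, :, :-1]
            gains = (now * (1 - prev)).sum(axis=1)
            n_now = now.sum(axis=1)
            tov = np.where(n_now > 0, gains / n_now, np.nan)  # (N, k, T-1)
            losses = (prev * (1 - now)).sum(axis=1)
            n_prev = prev.sum(axis=1)
            ext = np.where(n_prev > 0, losses / n_prev, np.nan)
            for t in range(design.n_years - 1):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    tm = np.nanmean(tov[:, :, t], axis=1)
                    em = np.nanmean(ext[:, :, t], axis=1)
                med, lo, hi = _summary(tm)
                rows.append({"group": label,
                             "year": design.year_labels[t + 1],
                             "statistic": "turnover",
                             "median": med, "lo": lo, "hi": hi})
                med, lo, hi = _summary(em)
                rows.append({"group": label,
                             "year": design.year_labels[t],
                             "statistic": "extinction",
                             "median": med, "lo": lo, "hi": hi})
    return pd.DataFrame(rows)


def local_survival_draws(draws, species: int, year: int | None = None) -> np.ndarray:
    """(N,) per-draw local survival for one species: the fraction of its
    occupied site-years (before the final year) still occupied the next
    year, pooled over sites and year pairs. nan when the species
    occupies nothing in a draw. ``year`` restricts the pooling to the
    single year pair (year, year + 1)."""
    z = _z_stack(draws)
    if year is None:
        now = z[:, species, :, :-1]
        nxt = z[:, species, :, 1:]
    else:
        if not 0 <= year < z.shape[3] - 1:
            raise ValueError("year must index a (year, year+1) pair")
        now = z[:, species, :, year:year + 1]
        nxt = z[:, species, :, year + 1:year + 2]
    persisted = (now & nxt).sum(axis=(1, 2)).astype(float)
    occupied = now.sum(axis=(1, 2)).astype(float)
    with np.errstate(invalid="ignore"):
        return np.where(occupied > 0, persisted / occupied, np.nan)


def local_survival(draws, species=None, labels=None) -> pd.DataFrame:
    """Posterior summary of local survival per species."""
    z = _z_stack(draws)
    if z.shape[3] < 2:
        raise ValueError("local survival needs at least two years")
    species_list = range(z.shape[1]) if species is None else [species]
    rows = []
    for i in species_list:
        med, lo, hi = _summary(local_survival_draws(z, i))
        rows.append({
            "species": labels[i] if labels else i + 1,
            "median": med, "lo": lo, "hi": hi,
        })
    return pd.DataFrame(rows)


def effect_table(draws, family: str, labels=None) -> pd.DataFrame:
    """Posterior median, 95% interval and a contains-zero flag for every
    species in one coefficient family, plus its community hyper-mean.

    The contains-zero flag is the evidence criterion used for
    species-level effects (no evidence of effect when the interval
    spans 0).
    """
    sp = draws.species_draws(family)  # (C, D, S)
    mu = draws.mu_draws(family).reshape(-1)
    rows = []
    med, lo, hi = _summary(mu)
    rows.append({"species": "hyper_mean", "median": med, "lo": lo, "hi": hi,
                 "contains_zero": bool(lo <= 0.0 <= hi)})
    S = sp.shape[2]
    for i in range(S):
        med, lo, hi = _summary(sp[:, :, i].reshape(-1))
        rows.append({
            "species": labels[i] if labels else f"sp{i + 1}",
            "median": med, "lo": lo, "hi": hi,
            "contains_zero": bool(lo <= 0.0 <= hi),
        })
    return pd.DataFrame(rows)


def posterior_interval(values: np.ndarray) -> tuple:
    """(median, 2.5%, 97.5%) of a flat draw vector."""
    return _summary(np.asarray(values).reshape(-1))
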