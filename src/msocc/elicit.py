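"""Informative hyper-prior elicitation from a previous study.

The informed hyper-priors are built from the collection of
species-specific posterior means reported by an earlier, ecologically
similar intervention study: a beta distribution is fitted to the
detection-intercept means (probability scale) and a normal distribution
to the occupancy treatment-effect means (logit scale). The fitted
distributions become the hyper-priors on the corresponding hyper-means.

The original study's numeric summaries are not published, so the module
also ships a synthetic stand-in generator that draws species posterior
means from configurable distributions, plus a reader for user-supplied
two-column summary files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._rng import as_rng
from .priors import DIFFUSE_MU_SD, PriorConfig

#: minimum species count for a distribution fit
MIN_SPECIES = 3


@dataclass
class PriorStudySummaries:
    """Species-specific posterior means from the prior study."""

    detection_means: np.ndarray  # probability scale, in (0, 1)
    treatment_effects: np.ndarray  # logit scale
    species: list = None

    def __post_init__(self):
        self.detection_means = np.asarray(self.detection_means, dtype=float)
        self.treatment_effects = np.asarray(self.treatment_effects, dtype=float)
        if np.any((self.detection_means <= 0) | (self.detection_means >= 1)):
            raise ValueError("detection means must lie strictly in (0, 1)")
        if min(self.detection_means.size, self.treatment_effects.size) < MIN_SPECIES:
            raise ValueError(f"need at least {MIN_SPECIES} species to fit priors")


def fit_beta(values, method: str = "moments") -> tuple:
    """Fit a beta distribution to values in (0, 1).

    Method-of-moments closed form (default): with sample mean m and
    variance v, a = m (m(1-m)/v - 1), b = (1-m) (m(1-m)/v - 1); this is
    only defined for v < m(1-m). ``method='mle'`` refines the moment
    estimate by maximum likelihood.
    """
    x = np.asarray(values, dtype=float)
    if x.size < MIN_SPECIES:
        raise ValueError(f"need at least {MIN_SPECIES} values, got {x.size}")
    if np.any((x <= 0) | (x >= 1)):
        raise ValueError("values must lie strictly in (0, 1)")
    m = x.mean()
    v = x.var(ddof=1)
    if v <= 0:
        raise ValueError("values are constant; no beta fit exists")
    if v >= m * (1 - m):
        raise ValueError(
            f"sample variance {v:.4g} >= m(1-m) = {m * (1 - m):.4g}: "
            "no beta distribution matches these moments"
        )
    scale = m * (1 - m) / v - 1.0
    a, b = m * scale, (1 - m) * scale
    if method == "moments":
        return (float(a), float(b))
    if method == "mle":
        a_hat, b_hat, _, _ = sps.beta.fit(x, floc=0, fscale=1)
        return (float(a_hat), float(b_hat))
    raise ValueError(f"unknown method {method!r}")


def fit_normal(values, sd_floor: float = 1e-3) -> tuple:
    """Sample mean and SD (n-1 denominator) of the values.

    A zero-variance sample gets its SD floored at ``sd_floor`` with a
    warning rather than producing a degenerate prior.
    """
    x = np.asarray(values, dtype=float)
    if x.size < MIN_SPECIES:
        raise ValueError(f"need at least {MIN_SPECIES} values, got {x.size}")
    m = float(x.mean())
    s = float(x.std(ddof=1))
    if s < sd_floor:
        warnings.warn(
            f"sample SD {s:.3g} below floor; using {sd_floor}", stacklevel=2
        )
        s = sd_floor
    return (m, s)


def build_prior_config(summaries: PriorStudySummaries | None,
                       scenario: str, method: str = "moments") -> PriorConfig:
    """Wire fitted distributions into one of the four prior scenarios.

    Informed scenarios require ``summaries``; the diffuse scenario
    ignores them.
    """
    if scenario == "diffuse":
        return PriorConfig(scenario="diffuse")
    if summaries is None:
        raise ValueError(f"scenario {scenario!r} requires prior-study summaries")
    beta_params = (1.0, 1.0)
    normal_params = (0.0, DIFFUSE_MU_SD)
    if scenario in ("informed_detection", "informed_both"):
        beta_params = fit_beta(summaries.detection_means, method=method)
    if scenario in ("informed_treatment", "informed_both"):
        normal_params = fit_normal(summaries.treatment_effects)
    return PriorConfig(scenario=scenario, beta_params=beta_params,
                       normal_params=normal_params)


def make_prior_study(n_species: int = 26, detection_beta=(2.0, 5.0),
                     treatment_normal=(0.5, 0.5), seed=0) -> PriorStudySummaries:
    """Synthetic stand-in for the prior study's posterior summaries.

    Draws species-specific detection-intercept posterior means from a
    beta distribution and treatment-effect means from a normal, at
    scales typical of songbird point-count studies (per-visit detection
    mostly 0.1-0.6, modest positive treatment effects).
    """
    rng = as_rng(seed)
    det = rng.beta(*detection_beta, size=n_species)
    det = np.clip(det, 1e-6, 1 - 1e-6)
    trt = rng.normal(*treatment_normal, size=n_species)
    return PriorStudySummaries(detection_means=det, treatment_effects=trt,
                               species=[f"sp{i + 1}" for i in range(n_species)])


def read_summaries(detection_path, treatment_path) -> PriorStudySummaries:
    """Read two-column delimited files (species, value), one per
    parameter, into prior-study summaries."""
    det = pd.read_csv(detection_path)
    trt = pd.read_csv(treatment_path)
    for df, name in ((det, "detection"), (trt, "treatment")):
        if df.shape[1] != 2:
            raise ValueError(f"{name} summaries must have exactly 2 columns")
    return PriorStudySummaries(
        detection_means=det.iloc[:, 1].to_numpy(dtype=float),
        treatment_effects=trt.iloc[:, 1].to_numpy(dtype=float),
        species=det.iloc[:, 0].astype(str).tolist(),
    )
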