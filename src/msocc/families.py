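"""Coefficient families of the hierarchical community model.

Every species-level coefficient belongs to a *family* (e.g. the
detection intercept, the occupancy treatment effect). Species values
within a family are exchangeable draws from a community-level normal
distribution with hyper-parameters (mu_f, sigma_f). Families are laid
out as columns of a (n_species, n_families) matrix so that Metropolis
sweeps and conjugate hyper-updates vectorise over species / families.

Detection families (logit scale):
    det_intercept   intercept of the detection mean model
    det_treatment   harvest-treatment effect on detection
    det_year_<t>    year offsets, first year as reference (t = 2..T)
    det_date        linear effect of the centred/scaled survey date
    det_date_sq     quadratic date effect

Occupancy families (logit scale):
    occ_intercept   base-year occupancy intercept
    occ_treatment   harvest-treatment effect on occupancy
    occ_district    management-district effect
    occ_trt_year_<t>  treatment x year offsets for t = 2..T
    occ_persist     autologistic term when the site was occupied the
                    previous year (replaces the intercept for t > 1)
    occ_colonize    autologistic term when the site was unoccupied the
                    previous year

For a one-year design the dynamic families are omitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import as_rng


class FamilyLayout:
    """Ordered coefficient families for a design with ``n_years`` years."""

    def __init__(self, n_years: int):
        if n_years < 1:
            raise ValueError("n_years must be >= 1")
        self.n_years = int(n_years)
        det = ["det_intercept", "det_treatment"]
        det += [f"det_year_{t}" for t in range(2, n_years + 1)]
        det += ["det_date", "det_date_sq"]
        occ = ["occ_intercept", "occ_treatment", "occ_district"]
        occ += [f"occ_trt_year_{t}" for t in range(2, n_years + 1)]
        if n_years > 1:
            occ += ["occ_persist", "occ_colonize"]
        self.detection_names = tuple(det)
        self.occupancy_names = tuple(occ)
        self.names = tuple(det + occ)
        self.index = {name: i for i, name in enumerate(self.names)}
        self.detection_idx = np.array([self.index[n] for n in det])
        self.occupancy_idx = np.array([self.index[n] for n in occ])

    @property
    def n_families(self) -> int:
        return len(self.names)

    def is_detection(self, name: str) -> bool:
        return name.startswith("det_")

    def __getitem__(self, name: str) -> int:
        return self.index[name]

    def __contains__(self, name: str) -> bool:
        return name in self.index

    def __eq__(self, other) -> bool:
        return isinstance(other, FamilyLayout) and other.names == self.names

    def __repr__(self) -> str:  # pragma: no cover
        return f"FamilyLayout(n_years={self.n_years}, n_families={self.n_families})"


@dataclass
class SpeciesParams:
    """Species-level coefficients: ``values[i, f]`` for species i, family f."""

    layout: FamilyLayout
    values: np.ndarray  # (n_species, n_families), float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.layout.n_families:
            raise ValueError(
                f"values must be (n_species, {self.layout.n_families}), "
                f"got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("species coefficients must be finite")

    @property
    def n_species(self) -> int:
        return self.values.shape[0]

    def get(self, name: str) -> np.ndarray:
        """Column of species values for one family."""
        return self.values[:, self.layout[name]]

    def year_offsets(self, prefix: str) -> np.ndarray:
        """(n_species, n_years) offset matrix with year 1 fixed at 0."""
        out = np.zeros((self.n_species, self.layout.n_years))
        for t in range(2, self.layout.n_years + 1):
            out[:, t - 1] = self.get(f"{prefix}{t}")
        return out

    def copy(self) -> "SpeciesParams":
        return SpeciesParams(self.layout, self.values.copy())

    @classmethod
    def zeros(cls, layout: FamilyLayout, n_species: int) -> "SpeciesParams":
        return cls(layout, np.zeros((n_species, layout.n_families)))

    @classmethod
    def from_dict(cls, layout: FamilyLayout, n_species: int, **families) -> "SpeciesParams":
        """Build from per-family scalars or length-n_species vectors."""
        p = cls.zeros(layout, n_species)
        for name, val in families.items():
            if name not in layout:
                raise KeyError(f"unknown family {name!r}")
            p.values[:, layout[name]] = val
        return p


@dataclass
class HyperParams:
    """Community-level means and SDs, one pair per coefficient family."""

    layout: FamilyLayout
    mu: np.ndarray  # (n_families,)
    sigma: np.ndarray  # (n_families,), all > 0

    def __post_init__(self):
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        F = self.layout.n_families
        if self.mu.shape != (F,) or self.sigma.shape != (F,):
            raise ValueError(f"mu and sigma must have shape ({F},)")

    def validate(self):
        if not np.all(self.sigma > 0):
            raise ValueError("hyper-parameter SDs must be > 0")

    def get_mu(self, name: str) -> float:
        return float(self.mu[self.layout[name]])

    def get_sigma(self, name: str) -> float:
        return float(self.sigma[self.layout[name]])

    def copy(self) -> "HyperParams":
        return HyperParams(self.layout, self.mu.copy(), self.sigma.copy())

    @classmethod
    def from_dicts(cls, layout: FamilyLayout, mu: dict | float = 0.0,
                   sigma: dict | float = 1.0) -> "HyperParams":
        """Build from {family: value} dicts (missing families get the
        scalar default passed as ``mu``/``sigma`` under key '*')."""

        def expand(spec, default):
            arr = np.full(layout.n_families, default, dtype=float)
            if isinstance(spec, dict):
                base = spec.get("*", default)
                arr[:] = base
                for name, val in spec.items():
                    if name == "*":
                        continue
                    if name not in layout:
                        raise KeyError(f"unknown family {name!r}")
                    arr[layout[name]] = val
            else:
                arr[:] = float(spec)
            return arr

        return cls(layout, expand(mu, 0.0), expand(sigma, 1.0))


def draw_from_hyper(hyper: HyperParams, n_species: int, seed) -> SpeciesParams:
    """Independent normal draw per species and family (community model).

    sigma = 0 gives the degenerate point mass at the community mean;
    negative SDs are rejected.
    """
    if np.any(hyper.sigma < 0):
        raise ValueError("hyper-parameter SDs must be >= 0")
    rng = as_rng(seed)
    vals = rng.normal(hyper.mu, hyper.sigma, size=(n_species, hyper.layout.n_families))
    return SpeciesParams(hyper.layout, vals)
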