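"""Study design: sites, treatment/district allocation, survey dates.

The default design mirrors a randomized-block salvage-logging
experiment: two management districts, each with equal numbers of
control and harvested stands (6 + 6 per district, 24 stands total),
surveyed three times per breeding season (15 May - 1 July, Julian days
135-182) for three consecutive years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import as_rng

#: default survey window, day-of-year (15 May to 1 July)
SEASON_WINDOW = (135, 182)


@dataclass
class StudyDesign:
    """Site-level covariates and survey dates for one study.

    Attributes
    ----------
    n_species : int
        Number of species in the observed community.
    treatment, district : (n_sites,) int arrays of 0/1
        Harvest-treatment and management-district indicators.
    date_raw : (n_sites, n_years, n_visits) float
        Raw Julian day-of-year of each survey visit. One date per
        (site, year, visit): a single point-count visit records all
        species.
    date_scaled : (n_sites, n_years, n_visits) float
        Dates centred and scaled (mean 0, SD 1) across all visits; the
        quadratic detection term uses the square of this value.
    year_labels : list of int
        Calendar labels for the years (used in emitted tables).
    """

    n_species: int
    treatment: np.ndarray
    district: np.ndarray
    date_raw: np.ndarray
    date_scaled: np.ndarray = None
    year_labels: list = None

    def __post_init__(self):
        self.treatment = np.asarray(self.treatment, dtype=np.int8)
        self.district = np.asarray(self.district, dtype=np.int8)
        self.date_raw = np.asarray(self.date_raw, dtype=float)
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.treatment.ndim != 1 or self.treatment.shape != self.district.shape:
            raise ValueError("treatment and district must be 1-d and the same length")
        for name, arr in (("treatment", self.treatment), ("district", self.district)):
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"{name} indicators must be 0/1")
        if self.date_raw.ndim != 3 or self.date_raw.shape[0] != self.n_sites:
            raise ValueError(
                "date_raw must be (n_sites, n_years, n_visits) with "
                f"n_sites={self.n_sites}, got {self.date_raw.shape}"
            )
        if self.date_scaled is None:
            self.date_scaled = scale_dates(self.date_raw)
        else:
            self.date_scaled = np.asarray(self.date_scaled, dtype=float)
            if self.date_scaled.shape != self.date_raw.shape:
                raise ValueError("date_scaled must match date_raw's shape")
        if self.year_labels is None:
            self.year_labels = list(range(1, self.n_years + 1))
        if len(self.year_labels) != self.n_years:
            raise ValueError("year_labels must have one entry per year")

    @property
    def n_sites(self) -> int:
        return self.treatment.shape[0]

    @property
    def n_years(self) -> int:
        return self.date_raw.shape[1]

    @property
    def n_visits(self) -> int:
        return self.date_raw.shape[2]


def scale_dates(date_raw: np.ndarray) -> np.ndarray:
    """Centre and scale dates to mean 0, SD 1 across all visits.

    A zero-variance date set (possible in degenerate one-visit designs)
    maps to all zeros rather than dividing by zero.
    """
    date_raw = np.asarray(date_raw, dtype=float)
    if date_raw.size == 0:
        return np.zeros_like(date_raw)
    sd = date_raw.std()
    if sd == 0:
        return np.zeros_like(date_raw)
    return (date_raw - date_raw.mean()) / sd


def make_design(
    n_species: int,
    n_sites_per_cell: int,
    n_years: int,
    n_visits: int,
    seed,
    season_window: tuple = SEASON_WINDOW,
    year_labels: list | None = None,
) -> StudyDesign:
    """Balanced treatment x district design with random survey dates.

    ``n_sites_per_cell`` sites are allocated to each of the four
    treatment x district cells (the study's 6-per-cell default gives 24
    stands). Visit dates are drawn uniformly (integer days) in the
    season window and sorted within each site-year so visits are in
    temporal order; dates are then centred and scaled across all visits.
    """
    for name, v in (
        ("n_species", n_species),
        ("n_sites_per_cell", n_sites_per_cell),
        ("n_years", n_years),
        ("n_visits", n_visits),
    ):
        if int(v) != v or v < 1:
            raise ValueError(f"{name} must be a positive integer, got {v!r}")
    rng = as_rng(seed)
    n_sites = 4 * n_sites_per_cell
    # cells ordered (district 0: control, treated), (district 1: control, treated)
    treatment = np.tile(
        np.repeat([0, 1], n_sites_per_cell), 2
    )
    district = np.repeat([0, 1], 2 * n_sites_per_cell)
    lo, hi = season_window
    dates = rng.integers(lo, hi + 1, size=(n_sites, n_years, n_visits)).astype(float)
    dates.sort(axis=2)
    return StudyDesign(
        n_species=int(n_species),
        treatment=treatment,
        district=district,
        date_raw=dates,
        year_labels=year_labels,
    )
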