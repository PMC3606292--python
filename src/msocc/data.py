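"""Detection-history container: the model's data layer."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import StudyDesign


@dataclass
class DetectionData:
    """Binary detections y over (species, site, year, visit).

    ``obs_mask`` marks which visits were actually surveyed; unsurveyed
    cells contribute nothing to the likelihood. ``y`` must be 0 at
    masked-out cells.
    """

    y: np.ndarray  # (S, K, T, J) of 0/1
    design: StudyDesign
    obs_mask: np.ndarray = None  # (S, K, T, J) bool
    species_labels: list = None

    def __post_init__(self):
        self.y = np.asarray(self.y)
        expected = (
            self.design.n_species,
            self.design.n_sites,
            self.design.n_years,
            self.design.n_visits,
        )
        if self.y.shape != expected:
            raise ValueError(f"y must have shape {expected}, got {self.y.shape}")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("detections y must be 0/1")
        self.y = self.y.astype(np.int8)
        if self.obs_mask is None:
            self.obs_mask = np.ones(expected, dtype=bool)
        else:
            self.obs_mask = np.asarray(self.obs_mask, dtype=bool)
            if self.obs_mask.shape != expected:
                raise ValueError("obs_mask must match y's shape")
            if np.any(self.y[~self.obs_mask] != 0):
                raise ValueError("y must be 0 at unobserved visits")
        if self.species_labels is None:
            self.species_labels = [f"sp{i + 1}" for i in range(expected[0])]
        if len(self.species_labels) != expected[0]:
            raise ValueError("species_labels must have one entry per species")
        self._detected_any = (self.y & self.obs_mask).any(axis=3)

    @property
    def n_species(self) -> int:
        return self.y.shape[0]

    @property
    def detected_any(self) -> np.ndarray:
        """(S, K, T) bool: any detection at the site-year — forces z = 1."""
        return self._detected_any
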