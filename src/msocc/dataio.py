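"""Readers/writers: long-format detection files, truth sidecars,
configuration, posterior draws, run manifests.

All tabular I/O is delimited text with headers. Species, sites and
visits are 1-based in files (0-based internally); years are carried as
calendar labels.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import DetectionData
from .design import StudyDesign
from .families import FamilyLayout, HyperParams, SpeciesParams
from .generate import GroundTruth
from .sampler import McmcConfig, PosteriorDraws

REQUIRED_COLUMNS = [
    "species_id", "site_id", "year", "visit", "y",
    "treatment", "district", "date_scaled", "date_scaled_sq",
]


def write_detection_data(data: DetectionData, path) -> None:
    """Write one row per observed (species, site, year, visit)."""
    design = data.design
    S, K, T, J = data.y.shape
    sp, site, yr, vis = np.meshgrid(
        np.arange(S), np.arange(K), np.arange(T), np.arange(J), indexing="ij"
    )
    obs = data.obs_mask.reshape(-1)
    df = pd.DataFrame({
        "species_id": sp.reshape(-1) + 1,
        "site_id": site.reshape(-1) + 1,
        "year": np.asarray(design.year_labels)[yr.reshape(-1)],
        "visit": vis.reshape(-1) + 1,
        "y": data.y.reshape(-1),
        "treatment": design.treatment[site.reshape(-1)],
        "district": design.district[site.reshape(-1)],
        "date_scaled": design.date_scaled[site.reshape(-1), yr.reshape(-1),
                                          vis.reshape(-1)],
        "date_scaled_sq": design.date_scaled[site.reshape(-1), yr.reshape(-1),
                                             vis.reshape(-1)] ** 2,
    })[obs]
    df.to_csv(path, index=False)


def read_detection_data(path) -> DetectionData:
    """Read and validate a long-format detection file.

    Rejects non-binary y, duplicate (species, site, year, visit) rows,
    and sites whose treatment/district codes are inconsistent across
    rows. Missing rows become unsurveyed visits (excluded from the
    likelihood).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad = ~df["y"].isin((0, 1))
    if bad.any():
        row = df.index[bad][0]
        raise ValueError(
            f"{path}: non-binary y={df.loc[row, 'y']!r} at row {row + 2} "
            "(1-based, counting the header)"
        )
    key = ["species_id", "site_id", "year", "visit"]
    dup = df.duplicated(subset=key)
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (species, site, year, visit) rows, e.g. "
            f"{df.loc[df.index[dup][0], key].to_dict()}"
        )
    for col in ("treatment", "district"):
        per_site = df.groupby("site_id")[col].nunique()
        bad_sites = per_site[per_site > 1].index.tolist()
        if bad_sites:
            raise ValueError(f"{path}: conflicting {col} codes for sites {bad_sites}")
    # dates must be consistent per (site, year, visit) across species
    per_visit = df.groupby(["site_id", "year", "visit"])["date_scaled"].nunique()
    if (per_visit > 1).any():
        raise ValueError(f"{path}: conflicting date_scaled within a (site, year, visit)")

    species = np.sort(df["species_id"].unique())
    sites = np.sort(df["site_id"].unique())
    years = np.sort(df["year"].unique())
    visits = np.sort(df["visit"].unique())
    S, K, T, J = len(species), len(sites), len(years), len(visits)
    sp_idx = df["species_id"].map({v: i for i, v in enumerate(species)}).to_numpy()
    si_idx = df["site_id"].map({v: i for i, v in enumerate(sites)}).to_numpy()
    yr_idx = df["year"].map({v: i for i, v in enumerate(years)}).to_numpy()
    vi_idx = df["visit"].map({v: i for i, v in enumerate(visits)}).to_numpy()

    y = np.zeros((S, K, T, J), dtype=np.int8)
    mask = np.zeros((S, K, T, J), dtype=bool)
    y[sp_idx, si_idx, yr_idx, vi_idx] = df["y"].to_numpy()
    mask[sp_idx, si_idx, yr_idx, vi_idx] = True

    treatment = np.zeros(K, dtype=np.int8)
    district = np.zeros(K, dtype=np.int8)
    dates = np.zeros((K, T, J))
    treatment[si_idx] = df["treatment"].to_numpy()
    district[si_idx] = df["district"].to_numpy()
    dates[si_idx, yr_idx, vi_idx] = df["date_scaled"].to_numpy()
    design = StudyDesign(
        n_species=S, treatment=treatment, district=district,
        date_raw=dates, date_scaled=dates, year_labels=[int(v) for v in years],
    )
    return DetectionData(y=y, design=design, obs_mask=mask,
                         species_labels=[f"sp{int(v)}" for v in species])


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Truth sidecar for recovery tests: hyper and species values, long."""
    layout = truth.hyper.layout
    rows = []
    for name in layout.names:
        f = layout[name]
        rows.append({"kind": "hyper_mu", "family": name, "species_id": "",
                     "value": truth.hyper.mu[f]})
        rows.append({"kind": "hyper_sigma", "family": name, "species_id": "",
                     "value": truth.hyper.sigma[f]})
        for i in range(truth.species.n_species):
            rows.append({"kind": "species", "family": name,
                         "species_id": i + 1,
                         "value": truth.species.values[i, f]})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ground_truth(path, n_years: int) -> tuple:
    """Read a truth sidecar back into (HyperParams, SpeciesParams)."""
    df = pd.read_csv(path)
    layout = FamilyLayout(n_years)
    mu = np.zeros(layout.n_families)
    sigma = np.ones(layout.n_families)
    for _, r in df[df["kind"] == "hyper_mu"].iterrows():
        mu[layout[r["family"]]] = r["value"]
    for _, r in df[df["kind"] == "hyper_sigma"].iterrows():
        sigma[layout[r["family"]]] = r["value"]
    sp = df[df["kind"] == "species"]
    n_species = int(sp["species_id"].astype(int).max())
    vals = np.zeros((n_species, layout.n_families))
    for _, r in sp.iterrows():
        vals[int(r["species_id"]) - 1, layout[r["family"]]] = r["value"]
    return HyperParams(layout, mu, sigma), SpeciesParams(layout, vals)


# ---------------------------------------------------------------------------
# posterior draws


def save_draws(draws: PosteriorDraws, path) -> None:
    """Persist draws in a columnar binary layout with an embedded manifest."""
    np.savez_compressed(
        path,
        species=draws.species, mu=draws.mu, sigma=draws.sigma, z=draws.z,
        accept_rate=draws.accept_rate,
        families=np.array(draws.layout.names),
        n_years=draws.layout.n_years,
        config=json.dumps(draws.config.to_dict()),
    )


def load_draws(path) -> PosteriorDraws:
    with np.load(path, allow_pickle=False) as f:
        layout = FamilyLayout(int(f["n_years"]))
        if tuple(f["families"]) != layout.names:
            raise ValueError(f"{path}: family layout mismatch")
        return PosteriorDraws(
            layout=layout,
            species=f["species"], mu=f["mu"], sigma=f["sigma"], z=f["z"],
            accept_rate=f["accept_rate"],
            config=McmcConfig.from_dict(json.loads(str(f["config"]))),
        )


# ---------------------------------------------------------------------------
# configuration and manifests


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Everything needed to reproduce a pipeline run."""

    config: dict
    config_sha256: str
    seed: int
    package_version: str
    stages_completed: list = field(default_factory=list)
    input_digests: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)
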