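"""Synthetic multi-site functional-connectivity cohorts with a planted high-risk subgroup.

The generator emulates the data regime of a resting-state case-control study:
per-individual, per-network seed-to-voxel connectivity maps (correlation scale,
clipped to [-1, 1]) with additive age, head-motion and site effects, a low-rank
shared component that gives subtype clustering structure to find, and a minority
subgroup of cases ("carriers") sharing an underconnectivity signature across a
subset of networks.  Everything downstream of fMRI preprocessing is emulated;
nothing upstream (time series, atlases, scanners) is.

Networks are split into two fixed "families" (first half / second half) whose
individual-level latent loadings are shared within family but independent across
families.  This mimics the empirical observation that predictors built on
functionally related networks produce correlated conformal scores, and gives the
2-ensemble clustering stage real structure to recover.  The default signature
networks lie inside the first family.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["GeneratorConfig", "CohortDataset", "generate_cohort"]

DIAGNOSES = ("ASD", "NTC")

#: columns every phenotype table must carry (severity is optional on load)
PHENOTYPE_COLUMNS = ("id", "diagnosis", "age", "motion", "site", "severity", "carrier")

_AGE_RANGE = (8.0, 35.0)          # years, typical multi-site autism cohort range
_MOTION_MEDIAN = 0.15             # mm framewise displacement, log-normal median
_MOTION_LOG_SD = 0.5
_BASELINE_MEAN = 0.25             # within-network FC baseline, correlation scale
_BASELINE_SD = 0.10
_SEVERITY_MEAN = 5.0              # ADOS-like calibrated severity scale 0..10
_SEVERITY_SD = 2.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Defaults describe a small desk-scale cohort; studies override counts.
    """

    n_per_site_per_group: int = 20
    n_sites: int = 4
    n_networks: int = 18
    n_units: int = 200
    age_effect: float = -0.002        # FC change per year of age
    motion_effect: float = -0.1       # FC change per mm framewise displacement
    site_shift_sd: float = 0.03       # SD of per-site additive offsets
    noise_sd: float = 0.15            # SD of i.i.d. per-unit map noise
    carrier_fraction: float = 0.1     # fraction of cases carrying the signature
    signature_networks: tuple[int, ...] | None = None  # None: first network family
    signature_shift: float = -0.3     # signed mean FC shift for carriers (< 0 = under)
    severity_link: float = 0.3        # point-biserial corr of severity with carrier status
    seed: int = 0
    # structural knobs of the generator itself (not study conditions)
    n_latent: int = 5                 # latent spatial patterns per network family
    latent_sd: float = 0.06           # SD of individual loadings on each pattern
    structure_seed: int | None = None # seed of the population structure (None: = seed)

    def __post_init__(self) -> None:
        if self.n_per_site_per_group < 1 or self.n_sites < 1:
            raise ValueError("counts must be >= 1")
        if self.n_networks < 1 or self.n_units < 2:
            raise ValueError("need at least 1 network and 2 spatial units")
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise ValueError(f"carrier_fraction must lie in [0, 1], got {self.carrier_fraction}")
        if self.signature_networks is None:
            # default: the first network family carries the signature
            sig = tuple(range((self.n_networks + 1) // 2))
        else:
            sig = tuple(int(j) for j in self.signature_networks)
        if any(j < 0 or j >= self.n_networks for j in sig):
            raise ValueError(f"signature_networks {sig} outside 0..{self.n_networks - 1}")
        for name in ("site_shift_sd", "noise_sd", "latent_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1.0 <= self.severity_link <= 1.0:
            raise ValueError("severity_link is a correlation and must lie in [-1, 1]")
        object.__setattr__(self, "signature_networks", sig)

    @property
    def n_individuals(self) -> int:
        return self.n_per_site_per_group * self.n_sites * 2

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=int(seed))

    def replicate(self, seed: int) -> "GeneratorConfig":
        """Config for an independent cohort drawn from the *same* population.

        The structural draws (baseline maps, latent patterns, signature
        weights) stay fixed while individuals are resampled, so a replication
        cohort carries the same planted signature as the discovery cohort.
        """
        structure = self.structure_seed if self.structure_seed is not None else self.seed
        return replace(self, seed=int(seed), structure_seed=structure)


@dataclass
class CohortDataset:
    """Connectivity array + phenotype table; the exchange object between stages.

    connectivity : float array, shape (n_individuals, n_networks, n_units)
    phenotype    : DataFrame aligned 1:1 with the first axis, columns
                   id, diagnosis, age, motion, site, severity, carrier
    config       : provenance of generation, None for loaded real data
    """

    connectivity: np.ndarray
    phenotype: pd.DataFrame
    config: GeneratorConfig | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.connectivity = np.asarray(self.connectivity, dtype=float)
        if self.connectivity.ndim != 3:
            raise ValueError(
                f"connectivity must be 3-D (individuals, networks, units), got shape "
                f"{self.connectivity.shape}"
            )
        if not np.isfinite(self.connectivity).all():
            raise ValueError("connectivity contains non-finite values")
        n = self.connectivity.shape[0]
        if len(self.phenotype) != n:
            raise ValueError(
                f"phenotype has {len(self.phenotype)} rows but connectivity has "
                f"{n} individuals"
            )
        missing = {"id", "diagnosis", "age", "motion", "site"} - set(self.phenotype.columns)
        if missing:
            raise ValueError(f"phenotype is missing required columns: {sorted(missing)}")
        bad = set(self.phenotype["diagnosis"].unique()) - set(DIAGNOSES)
        if bad:
            raise ValueError(f"diagnosis labels must be in {DIAGNOSES}, found {sorted(bad)}")
        if "severity" not in self.phenotype.columns:
            self.phenotype = self.phenotype.assign(severity=np.nan)
        if "carrier" not in self.phenotype.columns:
            self.phenotype = self.phenotype.assign(carrier=False)
        self.phenotype = self.phenotype.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.connectivity.shape[0]

    @property
    def n_networks(self) -> int:
        return self.connectivity.shape[1]

    @property
    def n_units(self) -> int:
        return self.connectivity.shape[2]

    @property
    def is_asd(self) -> np.ndarray:
        return (self.phenotype["diagnosis"] == "ASD").to_numpy()

    def subset(self, index: Sequence[int] | np.ndarray) -> "CohortDataset":
        """Row-subset (bootstrap resamples may repeat indices)."""
        index = np.asarray(index, dtype=int)
        return CohortDataset(
            connectivity=self.connectivity[index],
            phenotype=self.phenotype.iloc[index].reset_index(drop=True),
            config=self.config,
        )

    def select_ids(self, ids: Sequence[str]) -> "CohortDataset":
        pos = pd.Index(self.phenotype["id"])
        return self.subset([pos.get_loc(i) for i in ids])

    def equals(self, other: "CohortDataset") -> bool:
        return (
            np.array_equal(self.connectivity, other.connectivity)
            and self.phenotype.reset_index(drop=True).equals(
                other.phenotype.reset_index(drop=True)
            )
        )


def network_families(n_networks: int) -> np.ndarray:
    """Fixed two-family split of networks (first half = family 0)."""
    fam = np.zeros(n_networks, dtype=int)
    fam[(n_networks + 1) // 2:] = 1
    return fam


def generate_cohort(config: GeneratorConfig) -> CohortDataset:
    """Generate a deterministic synthetic cohort from ``config``.

    Carriers are drawn among cases only, at ``carrier_fraction`` (exact count,
    rounded).  Their maps in ``signature_networks`` receive an additive shift
    with per-unit exponential weights of mean 1, so the *mean* shift equals
    ``signature_shift`` while the pattern stays spatially structured (a uniform
    shift would vanish under the spatial-correlation features used downstream).
    All values are clipped to [-1, 1] after the additive effects.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    rng_structure = np.random.default_rng(
        cfg.structure_seed if cfg.structure_seed is not None else cfg.seed
    )
    n = cfg.n_individuals

    # --- population structure (shared by replicate() cohorts) ----------------
    baseline = rng_structure.normal(
        _BASELINE_MEAN, _BASELINE_SD, size=(cfg.n_networks, cfg.n_units)
    )
    fam = network_families(cfg.n_networks)
    patterns = rng_structure.normal(size=(2, cfg.n_latent, cfg.n_units))
    sig_weights = rng_structure.exponential(
        1.0, size=(len(cfg.signature_networks), cfg.n_units)
    )

    # --- phenotype -----------------------------------------------------------
    sites = np.repeat(
        [f"site{s:02d}" for s in range(cfg.n_sites)], cfg.n_per_site_per_group * 2
    )
    diagnosis = np.tile(
        np.repeat(DIAGNOSES, cfg.n_per_site_per_group), cfg.n_sites
    )
    age = rng.uniform(*_AGE_RANGE, size=n)
    motion = rng.lognormal(mean=np.log(_MOTION_MEDIAN), sigma=_MOTION_LOG_SD, size=n)

    is_asd = diagnosis == "ASD"
    asd_idx = np.flatnonzero(is_asd)
    n_carriers = int(round(cfg.carrier_fraction * asd_idx.size))
    carrier = np.zeros(n, dtype=bool)
    if n_carriers:
        carrier[rng.choice(asd_idx, size=n_carriers, replace=False)] = True

    # --- per-cohort draws ----------------------------------------------------
    loadings = rng.normal(scale=cfg.latent_sd, size=(n, 2, cfg.n_latent))
    site_shift = rng.normal(scale=cfg.site_shift_sd, size=cfg.n_sites)
    site_codes = np.repeat(np.arange(cfg.n_sites), cfg.n_per_site_per_group * 2)

    # --- assemble maps -------------------------------------------------------
    maps = np.empty((n, cfg.n_networks, cfg.n_units))
    age_c = age - np.mean(_AGE_RANGE)
    motion_c = motion - _MOTION_MEDIAN
    nuisance = (
        cfg.age_effect * age_c + cfg.motion_effect * motion_c + site_shift[site_codes]
    )
    for j in range(cfg.n_networks):
        latent = loadings[:, fam[j], :] @ patterns[fam[j]]
        maps[:, j, :] = baseline[j] + nuisance[:, None] + latent
    for k, j in enumerate(cfg.signature_networks):
        maps[carrier, j, :] += cfg.signature_shift * sig_weights[k]
    maps += rng.normal(scale=cfg.noise_sd, size=maps.shape)
    np.clip(maps, -1.0, 1.0, out=maps)

    # --- severity: point-biserial link with carrier status -------------------
    p = carrier.mean()
    z = rng.normal(size=n)
    if 0.0 < p < 1.0:
        x_std = (carrier - p) / np.sqrt(p * (1 - p))
        s_std = cfg.severity_link * x_std + np.sqrt(1 - cfg.severity_link**2) * z
    else:
        s_std = z
    severity = np.clip(_SEVERITY_MEAN + _SEVERITY_SD * s_std, 0.0, 10.0)

    phenotype = pd.DataFrame(
        {
            "id": [f"sub-{i:04d}" for i in range(n)],
            "diagnosis": diagnosis,
            "age": age,
            "motion": motion,
            "site": sites,
            "severity": severity,
            "carrier": carrier,
        }
    )
    return CohortDataset(connectivity=maps, phenotype=phenotype, config=cfg)
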