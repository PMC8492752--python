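"""Configuration for the synthetic lake-sediment study.

The synthetic generators emulate a two-lake field design: each lake has a
shallow littoral ("edge") and a deep pelagic ("middle") zone, bubble traps
record ebullitive CH4 flux against surface-sediment temperature, and four
sediment cores (one per lake x zone) are sampled down to ~40 cm for porewater
geochemistry, 16S rRNA amplicon community composition, and qPCR total
abundances.  One :class:`SyntheticConfig` instance fixes every generator
parameter; each output artifact draws from its own random stream derived from
``seed`` so artifacts are independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

ZONES = ("edge", "middle")
LAKES = ("MH", "IH")  # Mellersta Harrsjoen, Inre Harrsjoen


class ConfigError(ValueError):
    """Raised when a synthetic configuration violates an invariant."""


def _default_temp_range() -> dict:
    # middles stay colder than edges in situ
    return {"edge": (4.0, 22.0), "middle": (4.0, 14.0)}


def _default_slopes() -> dict:
    # ln(flux) vs 1/T_K; middle ~3.3-fold steeper than edge
    return {"edge": -6000.0, "middle": -20000.0}


def _default_lnA() -> dict:
    # chosen so fluxes land in the 1-50 mg CH4 m-2 d-1 range
    return {"edge": 23.0, "middle": 71.0}


def _default_guilds() -> dict:
    """Per-zone target mean relative abundances (fractions) per guild."""
    return {
        "methanogen": {"edge": 0.007, "middle": 0.020},
        "syntrophaceae": {"edge": 0.010, "middle": 0.020},
        "ANME": {"edge": 0.003, "middle": 0.0003},
        "aerobic_methanotroph": {"edge": 0.005, "middle": 0.005},
    }


def _default_core_depths() -> dict:
    """Community sample depths per core: 21 core-depth combinations."""
    return {
        ("MH", "edge"): (4, 8, 16, 24, 32, 40),
        ("MH", "middle"): (4, 12, 20, 28, 36),
        ("IH", "edge"): (4, 12, 20, 28, 36),
        ("IH", "middle"): (4, 12, 20, 28, 36),
    }


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic study, with field-realistic defaults."""

    seed: int = 0
    n_lakes: int = 2
    zones: Sequence[str] = ZONES
    traps_per_zone: int = 5
    n_flux_obs: int = 150  # observations per trap
    temp_range_C: Mapping[str, tuple] = field(default_factory=_default_temp_range)
    arrhenius_slope_K: Mapping[str, float] = field(default_factory=_default_slopes)
    arrhenius_lnA: Mapping[str, float] = field(default_factory=_default_lnA)
    flux_noise_sdlog: float = 0.8

    # geochemistry
    depth_grid_cm: Sequence[float] = tuple(range(4, 44, 4))
    d13C_TOC_permil: float = -28.0
    alpha_true: float = 1.060
    f_meth_base: float = 0.25        # f_meth at the surface, edge zone
    f_meth_depth_gain: float = 0.010  # per-cm linear increase of f_meth
    f_meth_zone_boost: float = 1.5    # middle:edge multiplier on f_meth
    DIC_surface_uM: float = 800.0
    DIC_bottom_uM: float = 3000.0
    DIC_noise_sdlog: float = 0.05
    measured_CH4_fraction: float = 0.3
    isotope_noise_sd: float = 0.0     # permil, applied to d13C_CH4 and d13C_DIC

    # community
    n_otus: int = 160
    library_size: int = 5000
    guild_fractions: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_guilds
    )
    methanotroph_max_depth_cm: float = 6.0
    zone_effect_sdlog: float = 0.4    # non-guild zone structure
    depth_effect_sdlog: float = 0.03  # per-cm log-abundance gradient scale
    overdispersion: float = 0.002     # 1 / total Dirichlet concentration
    activity_sdlog: float = 0.35      # shared latent methanogenic activity
    core_depths_cm: Mapping[tuple, Sequence[float]] = field(
        default_factory=_default_core_depths
    )
    rarefaction_depth: int = 3000

    # qPCR
    qpcr_surface_copies_per_g: float = 1.0e9
    qpcr_decay: float = 0.025   # log10 copies lost per cm depth
    qpcr_efficiency: float = 1.0
    qpcr_intercept_ct: float = 38.0  # Ct at 1 copy/uL
    qpcr_noise_sd_ct: float = 0.0

    def __post_init__(self) -> None:
        if self.traps_per_zone < 1 or self.n_flux_obs < 1:
            raise ConfigError("traps_per_zone and n_flux_obs must be >= 1")
        if self.n_otus < len(self.guild_fractions) + 1:
            raise ConfigError("n_otus must exceed the number of guilds")
        for zone, s in self.arrhenius_slope_K.items():
            if s >= 0:
                raise ConfigError(f"Arrhenius slope for {zone} must be negative")
        d = np.asarray(self.depth_grid_cm, dtype=float)
        if d.size < 2 or np.any(np.diff(d) <= 0):
            raise ConfigError("depth_grid_cm must be strictly increasing")
        for frac in (self.measured_CH4_fraction, self.overdispersion):
            if not 0 <= frac <= 1:
                raise ConfigError("fractions must lie in [0, 1]")
        for g, per_zone in self.guild_fractions.items():
            for z, v in per_zone.items():
                if not 0 <= v <= 1:
                    raise ConfigError(f"guild fraction {g}/{z} outside [0, 1]")
        if self.qpcr_efficiency <= 0:
            raise ConfigError("qPCR efficiency must be positive")
        if self.f_meth_profile().max() > 1 or self.f_meth_profile().min() < 0:
            raise ConfigError("f_meth profile leaves [0, 1]")

    # -- profiles on the depth grid -------------------------------------
    def f_meth_profile(self, zone: str = "edge") -> np.ndarray:
        """Fraction of DIC from methanogenesis at each grid depth."""
        d = np.asarray(self.depth_grid_cm, dtype=float)
        boost = self.f_meth_zone_boost if zone == "middle" else 1.0
        return np.clip(boost * (self.f_meth_base + self.f_meth_depth_gain * d), 0.0, 1.0)

    def DIC_uM_profile(self) -> np.ndarray:
        d = np.asarray(self.depth_grid_cm, dtype=float)
        t = (d - d[0]) / (d[-1] - d[0])
        return self.DIC_surface_uM + t * (self.DIC_bottom_uM - self.DIC_surface_uM)

    # -- reproducibility helpers ----------------------------------------
    def rng(self, artifact: str) -> np.random.Generator:
        """Independent random stream for one output artifact."""
        return np.random.default_rng([self.seed, zlib.crc32(artifact.encode())])

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["core_depths_cm"] = {
            "|".join(k): list(v) for k, v in self.core_depths_cm.items()
        }
        blob = json.dumps(payload, sort_keys=True, default=list)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    @property
    def lakes(self) -> Sequence[str]:
        return LAKES[: self.n_lakes]
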