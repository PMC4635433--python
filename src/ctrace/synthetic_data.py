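"""Seeded synthetic gridded inputs: biome map, soil texture, forcing, NPP.

Small abstract grids (no projection) whose per-biome climate envelopes mimic
realistic global drivers — tropical forest cells warm, wet and productive,
tundra cells cold and unproductive — so the whole pipeline runs with no
external data.  Output is bit-reproducible for a given (config, seed) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import SoilTexture, TransferSystem, ValidationError, N_POOLS

__all__ = [
    "BiomeEnvelope",
    "SyntheticGrid",
    "DEFAULT_ENVELOPES",
    "generate_grid",
    "fixture_system",
    "FIXTURE_NAMES",
]

N_DAYS = 365


@dataclass(frozen=True)
class BiomeEnvelope:
    """Statistical envelope a biome's cells are drawn from.

    Temperatures in degC, NPP in gC m^-2 yr^-1, moisture as a fraction of
    porosity.
    """

    t_mean: float
    t_amplitude: float
    t_sd: float
    wetness: float          # mean swc / porosity
    wetness_sd: float
    npp_mean: float
    npp_sd: float
    clay_range: tuple[float, float] = (0.10, 0.35)
    silt_range: tuple[float, float] = (0.20, 0.45)
    porosity_range: tuple[float, float] = (0.38, 0.52)


# Envelopes loosely follow the relative biome magnitudes of global driver
# archives: EBF warm/wet/productive, DNF and TUN cold, BAR dry/unproductive.
DEFAULT_ENVELOPES: dict[str, BiomeEnvelope] = {
    "ENF": BiomeEnvelope(2.0, 12.0, 2.0, 0.55, 0.08, 400.0, 80.0),
    "EBF": BiomeEnvelope(24.0, 3.0, 1.5, 0.70, 0.08, 1300.0, 200.0),
    "DNF": BiomeEnvelope(-4.0, 18.0, 2.0, 0.50, 0.08, 280.0, 60.0),
    "DBF": BiomeEnvelope(12.0, 10.0, 2.0, 0.60, 0.08, 790.0, 150.0),
    "MF": BiomeEnvelope(8.0, 11.0, 2.0, 0.58, 0.08, 600.0, 120.0),
    "CSH": BiomeEnvelope(16.0, 8.0, 2.5, 0.40, 0.10, 350.0, 90.0),
    "OSH": BiomeEnvelope(10.0, 10.0, 3.0, 0.30, 0.10, 200.0, 70.0),
    "GRA": BiomeEnvelope(10.0, 10.0, 2.5, 0.45, 0.10, 450.0, 110.0),
    "WET": BiomeEnvelope(10.0, 9.0, 2.0, 0.85, 0.05, 500.0, 120.0),
    "CRO": BiomeEnvelope(13.0, 10.0, 2.0, 0.55, 0.08, 230.0, 60.0),
    "CRN": BiomeEnvelope(14.0, 9.0, 2.0, 0.55, 0.08, 410.0, 90.0),
    "BAR": BiomeEnvelope(18.0, 12.0, 3.0, 0.10, 0.05, 30.0, 15.0),
    "TUN": BiomeEnvelope(-8.0, 14.0, 2.0, 0.50, 0.10, 60.0, 25.0),
}


@dataclass(frozen=True)
class SyntheticGrid:
    """A flat collection of synthetic cells plus daily forcing series."""

    shape: tuple[int, int]
    biome: np.ndarray              # (n_cells,) str
    texture: tuple[SoilTexture, ...]
    t_soil: np.ndarray             # (n_cells, N_DAYS) degC
    swc: np.ndarray                # (n_cells, N_DAYS) volumetric
    npp: np.ndarray                # (n_cells,) gC m^-2 yr^-1
    seed: int
    area_weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.area_weights is None:
            object.__setattr__(
                self, "area_weights", np.full(self.n_cells, 1.0 / self.n_cells)
            )

    @property
    def n_cells(self) -> int:
        return self.shape[0] * self.shape[1]

    def porosity(self) -> np.ndarray:
        return np.array([t.porosity for t in self.texture])

    def cells_of(self, biome: str) -> np.ndarray:
        return np.where(self.biome == biome)[0]


def generate_grid(
    biomes: list[str] | None = None,
    shape: tuple[int, int] = (20, 20),
    seed: int = 0,
    envelopes: dict[str, BiomeEnvelope] | None = None,
) -> SyntheticGrid:
    """Draw a seeded synthetic grid; every requested biome appears >= 1 cell."""
    if envelopes is None:
        envelopes = DEFAULT_ENVELOPES
    if biomes is None:
        biomes = list(envelopes)
    unknown = [b for b in biomes if b not in envelopes]
    if unknown:
        raise ValidationError(f"unknown biome codes {unknown}; known: {sorted(envelopes)}")
    rows, cols = shape
    if rows < 2 or cols < 2:
        raise ValidationError(f"grid shape must be at least 2x2, got {shape}")
    n = rows * cols
    if n < len(biomes):
        raise ValidationError("grid too small to host every requested biome")

    rng = np.random.default_rng(seed)
    # guarantee coverage, then fill the rest uniformly
    assignment = np.array(biomes + list(rng.choice(biomes, size=n - len(biomes))))
    rng.shuffle(assignment)

    day = np.arange(N_DAYS)
    season = np.sin(2.0 * np.pi * (day - 80.0) / N_DAYS)

    textures = []
    t_soil = np.empty((n, N_DAYS))
    swc = np.empty((n, N_DAYS))
    npp = np.empty(n)
    for i, b in enumerate(assignment):
        env = envelopes[b]
        clay = rng.uniform(*env.clay_range)
        silt = rng.uniform(*env.silt_range)
        porosity = rng.uniform(*env.porosity_range)
        tex = SoilTexture(clay=clay, silt=silt, sand=1.0 - clay - silt, porosity=porosity)
        textures.append(tex)

        t_base = rng.normal(env.t_mean, env.t_sd)
        t_soil[i] = t_base + env.t_amplitude * season + rng.normal(0.0, 0.5, N_DAYS)

        wet = np.clip(rng.normal(env.wetness, env.wetness_sd), 0.02, 0.98)
        k_series = np.clip(
            wet + 0.1 * np.sin(2.0 * np.pi * (day - 140.0) / N_DAYS)
            + rng.normal(0.0, 0.02, N_DAYS),
            0.0,
            1.0,
        )
        swc[i] = k_series * porosity

        npp[i] = max(rng.normal(env.npp_mean, env.npp_sd), 1.0)

    return SyntheticGrid(
        shape=shape,
        biome=assignment,
        texture=tuple(textures),
        t_soil=t_soil,
        swc=swc,
        npp=npp,
        seed=seed,
    )


FIXTURE_NAMES = ("one_pool", "chain_2", "chain_3", "full_13_default")


def fixture_system(name: str):
    """Hand-analyzable toy systems: returns (TransferSystem, xi, U).

    one_pool:  tau = 1/c.
    chain_2:   donor -> receiver with full transfer, tau = 1/c1 + 1/c2.
    chain_3:   three-pool cascade with a 0.6 transfer at the second step,
               tau = 1/c1 + 1/c2 + 0.6/c3.
    full_13_default: the shipped DBF parameterization on a loam texture.
    """
    if name == "one_pool":
        sys = TransferSystem(A=np.eye(1), C=np.diag([0.5]), B=np.array([1.0]))
        return sys, np.eye(1), 10.0
    if name == "chain_2":
        A = np.array([[1.0, 0.0], [-1.0, 1.0]])
        sys = TransferSystem(A=A, C=np.diag([0.5, 0.1]), B=np.array([1.0, 0.0]))
        return sys, np.eye(2), 5.0
    if name == "chain_3":
        A = np.array([[1.0, 0.0, 0.0], [-1.0, 1.0, 0.0], [0.0, -0.6, 1.0]])
        sys = TransferSystem(
            A=A, C=np.diag([1.0, 0.25, 0.05]), B=np.array([1.0, 0.0, 0.0])
        )
        return sys, np.eye(3), 2.0
    if name == "full_13_default":
        from .cli_io import default_parameter_table
        from .model_core import build_transfer_system

        params = default_parameter_table()["DBF"]
        texture = SoilTexture.from_clay_silt(0.2, 0.35, porosity=0.45)
        sys = build_transfer_system(params, texture)
        return sys, np.eye(N_POOLS), 500.0
    raise KeyError(f"unknown fixture {name!r}; registry: {FIXTURE_NAMES}")
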