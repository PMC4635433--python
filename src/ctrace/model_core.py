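"""13-pool carbon cycle structure: transfer matrix A, turnover matrix C, allocation vector B.

The pool system follows a CENTURY-lineage topology: four vegetation pools
shed carbon into five litter pools, whose decomposition products cascade
through four soil organic matter pools.  Matrix ``A`` carries the routing
fractions (diagonal +1, off-diagonal negative), diagonal matrix ``C`` the
potential (climate-unlimited) turnover rates in yr^-1, and vector ``B`` the
NPP allocation to the vegetation pools.  Neither ``A`` nor ``C`` depends on
climate; all forcing dependence lives in the environmental scalar matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "N_POOLS",
    "PoolLayout",
    "BiomeParameterSet",
    "SoilTexture",
    "TransferSystem",
    "metabolic_fraction",
    "build_allocation_vector",
    "build_transfer_matrix",
    "build_turnover_matrix",
    "build_transfer_system",
]

N_POOLS = 13

VEGETATION = "vegetation"
LITTER = "litter"
SOIL = "soil"

_POOL_NAMES = (
    "leaf",
    "woody",
    "fine_root",
    "coarse_root",
    "surface_metabolic",
    "surface_structural",
    "soil_metabolic",
    "soil_structural",
    "coarse_detritus",
    "surface_microbe",
    "soil_microbe",
    "slow",
    "passive",
)

_POOL_CLASSES = (
    (VEGETATION,) * 4 + (LITTER,) * 5 + (SOIL,) * 4
)


class ValidationError(ValueError):
    """Raised when a parameter set or matrix violates a structural invariant."""


@dataclass(frozen=True)
class PoolLayout:
    """Fixed ordering and classification of the 13 carbon pools.

    Vegetation pools occupy the first four indices so that the environmental
    scalar diagonal pattern (1, 1, 1, 1, xi, ..., xi) is well formed.
    """

    names: tuple[str, ...] = _POOL_NAMES
    class_of: Mapping[str, str] = field(
        default_factory=lambda: dict(zip(_POOL_NAMES, _POOL_CLASSES))
    )

    def __post_init__(self) -> None:
        if len(self.names) != N_POOLS:
            raise ValidationError(f"expected {N_POOLS} pools, got {len(self.names)}")
        counts = {VEGETATION: 0, LITTER: 0, SOIL: 0}
        for name in self.names:
            counts[self.class_of[name]] += 1
        if counts != {VEGETATION: 4, LITTER: 5, SOIL: 4}:
            raise ValidationError(f"bad pool class counts: {counts}")
        for i in range(4):
            if self.class_of[self.names[i]] != VEGETATION:
                raise ValidationError("vegetation pools must occupy indices 0-3")

    def index(self, name: str) -> int:
        return self.names.index(name)

    def indices_of(self, pool_class: str) -> list[int]:
        return [i for i, n in enumerate(self.names) if self.class_of[n] == pool_class]

    @property
    def vegetation_slice(self) -> slice:
        return slice(0, 4)


DEFAULT_LAYOUT = PoolLayout()


@dataclass(frozen=True)
class BiomeParameterSet:
    """Per-biome parameters: allocation, litter chemistry, potential turnover.

    ``b`` is ordered (leaf, wood, fine root, coarse root); ``c`` follows the
    pool layout order and is in yr^-1.
    """

    biome: str
    b: tuple[float, float, float, float]
    LN: float
    Lleaf: float
    Lfroot: float
    Lwood: float
    c: tuple[float, ...]

    def __post_init__(self) -> None:
        b = np.asarray(self.b, dtype=float)
        if b.shape != (4,):
            raise ValidationError(f"{self.biome}: b must have 4 entries")
        if np.any(b < 0):
            raise ValidationError(f"{self.biome}: allocation fractions must be >= 0")
        if abs(b.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"{self.biome}: allocation fractions sum to {b.sum():.6f}, expected 1"
            )
        if self.LN <= 0:
            raise ValidationError(f"{self.biome}: LN must be > 0")
        for nm, lg in (("Lleaf", self.Lleaf), ("Lfroot", self.Lfroot), ("Lwood", self.Lwood)):
            if not 0.0 < lg < 1.0:
                raise ValidationError(f"{self.biome}: {nm}={lg} outside (0,1)")
        c = np.asarray(self.c, dtype=float)
        if c.shape != (N_POOLS,):
            raise ValidationError(f"{self.biome}: c must have {N_POOLS} entries")
        if np.any(c <= 0):
            raise ValidationError(f"{self.biome}: turnover rates must be > 0")

    def c_array(self) -> np.ndarray:
        return np.asarray(self.c, dtype=float)

    def with_updates(self, **kwargs) -> "BiomeParameterSet":
        """Return a copy with the given fields replaced (used by sensitivity)."""
        data = {
            "biome": self.biome,
            "b": self.b,
            "LN": self.LN,
            "Lleaf": self.Lleaf,
            "Lfroot": self.Lfroot,
            "Lwood": self.Lwood,
            "c": self.c,
        }
        data.update(kwargs)
        return BiomeParameterSet(**data)


@dataclass(frozen=True)
class SoilTexture:
    """Mineral fractions of a soil cell; clay + silt + sand must equal 1."""

    clay: float
    silt: float
    sand: float
    porosity: float

    def __post_init__(self) -> None:
        total = self.clay + self.silt + self.sand
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(f"clay+silt+sand = {total:.8f}, expected 1")
        for nm, v in (("clay", self.clay), ("silt", self.silt), ("sand", self.sand)):
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{nm}={v} outside [0,1]")
        if not 0.0 < self.porosity < 1.0:
            raise ValidationError(f"porosity={self.porosity} outside (0,1)")

    @classmethod
    def from_clay_silt(cls, clay: float, silt: float, porosity: float = 0.45) -> "SoilTexture":
        return cls(clay=clay, silt=silt, sand=1.0 - clay - silt, porosity=porosity)


@dataclass(frozen=True)
class TransferSystem:
    """The (A, C, B) triple assembled for one grid cell / biome."""

    A: np.ndarray
    C: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        A, C, B = self.A, self.C, self.B
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValidationError("A must be square")
        n = A.shape[0]
        if C.shape != (n, n) or B.shape != (n,):
            raise ValidationError("A, C, B shapes inconsistent")
        if not np.allclose(np.diag(A), 1.0):
            raise ValidationError("A diagonal must be all ones")
        off = A - np.diag(np.diag(A))
        if np.any(off > 1e-12):
            raise ValidationError("A off-diagonal entries must be <= 0")
        col_out = -off.sum(axis=0)
        bad = np.where(col_out > 1.0 + 1e-9)[0]
        if bad.size:
            raise ValidationError(f"transfer fractions exceed 1 in columns {bad.tolist()}")
        if np.any(np.diag(C) <= 0) or not np.allclose(C, np.diag(np.diag(C))):
            raise ValidationError("C must be diagonal with positive entries")

    @property
    def n_pools(self) -> int:
        return self.A.shape[0]

    def respired_fractions(self) -> np.ndarray:
        """Per-donor-pool fraction of exiting carbon respired as CO2."""
        off = self.A - np.diag(np.diag(self.A))
        return 1.0 - (-off).sum(axis=0)


def metabolic_fraction(LN: float) -> float:
    """Fraction of fresh leaf/fine-root litter routed to the metabolic pool.

    Linear CENTURY-lineage form 0.85 - 0.018 * (L/N), clamped to [0, 1];
    the remainder enters the structural pool.
    """
    if LN <= 0:
        raise ValidationError(f"LN must be > 0, got {LN}")
    return float(np.clip(0.85 - 0.018 * LN, 0.0, 1.0))


def build_allocation_vector(
    params: BiomeParameterSet, layout: PoolLayout = DEFAULT_LAYOUT
) -> np.ndarray:
    """Return the 13-vector B: NPP allocation to the four vegetation pools."""
    B = np.zeros(N_POOLS)
    b = np.asarray(params.b, dtype=float)
    B[layout.index("leaf")] = b[0]
    B[layout.index("woody")] = b[1]
    B[layout.index("fine_root")] = b[2]
    B[layout.index("coarse_root")] = b[3]
    return B


# CENTURY-lineage routing efficiencies (the non-respired share of each flow).
_EFF_METABOLIC = 0.45          # metabolic litter -> microbe
_EFF_STRUCT_SURFACE = 0.55     # surface structural non-lignin -> surface microbe
_EFF_STRUCT_SOIL = 0.45        # soil structural non-lignin -> soil microbe
_EFF_LIGNIN_SLOW = 0.7         # structural/detritus lignin -> slow
_EFF_SURFACE_MICROBE = 0.4     # surface microbe -> slow
_EFF_PASSIVE_OUT = 0.45        # passive -> soil microbe


def build_transfer_matrix(
    params: BiomeParameterSet,
    texture: SoilTexture,
    layout: PoolLayout = DEFAULT_LAYOUT,
) -> np.ndarray:
    """Assemble the 13x13 transfer matrix A.

    Routing topology: leaf splits into surface metabolic/structural by the
    L/N-controlled metabolic fraction, fine root likewise into the soil
    litter pools, woody and coarse root go wholly to coarse detritus.
    Litter-to-soil and soil-to-soil fractions carry the lignin-content and
    clay/silt texture modifiers; the unrouted remainder of each donor column
    is respired CO2.
    """
    ix = layout.index
    A = np.eye(N_POOLS)

    def route(donor: str, receiver: str, frac: float) -> None:
        A[ix(receiver), ix(donor)] -= frac

    fm = metabolic_fraction(params.LN)
    # Vegetation pools transfer their whole exiting flux (no CO2 at litterfall).
    route("leaf", "surface_metabolic", fm)
    route("leaf", "surface_structural", 1.0 - fm)
    route("fine_root", "soil_metabolic", fm)
    route("fine_root", "soil_structural", 1.0 - fm)
    route("woody", "coarse_detritus", 1.0)
    route("coarse_root", "coarse_detritus", 1.0)

    route("surface_metabolic", "surface_microbe", _EFF_METABOLIC)
    route("soil_metabolic", "soil_microbe", _EFF_METABOLIC)
    route("surface_structural", "surface_microbe", _EFF_STRUCT_SURFACE * (1.0 - params.Lleaf))
    route("surface_structural", "slow", _EFF_LIGNIN_SLOW * params.Lleaf)
    route("soil_structural", "soil_microbe", _EFF_STRUCT_SOIL * (1.0 - params.Lfroot))
    route("soil_structural", "slow", _EFF_LIGNIN_SLOW * params.Lfroot)
    route("coarse_detritus", "soil_microbe", _EFF_STRUCT_SOIL * (1.0 - params.Lwood))
    route("coarse_detritus", "slow", _EFF_LIGNIN_SLOW * params.Lwood)

    route("surface_microbe", "slow", _EFF_SURFACE_MICROBE)

    # Soil microbe respiration rises with sandiness: f(clay_silt).
    clay_silt = texture.clay + texture.silt
    microbe_out = 0.15 + 0.68 * clay_silt          # non-respired share
    to_passive = 0.003 + 0.032 * texture.clay      # f(clay)
    route("soil_microbe", "passive", to_passive)
    route("soil_microbe", "slow", microbe_out - to_passive)

    slow_to_passive = 0.003 + 0.009 * texture.clay
    route("slow", "passive", slow_to_passive)
    route("slow", "soil_microbe", 0.45 - slow_to_passive)

    route("passive", "soil_microbe", _EFF_PASSIVE_OUT)

    off = A - np.eye(N_POOLS)
    col_out = -off.sum(axis=0)
    bad = np.where(col_out > 1.0 + 1e-9)[0]
    if bad.size:
        names = [layout.names[i] for i in bad]
        raise ValidationError(f"column transfer sum exceeds 1 for pools {names}")
    return A


def build_turnover_matrix(params: BiomeParameterSet) -> np.ndarray:
    """Diagonal 13x13 matrix of potential turnover rates (yr^-1)."""
    c = params.c_array()
    if np.any(c <= 0):
        raise ValidationError(f"{params.biome}: turnover rates must be > 0")
    return np.diag(c)


def build_transfer_system(
    params: BiomeParameterSet,
    texture: SoilTexture,
    layout: PoolLayout = DEFAULT_LAYOUT,
) -> TransferSystem:
    """Assemble the full (A, C, B) triple for one cell."""
    return TransferSystem(
        A=build_transfer_matrix(params, texture, layout),
        C=build_turnover_matrix(params),
        B=build_allocation_vector(params, layout),
    )
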