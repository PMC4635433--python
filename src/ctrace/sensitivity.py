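"""Relative (elasticity-style) sensitivity of baseline residence time.

S = [(O(p*(1+d)) - O(p*(1-d))) / O(p)] / (2d): the relative change in output
per relative change in the parameter, by symmetric central difference.  A
parameter is classified sensitive when |S| exceeds 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model_core import (
    BiomeParameterSet,
    SoilTexture,
    ValidationError,
    build_transfer_system,
)
from .steady_state import baseline_residence_time

__all__ = [
    "SENSITIVE_THRESHOLD",
    "SensitivityResult",
    "sensitivity_index",
    "sensitivity_screen",
    "DEFAULT_SCREEN_PARAMETERS",
]

SENSITIVE_THRESHOLD = 0.2
DEFAULT_DELTA = 0.10
DEFAULT_SCREEN_PARAMETERS = ("LN", "Lleaf", "Lfroot", "Lwood", "clay", "silt")


class UndefinedSensitivityError(ZeroDivisionError):
    """Raised when the base output is zero and S is undefined."""


@dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    S: float
    perturbation: float

    @property
    def sensitive(self) -> bool:
        return abs(self.S) > SENSITIVE_THRESHOLD


def sensitivity_index(
    model_fn: Callable[[Mapping[str, float]], float],
    param: str,
    base: Mapping[str, float],
    delta: float = DEFAULT_DELTA,
) -> SensitivityResult:
    """Central-difference relative sensitivity of ``model_fn`` to ``param``.

    ``base`` maps parameter names to values; the chosen parameter is scaled
    by (1 +/- delta) while the rest stay fixed.
    """
    if delta <= 0:
        raise ValidationError(f"delta must be > 0, got {delta}")
    if param not in base:
        raise KeyError(f"parameter {param!r} not in base set {sorted(base)}")
    o_base = model_fn(dict(base))
    if o_base == 0:
        raise UndefinedSensitivityError(f"model output is 0 at base point for {param!r}")
    up = dict(base)
    up[param] = base[param] * (1.0 + delta)
    down = dict(base)
    down[param] = base[param] * (1.0 - delta)
    s = (model_fn(up) - model_fn(down)) / o_base / (2.0 * delta)
    return SensitivityResult(parameter=param, S=float(s), perturbation=delta)


def _clamp_fraction(x: float) -> float:
    return float(np.clip(x, 1e-6, 1.0 - 1e-6))


def _tau_baseline_model(
    params: BiomeParameterSet, texture: SoilTexture
) -> Callable[[Mapping[str, float]], float]:
    """Model closure: bundle of perturbable inputs -> baseline residence time.

    Lignin fractions are re-clamped into (0, 1) and the sand fraction is
    recomputed so texture stays on the simplex after perturbation.
    """

    def model(bundle: Mapping[str, float]) -> float:
        p = params.with_updates(
            LN=max(bundle["LN"], 1e-6),
            Lleaf=_clamp_fraction(bundle["Lleaf"]),
            Lfroot=_clamp_fraction(bundle["Lfroot"]),
            Lwood=_clamp_fraction(bundle["Lwood"]),
        )
        clay = float(np.clip(bundle["clay"], 0.0, 1.0))
        silt = float(np.clip(bundle["silt"], 0.0, 1.0 - clay))
        tex = SoilTexture(
            clay=clay, silt=silt, sand=1.0 - clay - silt, porosity=texture.porosity
        )
        return baseline_residence_time(build_transfer_system(p, tex))

    return model


def base_bundle(params: BiomeParameterSet, texture: SoilTexture) -> dict[str, float]:
    return {
        "LN": params.LN,
        "Lleaf": params.Lleaf,
        "Lfroot": params.Lfroot,
        "Lwood": params.Lwood,
        "clay": texture.clay,
        "silt": texture.silt,
    }


def sensitivity_screen(
    biomes: Sequence[str],
    parameters: Sequence[str] = DEFAULT_SCREEN_PARAMETERS,
    delta: float = DEFAULT_DELTA,
    parameter_table: Mapping[str, BiomeParameterSet] | None = None,
    texture: SoilTexture | None = None,
) -> pd.DataFrame:
    """Full biomes x parameters sensitivity table for baseline residence time.

    Returns a DataFrame with columns biome, parameter, S, abs_S, rank (1 =
    largest |S| within the biome), perturbation, sensitive.
    """
    if parameter_table is None:
        from .cli_io import default_parameter_table

        parameter_table = default_parameter_table()
    if texture is None:
        texture = SoilTexture.from_clay_silt(0.20, 0.35, porosity=0.45)

    rows = []
    for biome in biomes:
        params = parameter_table[biome]
        model = _tau_baseline_model(params, texture)
        bundle = base_bundle(params, texture)
        for param in parameters:
            res = sensitivity_index(model, param, bundle, delta=delta)
            rows.append(
                {
                    "biome": biome,
                    "parameter": param,
                    "S": res.S,
                    "abs_S": abs(res.S),
                    "perturbation": delta,
                    "sensitive": res.sensitive,
                }
            )
    df = pd.DataFrame(rows)
    df["rank"] = (
        df.groupby("biome")["abs_S"].rank(ascending=False, method="first").astype(int)
    )
    return df
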