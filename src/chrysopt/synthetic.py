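"""Synthetic transformation-protocol datasets with known ground truth.

The generator emulates the statistical shape of the literature database: one
categorical factor (strain) with additive per-level effects, ten
non-negative continuous factors on realistic dose/density/duration scales
(antibiotic doses are structurally zero in a fraction of rows, as most
studies use only a subset of antibiotics), and a smooth unimodal response

    efficiency = base + strain_effect + sum_j w_j * exp(-(v_j - o_j)^2 / (2 tau_j^2)) + noise

clipped to [0, 100].  Because the surface is a separable sum of Gaussian
bumps, its argmax (best strain level plus per-factor optima) and maximum are
known in closed form, giving every downstream stage — model fit, fusion,
FOA optimum recovery, VSR ranking — an exact oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from chrysopt.database import FEATURE_NAMES

__all__ = ["ContinuousFactor", "SyntheticConfig", "GroundTruth", "generate", "true_optimum"]


@dataclass(frozen=True)
class ContinuousFactor:
    name: str
    bounds: tuple[float, float]
    optimum: float
    weight: float  # bump amplitude, percentage points
    rel_width: float = 0.25  # tau as a fraction of the range
    zero_prob: float = 0.0  # fraction of rows with the factor structurally 0

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not (lo <= self.optimum <= hi):
            raise ValueError(f"{self.name}: optimum {self.optimum} outside {self.bounds}")
        if self.weight < 0:
            raise ValueError(f"{self.name}: weight must be >= 0")

    @property
    def tau(self) -> float:
        lo, hi = self.bounds
        return max(self.rel_width * (hi - lo), 1e-9)

    def bump(self, v: np.ndarray) -> np.ndarray:
        return self.weight * np.exp(-((v - self.optimum) ** 2) / (2.0 * self.tau**2))


def _default_factors() -> tuple[ContinuousFactor, ...]:
    # scales mirror the literature table: OD 0.1-2.2, CCP 1-8 days,
    # selection antibiotics in mg/L, counter-selection in ug/mL
    return (
        ContinuousFactor("OD", (0.1, 2.2), 0.9, 3.0),
        ContinuousFactor("CCP", (1.0, 8.0), 3.8, 8.0),
        ContinuousFactor("K", (0.0, 100.0), 10.0, 6.0, zero_prob=0.3),
        ContinuousFactor("H", (0.0, 40.0), 18.0, 2.0, zero_prob=0.5),
        ContinuousFactor("P", (0.0, 50.0), 46.0, 4.0, zero_prob=0.5),
        ContinuousFactor("G", (0.0, 30.0), 5.0, 1.0, zero_prob=0.5),
        ContinuousFactor("VA", (0.0, 500.0), 110.0, 3.5, zero_prob=0.5),
        ContinuousFactor("CF", (0.0, 500.0), 290.0, 5.0, zero_prob=0.3),
        ContinuousFactor("CA", (0.0, 500.0), 330.0, 2.5, zero_prob=0.5),
        ContinuousFactor("TI", (0.0, 500.0), 87.0, 1.5, zero_prob=0.5),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Defaults are the study conditions of the recovery experiments:
    n = 500 rows, noise_sd = 2 percentage points, a dominant categorical
    (strain) effect and heterogeneous continuous effect sizes."""

    n: int = 500
    strain_effects: tuple[float, ...] = (0.0, 3.0, 7.0, 12.0)
    factors: tuple[ContinuousFactor, ...] = field(default_factory=_default_factors)
    base: float = 5.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 20:
            raise ValueError("n must be >= 20")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def strain_labels(self) -> tuple[str, ...]:
        return tuple(f"S{k + 1}" for k in range(len(self.strain_effects)))


@dataclass
class GroundTruth:
    config: SyntheticConfig
    best_strain: str
    optimum_inputs: dict[str, float]  # original units; strain as level index
    optimum_value: float
    effect_sizes: dict[str, float]  # comparable effect magnitude per variable
    clip_fraction: float

    def surface(self, strain_idx: np.ndarray, values: np.ndarray) -> np.ndarray:
        """Noiseless response; values has one column per continuous factor."""
        effects = np.asarray(self.config.strain_effects)[
            np.asarray(strain_idx, dtype=int)
        ]
        out = self.config.base + effects
        for j, f in enumerate(self.config.factors):
            out = out + f.bump(values[:, j])
        return out

    def dominant_variable(self) -> str:
        return max(self.effect_sizes, key=self.effect_sizes.get)

    def effect_ordering(self) -> list[str]:
        return sorted(self.effect_sizes, key=self.effect_sizes.get, reverse=True)


def true_optimum(config: SyntheticConfig) -> tuple[dict[str, float], float]:
    """Closed-form argmax of the noiseless surface and its value."""
    best_level = int(np.argmax(config.strain_effects))
    inputs = {"strain": float(best_level)}
    value = config.base + config.strain_effects[best_level]
    for f in config.factors:
        inputs[f.name] = f.optimum
        value += f.weight
    return inputs, min(value, 100.0)


def generate(config: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Sample rows in the resolved-database schema plus the ground truth.

    Strain labels are sampled uniformly; continuous factors are uniform in
    their bounds, with antibiotics zeroed with their structural-zero
    probability.  Noise is additive Gaussian; efficiencies are clipped to
    [0, 100] and the clip fraction is recorded so tests can keep it small.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    strain_idx = rng.integers(0, len(config.strain_effects), size=n)
    values = np.column_stack(
        [rng.uniform(f.bounds[0], f.bounds[1], size=n) for f in config.factors]
    )
    for j, f in enumerate(config.factors):
        if f.zero_prob > 0:
            values[rng.random(n) < f.zero_prob, j] = 0.0

    inputs, opt_value = true_optimum(config)
    effect_sizes = {
        "strain": float(np.ptp(config.strain_effects)),
        **{f.name: f.weight for f in config.factors},
    }
    truth = GroundTruth(
        config=config,
        best_strain=config.strain_labels[int(inputs["strain"])],
        optimum_inputs=inputs,
        optimum_value=opt_value,
        effect_sizes=effect_sizes,
        clip_fraction=0.0,
    )
    clean = truth.surface(strain_idx, values)
    noisy = clean + rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd else clean
    clipped = np.clip(noisy, 0.0, 100.0)
    truth.clip_fraction = float(np.mean(clipped != noisy))

    frame = pd.DataFrame(values, columns=[f.name for f in config.factors])
    frame.insert(0, "strain", [config.strain_labels[k] for k in strain_idx])
    frame["efficiency"] = clipped
    frame["od_wavelength_nm"] = 600
    frame["record_index"] = np.arange(n)
    # canonical column order shared with the resolved literature rows
    ordered = ["strain"] + [f.name for f in config.factors]
    frame = frame[ordered + ["efficiency", "od_wavelength_nm", "record_index"]]
    return frame, truth
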