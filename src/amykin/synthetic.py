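"""Seeded generators for the study's two data modalities.

The raw measurements behind the published kinetics and morphometry are not
deposited, so this module generates stand-ins with fully specified
distributions:

* ThT fluorescence time courses: the closed-form sigmoid of the
  autocatalytic model plus additive Gaussian noise (SD expressed relative
  to the amplitude dF, truncated below at zero intensity), sampled by
  default on the experimental 0/6/12/24/36/48 h schedule or any denser grid.
* AFM particle tables: mixtures of aggregate species, each with a
  log-normal length (strictly positive, right-skewed, as in AFM length
  data) and a zero-truncated normal height (narrow and near-symmetric).

Presets keyed by experimental condition reproduce the published bin
percentages by construction; they are emulation constants, not inferences.
All generators are deterministic given their seed; replicates draw from
independent spawned substreams of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .kinetics import KineticRates, ValidationError, fibril_fraction, reduce_rates
from .fitting import ThTTimeCourse
from .morphology import Particle

__all__ = [
    "NoiseSpec",
    "SpeciesDist",
    "MorphMixtureSpec",
    "DEFAULT_SCHEDULE_H",
    "simulate_tht",
    "simulate_particles",
    "paper_like_mixture",
    "preset_conditions",
]

#: the experimental sampling schedule, hours
DEFAULT_SCHEDULE_H = (0.0, 6.0, 12.0, 24.0, 36.0, 48.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive intensity noise: SD = sigma_rel * dF, truncated at 0 intensity."""

    sigma_rel: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.sigma_rel < 0.5):
            raise ValidationError("sigma_rel must lie in [0, 0.5)")


@dataclass(frozen=True)
class SpeciesDist:
    """Length/height distribution of one aggregate species.

    Length ~ LogNormal(ln median, sigma_log); height ~ Normal(mean, sd)
    truncated at 0.
    """

    length_median_nm: float
    length_sigma_log: float
    height_mean_nm: float
    height_sd_nm: float

    def __post_init__(self) -> None:
        if self.length_median_nm <= 0 or self.height_mean_nm <= 0:
            raise ValidationError("medians/means must be > 0")
        if self.length_sigma_log < 0 or self.height_sd_nm < 0:
            raise ValidationError("spreads must be >= 0")


@dataclass(frozen=True)
class MorphMixtureSpec:
    """Weighted mixture of aggregate species with a sampling seed."""

    species: dict[str, SpeciesDist]
    weights: dict[str, float]
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if set(self.species) != set(self.weights):
            raise ValidationError("species and weights must share the same keys")
        w = np.array([self.weights[s] for s in self.weights], dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError("weights must be >= 0 and sum to 1")


def simulate_tht(
    rates: KineticRates,
    times_s,
    noise: NoiseSpec | None = None,
    n_replicates: int = 1,
    F0: float = 50.0,
    dF: float = 400.0,
    condition: str = "",
) -> list[ThTTimeCourse]:
    """Simulate noisy ThT traces F(t) = F0 + dF * f(t) + eps.

    eps ~ Normal(0, sigma_rel * dF) i.i.d. per point, and the resulting
    intensity is truncated below at 0 (a fluorimeter cannot read negative).
    Replicate r draws from the r-th spawned child of ``noise.seed`` via
    numpy's SeedSequence, so runs are bit-for-bit reproducible and
    replicates are independent.
    """
    noise = noise or NoiseSpec()
    t = np.asarray(times_s, dtype=float)
    if t.ndim != 1 or t.size == 0 or np.any(np.diff(t) <= 0) or t[0] < 0:
        raise ValidationError("times_s must be non-empty, >= 0 and strictly increasing")
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    f = fibril_fraction(reduce_rates(rates), t)
    clean = F0 + dF * f
    streams = np.random.SeedSequence(noise.seed).spawn(n_replicates)
    out = []
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        eps = rng.normal(0.0, noise.sigma_rel * dF, size=t.shape) if noise.sigma_rel > 0 else 0.0
        y = np.maximum(clean + eps, 0.0)
        out.append(
            ThTTimeCourse(times=t, intensities=y, condition=condition, replicate=f"rep{r + 1}")
        )
    return out


def simulate_particles(mix: MorphMixtureSpec, n: int) -> list[Particle]:
    """Draw n particles: species by categorical weight, then length and height
    independently from that species' distributions.  Deterministic per seed."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(mix.seed)
    names = sorted(mix.species)
    w = np.array([mix.weights[s] for s in names], dtype=float)
    idx = rng.choice(len(names), size=n, p=w)
    particles = []
    for i in idx:
        d = mix.species[names[i]]
        length = float(np.exp(rng.normal(math.log(d.length_median_nm), d.length_sigma_log)))
        height = -1.0
        while height <= 0:  # truncate the normal at 0
            height = float(rng.normal(d.height_mean_nm, d.height_sd_nm))
        particles.append(Particle(length=length, height=height, condition=mix.label))
    return particles


def _load_presets() -> dict:
    text = resources.files("amykin.data").joinpath("morphology_presets.yaml").read_text()
    return yaml.safe_load(text)


def preset_conditions() -> list[str]:
    """Names of the available condition presets."""
    return sorted(_load_presets()["presets"])


def paper_like_mixture(condition: str, seed: int = 0) -> MorphMixtureSpec:
    """Preset particle mixture for one experimental condition.

    Conditions: alone_12h, alone_24h, dopc_24h, chol_12h, chol_24h, 7keto_24h.
    The presets are frozen constants (see the packaged YAML) whose analytic
    bin mass matches the published length/height percentages within a few
    percentage points.
    """
    cfg = _load_presets()
    if condition not in cfg["presets"]:
        valid = ", ".join(sorted(cfg["presets"]))
        raise ValidationError(f"unknown condition {condition!r}; valid conditions: {valid}")
    lib = {
        name: SpeciesDist(**params) for name, params in cfg["species_library"].items()
    }
    weights = cfg["presets"][condition]
    return MorphMixtureSpec(
        species={s: lib[s] for s in weights},
        weights=dict(weights),
        seed=seed,
        label=condition,
    )
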