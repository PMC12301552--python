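"""Synthetic study generation emulating a clinical-pathology panel.

Raw per-animal data behind the packaged panel are unavailable, so tests and
demonstrations run on synthetic studies instead: per-sex draws from simple
families moment-matched to the panel's printed mean/SD, with optional gross
outlier contamination and per-cell missingness.  Identical seeds produce
byte-identical tables.

Family heuristics (unknowable from summaries, flagged as such): measurands
printed as non-Gaussian default to a lognormal with matched first two
moments; Gaussian-labelled and unlabelled ones to a normal.  Values below a
physical floor (zero for concentrations) are redrawn, not truncated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .model import StudyTable, stable_substream_seed
from .panel import PANEL_ROWS, PanelRow

__all__ = [
    "MeasurandSpec",
    "StudyConfig",
    "generate_measurand",
    "generate_study",
    "default_measurand_specs",
    "default_study_config",
]

_FAMILIES = ("gaussian", "lognormal", "gamma")


@dataclass(frozen=True)
class MeasurandSpec:
    """Generative recipe for one measurand.

    ``params`` maps a sex label to its (mean, sd) on the observation scale;
    a missing label falls back to the first entry.  ``contamination`` is
    ``(epsilon, shift)``: each draw is displaced by ``shift * sd`` with
    probability epsilon.
    """

    name: str
    unit: str
    family: str
    params: Mapping[str, tuple[float, float]]
    missing_rate: float = 0.0
    contamination: tuple[float, float] = (0.0, 0.0)
    floor: float | None = 0.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigError(f"{self.name}: unknown family {self.family!r}")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigError(f"{self.name}: missing_rate outside [0, 1]")
        eps, _shift = self.contamination
        if not 0.0 <= eps <= 1.0:
            raise ConfigError(f"{self.name}: contamination epsilon outside [0, 1]")
        for sex, (mean, sd) in self.params.items():
            if sd < 0:
                raise ConfigError(f"{self.name}/{sex}: sd must be >= 0")

    def params_for(self, sex: str) -> tuple[float, float]:
        if sex in self.params:
            return self.params[sex]
        return next(iter(self.params.values()))


@dataclass(frozen=True)
class StudyConfig:
    """Cohort layout and per-measurand recipes for one synthetic study."""

    specs: tuple[MeasurandSpec, ...]
    n_male: int = 61
    n_female: int = 31
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_male < 0 or self.n_female < 0:
            raise ConfigError("cohort sizes must be non-negative")
        if not self.specs:
            raise ConfigError("at least one measurand spec required")
        object.__setattr__(self, "specs", tuple(self.specs))

    @property
    def n_animals(self) -> int:
        return self.n_male + self.n_female


def _base_draw(
    family: str, mean: float, sd: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    if sd == 0.0:
        return np.full(n, mean)
    if family == "gaussian":
        return rng.normal(mean, sd, size=n)
    if mean <= 0.0:
        # Moment matching of positive families needs a positive mean.
        return rng.normal(mean, sd, size=n)
    if family == "lognormal":
        sigma2 = math.log1p((sd / mean) ** 2)
        mu = math.log(mean) - sigma2 / 2.0
        return rng.lognormal(mu, math.sqrt(sigma2), size=n)
    # gamma: shape/scale from the first two moments
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return rng.gamma(shape, scale, size=n)


def generate_measurand(
    spec: MeasurandSpec,
    n: int,
    seed: int | np.random.Generator,
    sex: str = "M",
    return_outlier_mask: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` values for one sex; deterministic in (spec, n, seed, sex).

    Base draws falling below the physical floor are redrawn so the family
    shape is approximately preserved; contamination displaces each value by
    ``shift * sd`` with probability epsilon, applied after flooring so gross
    outliers survive.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(stable_substream_seed(seed, spec.name, sex))
    )
    mean, sd = spec.params_for(sex)
    values = _base_draw(spec.family, mean, sd, n, rng)
    if spec.floor is not None and sd > 0.0:
        for _ in range(1000):
            below = values < spec.floor
            if not below.any():
                break
            values[below] = _base_draw(spec.family, mean, sd, int(below.sum()), rng)
        else:
            values = np.maximum(values, spec.floor)
    eps, shift = spec.contamination
    mask = np.zeros(n, dtype=bool)
    if eps > 0.0 and sd > 0.0:
        mask = rng.random(n) < eps
        values = values + mask * shift * sd
    if return_outlier_mask:
        return values, mask
    return values


def generate_study(config: StudyConfig) -> tuple[StudyTable, dict]:
    """Build a long-format synthetic study plus its ground-truth log.

    Missingness is independent per (animal, measurand) cell, so each
    measurand ends up with its own analyzable n — matching how real panels
    lose individual assays, not whole animals.
    """
    sexes = ["M"] * config.n_male + ["F"] * config.n_female
    width = max(3, len(str(config.n_animals)))
    animal_ids = [f"A{i + 1:0{width}d}" for i in range(config.n_animals)]
    by_sex: dict[str, list[int]] = {"M": [], "F": []}
    for i, s in enumerate(sexes):
        by_sex[s].append(i)

    rows: list[dict] = []
    truth: dict = {
        "seed": config.seed,
        "n_male": config.n_male,
        "n_female": config.n_female,
        "measurands": {},
    }
    for spec in config.specs:
        entry: dict = {
            "family": spec.family,
            "params": {s: list(p) for s, p in spec.params.items()},
            "missing_rate": spec.missing_rate,
            "contamination": list(spec.contamination),
            "floor": spec.floor,
            "outlier_animal_ids": [],
            "missing_animal_ids": [],
        }
        for sex in ("M", "F"):
            idx = by_sex[sex]
            if not idx:
                continue
            rng = np.random.default_rng(
                stable_substream_seed(config.seed, spec.name, sex)
            )
            values, mask = generate_measurand(
                spec, len(idx), rng, sex=sex, return_outlier_mask=True
            )
            missing = rng.random(len(idx)) < spec.missing_rate
            for j, animal_pos in enumerate(idx):
                aid = animal_ids[animal_pos]
                if missing[j]:
                    entry["missing_animal_ids"].append(aid)
                    continue
                if mask[j]:
                    entry["outlier_animal_ids"].append(aid)
                rows.append(
                    {
                        "animal_id": aid,
                        "sex": sex,
                        "measurand": spec.name,
                        "unit": spec.unit,
                        "value": float(values[j]),
                    }
                )
        truth["measurands"][spec.name] = entry
    df = pd.DataFrame(rows, columns=["animal_id", "sex", "measurand", "unit", "value"])
    return StudyTable(df=df, partition_columns=("sex",)), truth


def _family_for(row: PanelRow) -> str:
    if row.sd in (None, 0.0):
        return "gaussian"
    return "lognormal" if row.distribution == "NG" else "gaussian"


def default_measurand_specs(
    contamination: tuple[float, float] = (0.02, 6.0),
    cohort_size: int = 92,
    rows: Iterable[PanelRow] = PANEL_ROWS,
) -> tuple[MeasurandSpec, ...]:
    """Specs emulating the packaged panel's printed per-sex summaries.

    The per-measurand missing rate is chosen so the expected analyzable n
    matches the printed pooled n; family labels follow the printed
    distribution flag (a heuristic — the true families are unknowable from
    summaries).
    """
    by_name: dict[str, dict[str, PanelRow]] = {}
    order: list[str] = []
    for row in rows:
        if row.measurand not in by_name:
            by_name[row.measurand] = {}
            order.append(row.measurand)
        by_name[row.measurand][row.sex] = row
    specs = []
    for name in order:
        group = by_name[name]
        all_row = group.get("All") or next(iter(group.values()))
        params: dict[str, tuple[float, float]] = {}
        for sex in ("M", "F"):
            row = group.get(sex)
            if row is not None and row.mean is not None and row.sd is not None:
                params[sex] = (row.mean, row.sd)
        if not params and all_row.mean is not None:
            params = {"M": (all_row.mean, all_row.sd or 0.0)}
        if not params:
            continue
        missing_rate = max(0.0, 1.0 - all_row.n / cohort_size)
        floor = None if (all_row.min is not None and all_row.min < 0) else 0.0
        eps, shift = contamination
        sd_all = all_row.sd or 0.0
        specs.append(
            MeasurandSpec(
                name=name,
                unit=all_row.unit,
                family=_family_for(all_row),
                params=params,
                missing_rate=missing_rate,
                contamination=(eps if sd_all > 0 else 0.0, shift),
                floor=floor,
            )
        )
    return tuple(specs)


def default_study_config(seed: int = 0) -> StudyConfig:
    """The packaged default: 92 animals (61 M / 31 F), full panel."""
    return StudyConfig(specs=default_measurand_specs(), seed=seed)
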