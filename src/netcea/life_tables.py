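"""Age-indexed background mortality from a period life table.

The Markov model needs an annual probability of death "for other reasons" at
every cohort age.  This module reads and writes two-column (age, qx) CSV life
tables, applies an optional relative-risk multiplier, and can synthesize a
Gompertz–Makeham table whose defaults approximate an adult US period
mortality curve.  A synthetic table covering ages 0–100 is bundled with the
package so the base case runs without any download; it is an approximation,
not a published vintage.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "load_life_table",
    "save_life_table",
    "background_death_prob",
    "synth_life_table",
    "load_bundled",
]

BUNDLED_NAME = "synthetic_us_life_table.csv"


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities qx indexed by contiguous integer ages."""

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.size == 0:
            raise ValueError("life table is empty")
        if ages.size != qx.size:
            raise ValueError("ages and qx must have equal length")
        if not np.array_equal(ages, np.arange(ages[0], ages[0] + ages.size)):
            raise ValueError("ages must be contiguous integers without duplicates")
        if np.any((qx < 0.0) | (qx > 1.0)) or not np.all(np.isfinite(qx)):
            raise ValueError("every qx must lie in [0, 1]")

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def q(self, age: int) -> float:
        """Annual death probability at integer ``age``."""
        if not (self.min_age <= age <= self.max_age):
            raise ValueError(
                f"age {age} outside life-table range [{self.min_age}, {self.max_age}]"
            )
        return float(self.qx[int(age) - self.min_age])

    def q_slice(self, start_age: int, stop_age: int) -> np.ndarray:
        """qx for ages start_age .. stop_age-1 (one value per model cycle)."""
        if start_age < self.min_age or stop_age - 1 > self.max_age:
            raise ValueError(
                f"ages [{start_age}, {stop_age - 1}] not covered by life table "
                f"[{self.min_age}, {self.max_age}]"
            )
        i = start_age - self.min_age
        return self.qx[i : i + (stop_age - start_age)].copy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.qx})


def load_life_table(path: str | Path) -> LifeTable:
    """Read a two-column (age, qx) CSV life table; a header row is optional."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"life table not found: {path}")
    first = path.read_text().splitlines()[0] if path.stat().st_size else ""
    has_header = any(c.isalpha() for c in first)
    df = pd.read_csv(path, header=0 if has_header else None)
    if df.shape[1] < 2:
        raise ValueError("life table needs two columns: age, qx")
    ages = df.iloc[:, 0].to_numpy()
    if not np.allclose(ages, np.round(ages)):
        raise ValueError("ages must be integers")
    order = np.argsort(ages)
    return LifeTable(ages=np.round(ages[order]).astype(int), qx=df.iloc[:, 1].to_numpy()[order])


def save_life_table(lt: LifeTable, path: str | Path) -> None:
    lt.to_frame().to_csv(path, index=False)


def background_death_prob(lt: LifeTable, age: int, rr: float = 1.0) -> float:
    """Life-table death probability at ``age`` scaled by relative risk ``rr``.

    The product is clamped to [0, 1]; rr = 0 switches background mortality off.
    """
    if rr < 0.0:
        raise ValueError(f"relative risk must be non-negative, got {rr!r}")
    return min(1.0, lt.q(age) * rr)


def synth_life_table(
    a: float = 5e-4, b: float = 3e-5, c: float = 0.09, max_age: int = 100
) -> LifeTable:
    """Gompertz–Makeham synthetic life table: qx(age) = min(1, a + b·e^(c·age)).

    The defaults (a = 5e-4, b = 3e-5, c = 0.09) put adult qx values in the
    range of a recent US period life table (about 1e-3 at age 30, 5e-2 at 80).
    qx at ``max_age`` is forced to 1 so the model horizon is well defined.
    """
    if a < 0.0:
        raise ValueError("Makeham constant a must be non-negative")
    if b <= 0.0 or c <= 0.0:
        raise ValueError("Gompertz parameters b and c must be positive")
    ages = np.arange(0, max_age + 1)
    qx = np.minimum(1.0, a + b * np.exp(c * ages))
    qx[-1] = 1.0
    return LifeTable(ages=ages, qx=qx)


def load_bundled() -> LifeTable:
    """Load the synthetic US-style life table shipped with the package."""
    with resources.as_file(
        resources.files("netcea").joinpath("data", BUNDLED_NAME)
    ) as path:
        return load_life_table(path)
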