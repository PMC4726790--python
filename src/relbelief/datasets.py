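"""Packaged example data and the synthetic-data generator.

The coin-flip example dataset is 20 Bernoulli observations (8 successes)
drawn from a Bernoulli(1/2); paired with a beta(4, 4) prior it exercises
every inferential quantity in the package with known reference values.
The generator produces reproducible Bernoulli or normal samples from an
explicit integer seed — no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["coin_flips", "SyntheticSpec", "generate_data", "load_data"]

_COIN_FLIPS = "11000000001111010010"


def coin_flips() -> np.ndarray:
    """The packaged 20-flip example dataset (8 ones, mean 0.400)."""
    return np.array([int(c) for c in _COIN_FLIPS], dtype=float)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a reproducible synthetic dataset.

    family : "bernoulli" (theta = success probability in (0, 1)) or
             "normal" (mu = true mean; unit variance unless sigma_sq set)
    """

    family: str
    param: float
    n: int
    seed: int
    sigma_sq: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("bernoulli", "normal"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if self.family == "bernoulli" and not (0 < self.param < 1):
            raise ValueError("Bernoulli parameter must lie in (0, 1)")
        if self.sigma_sq <= 0:
            raise ValueError("sigma_sq must be positive")


def generate_data(spec: SyntheticSpec) -> np.ndarray:
    """Draw a dataset according to the spec; identical for identical seeds."""
    rng = np.random.default_rng(spec.seed)
    if spec.family == "bernoulli":
        return rng.binomial(1, spec.param, size=spec.n).astype(float)
    return rng.normal(spec.param, np.sqrt(spec.sigma_sq), size=spec.n)


def load_data(source: str | Path | Sequence[float]) -> np.ndarray:
    """Load observations from a file path, an inline string, or a sequence.

    Files hold one value per line (CSV-style single column).  A bare
    digit string such as "11000000001111010010" — inline or as the whole
    file content — is split into single-character 0/1 observations.
    """
    if isinstance(source, (list, tuple, np.ndarray)):
        return np.asarray(source, dtype=float)
    text: str
    p = Path(str(source))
    if p.exists() and p.is_file():
        text = p.read_text().strip()
    else:
        text = str(source).strip()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if len(lines) == 1 and set(lines[0]) <= {"0", "1"} and len(lines[0]) > 1:
        return np.array([int(c) for c in lines[0]], dtype=float)
    try:
        return np.array([float(ln.split(",")[0]) for ln in lines], dtype=float)
    except ValueError as exc:
        raise ValueError(f"could not parse data source: {exc}") from exc
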