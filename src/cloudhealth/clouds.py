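"""Normal cloud concepts and forward cloud generators.

A normal cloud represents a qualitative concept by three digital features:
the expectation ``Ex`` (the value most representative of the concept), the
entropy ``En`` (the concept's spread over the universe of discourse) and the
hyper-entropy ``He`` (the spread of the spread, i.e. second-order
uncertainty).  The forward cloud generator turns these features into a
population of stochastic realisations, the *cloud drops* ``(x, u)``: a
universe value together with its certainty degree under the concept.

Drops are held as :class:`pandas.DataFrame` objects with columns ``x,u``
(1D) or ``x,y,u`` (2D), which is also the on-disk CSV dialect.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "CloudConcept1D",
    "CloudConcept2D",
    "as_rng",
    "forward_cloud_1d",
    "forward_cloud_2d",
    "membership_1d",
    "read_drops",
    "write_drops",
]

#: Bounded retries when a drawn per-drop entropy is exactly zero (the
#: Gaussian kernel is undefined there).  Hitting the bound is effectively
#: impossible for a continuous draw and signals a broken RNG.
_MAX_REDRAWS = 64

SeedLike = Union[int, np.random.Generator, np.random.SeedSequence, None]


def as_rng(seed: SeedLike) -> np.random.Generator:
    """Coerce a seed (or an existing Generator) into a numpy Generator.

    All stochastic operations in this package take an explicit ``rng``
    argument threaded through the call chain; there is no global state, so
    identical seed + identical call sequence gives identical draws.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class CloudConcept1D:
    """A one-dimensional normal cloud concept (Ex, En, He).

    Parameters
    ----------
    ex : float
        Expectation, in universe units (e.g. mental-health-index points).
    en : float
        Entropy (>= 0), same units; the standard deviation of the drop
        positions when He = 0.
    he : float
        Hyper-entropy (>= 0); standard deviation of the per-drop entropy.
    """

    ex: float
    en: float
    he: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "ex", _check_finite("ex", self.ex))
        object.__setattr__(self, "en", _check_finite("en", self.en))
        object.__setattr__(self, "he", _check_finite("he", self.he))
        if self.en < 0:
            raise ValueError(f"entropy en must be >= 0, got {self.en}")
        if self.he < 0:
            raise ValueError(f"hyper-entropy he must be >= 0, got {self.he}")
        if self.en == 0 and self.he > 0:
            # the per-drop entropy draw N(0, he) has indeterminate sign and
            # straddles zero, where the kernel is undefined
            raise ValueError("en = 0 with he > 0 is ill-posed; rejected")

    @property
    def is_degenerate(self) -> bool:
        """True when en = he = 0: the concept is the single drop (ex, 1)."""
        return self.en == 0 and self.he == 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CloudConcept1D":
        return cls(ex=d["ex"], en=d["en"], he=d["he"])

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "CloudConcept1D":
        """Load from a JSON file path or a literal JSON string."""
        text = str(source)
        if text.lstrip().startswith("{"):
            return cls.from_dict(json.loads(text))
        return cls.from_dict(json.loads(Path(source).read_text()))


@dataclass(frozen=True)
class CloudConcept2D:
    """A two-dimensional normal cloud concept (Ex, Enx, Hx, Ey, Eny, Hy).

    The two axes are independent: no correlation parameter exists in this
    model, so the bivariate draw uses a diagonal covariance.
    """

    ex: float
    enx: float
    hx: float
    ey: float
    eny: float
    hy: float

    def __post_init__(self) -> None:
        for name in ("ex", "enx", "hx", "ey", "eny", "hy"):
            object.__setattr__(self, name, _check_finite(name, getattr(self, name)))
        for name in ("enx", "hx", "eny", "hy"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for en, he in (("enx", "hx"), ("eny", "hy")):
            if getattr(self, en) == 0 and getattr(self, he) > 0:
                raise ValueError(f"{en} = 0 with {he} > 0 is ill-posed; rejected")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CloudConcept2D":
        return cls(**{k: d[k] for k in ("ex", "enx", "hx", "ey", "eny", "hy")})


def draw_en_prime(en: float, he: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n per-drop entropies En' ~ Normal(en, he).

    ``he`` enters as the standard deviation.  A draw of exactly zero is
    redrawn (bounded retries) because the membership kernel divides by En'².
    The draw may be negative when he > 0; the kernel squares it, so the
    certainty degree depends only on |En'|.
    """
    if he == 0:
        return np.full(n, en, dtype=float)
    values = rng.normal(en, he, size=n)
    for _ in range(_MAX_REDRAWS):
        zero = values == 0.0
        if not zero.any():
            return values
        values[zero] = rng.normal(en, he, size=int(zero.sum()))
    raise RuntimeError("exceeded redraw budget for En' = 0")


def membership_1d(x, concept: CloudConcept1D, en_prime: float):
    """Gaussian certainty kernel u = exp(-(x - Ex)^2 / (2 En'^2)).

    Deterministic given ``en_prime``; symmetric about Ex and strictly
    decreasing in |x - Ex|.  Accepts scalars or arrays for ``x``.
    """
    en_prime = float(en_prime)
    if en_prime <= 0:
        raise ValueError(f"en_prime must be > 0, got {en_prime}")
    x = np.asarray(x, dtype=float)
    u = np.exp(-((x - concept.ex) ** 2) / (2.0 * en_prime**2))
    return float(u) if u.ndim == 0 else u


def _check_n(n: int) -> int:
    if not isinstance(n, (int, np.integer)) or isinstance(n, bool) or n < 1:
        raise ValueError(f"n must be a positive integer, got {n!r}")
    return int(n)


def forward_cloud_1d(
    concept: CloudConcept1D, n: int, rng: SeedLike = None
) -> pd.DataFrame:
    """Generate n cloud drops from a 1D concept.

    Each drop draws a position x ~ Normal(Ex, En), a per-drop entropy
    En' ~ Normal(En, He), and sets u = exp(-(x - Ex)^2 / (2 En'^2)).
    For the degenerate concept En = He = 0 every drop is (Ex, 1), the
    limit of the kernel.

    Returns a DataFrame with columns ``x`` and ``u``; all u lie in (0, 1].
    """
    n = _check_n(n)
    rng = as_rng(rng)
    if concept.is_degenerate:
        return pd.DataFrame({"x": np.full(n, concept.ex), "u": np.ones(n)})
    x = rng.normal(concept.ex, concept.en, size=n)
    en_prime = draw_en_prime(concept.en, concept.he, n, rng)
    u = np.exp(-((x - concept.ex) ** 2) / (2.0 * en_prime**2))
    return pd.DataFrame({"x": x, "u": u})


def forward_cloud_2d(
    concept: CloudConcept2D, n: int, rng: SeedLike = None
) -> pd.DataFrame:
    """Generate n cloud drops from a 2D concept.

    Positions (Xi, Yi) come from the bivariate normal with means (Ex, Ey)
    and standard deviations (Enx, Eny) on independent axes; per-drop
    spreads are Enxi ~ Normal(Enx, Hx), Enyi ~ Normal(Eny, Hy); and

        Ui = exp(-1/2 [ (Xi-Ex)^2/Enxi^2 + (Yi-Ey)^2/Enyi^2 ]).

    A degenerate axis (en = he = 0) contributes its expectation and a zero
    exponent term.  Returns a DataFrame with columns ``x``, ``y``, ``u``.
    """
    n = _check_n(n)
    rng = as_rng(rng)

    def axis(ex: float, en: float, he: float):
        if en == 0 and he == 0:
            return np.full(n, ex), np.zeros(n)
        pos = rng.normal(ex, en, size=n)
        enp = draw_en_prime(en, he, n, rng)
        return pos, (pos - ex) ** 2 / enp**2

    x, qx = axis(concept.ex, concept.enx, concept.hx)
    y, qy = axis(concept.ey, concept.eny, concept.hy)
    u = np.exp(-0.5 * (qx + qy))
    return pd.DataFrame({"x": x, "y": y, "u": u})


def write_drops(drops: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write drops to CSV (header ``x,u`` or ``x,y,u``, full precision)."""
    drops.to_csv(path, index=False)


def read_drops(path: Union[str, Path]) -> pd.DataFrame:
    """Read a drop CSV written by :func:`write_drops`."""
    drops = pd.read_csv(path)
    missing = {"x", "u"} - set(drops.columns)
    if missing:
        raise ValueError(f"drop CSV missing columns: {sorted(missing)}")
    return drops
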