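"""Backward (reverse) cloud generator: estimate (Ex, En, He) from drops.

Given observed cloud drops (x_i, u_i), the reverse generator recovers the
digital features of the generating concept in four steps:

1. fit the expectation curve y = exp(-(x - Ex)^2 / (2 En^2)) to the drops
   by nonlinear least squares and keep the fitted Ex;
2. discard drops with u > 0.999 (they sit on the flat top of the curve,
   where the per-drop entropy is numerically indeterminate), leaving m;
3. back out a per-drop entropy En'_i = |x_i - Ex^| / sqrt(-2 ln u_i);
4. set En^ = mean(En'_i) and He^ = sample standard deviation of the En'_i.

The module follows the statsmodels convention: build a
:class:`ReverseCloudModel` from data, call :meth:`~ReverseCloudModel.fit`,
and read estimates, standard errors and diagnostics off the returned
:class:`ReverseCloudResults`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .clouds import CloudConcept1D, SeedLike, forward_cloud_1d, read_drops

__all__ = ["EstimationError", "ReverseCloudModel", "ReverseCloudResults"]

#: Drops with certainty above this sit on the flat top of the expectation
#: curve and are excluded from the per-drop entropy computation.
U_FILTER = 0.999

#: Minimum number of drops retained after filtering for Eqs to be usable.
MIN_DROPS = 5


class EstimationError(RuntimeError):
    """Raised when the reverse generator cannot produce an estimate."""


def _expectation_curve(x: np.ndarray, ex: float, en: float) -> np.ndarray:
    return np.exp(-((x - ex) ** 2) / (2.0 * en**2))


class ReverseCloudModel:
    """Reverse cloud generator over observed drops (x_i, u_i).

    Parameters
    ----------
    x : array-like
        Drop positions in universe units.
    u : array-like
        Certainty degrees, each in (0, 1].

    Examples
    --------
    >>> from cloudhealth import CloudConcept1D, forward_cloud_1d
    >>> drops = forward_cloud_1d(CloudConcept1D(22.4, 5.043, 0.325), 5000, rng=7)
    >>> res = ReverseCloudModel.from_drops(drops).fit()
    >>> round(res.ex_hat, 1)
    22.4
    """

    def __init__(self, x, u) -> None:
        x = np.asarray(x, dtype=float)
        u = np.asarray(u, dtype=float)
        if x.ndim != 1 or u.ndim != 1 or len(x) != len(u):
            raise ValueError("x and u must be 1D arrays of equal length")
        if not (np.isfinite(x).all() and np.isfinite(u).all()):
            raise ValueError("drops must be finite")
        if ((u <= 0) | (u > 1)).any():
            bad = u[(u <= 0) | (u > 1)][0]
            raise ValueError(f"certainty degrees must lie in (0, 1]; got {bad}")
        if len(x) < MIN_DROPS:
            raise EstimationError(
                f"need at least {MIN_DROPS} drops, got {len(x)}"
            )
        self.x = x
        self.u = u

    @classmethod
    def from_drops(cls, drops: pd.DataFrame) -> "ReverseCloudModel":
        """Build from a DataFrame with columns ``x`` and ``u``."""
        return cls(drops["x"].to_numpy(), drops["u"].to_numpy())

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "ReverseCloudModel":
        """Build from the ``x,u`` CSV dialect."""
        return cls.from_drops(read_drops(path))

    def _fit_ex(self) -> tuple[float, float]:
        """Least-squares fit of the expectation curve; returns (ex_hat, se).

        The fitted En is discarded: the entropy estimate comes from the
        per-drop backout, which stays authoritative.  Initialisation uses
        the u-weighted mean of x and the sample standard deviation of x.
        """
        ex0 = float(np.average(self.x, weights=self.u))
        en0 = float(np.std(self.x, ddof=1)) if len(self.x) > 1 else 1.0
        if en0 == 0:
            en0 = 1.0
        try:
            popt, pcov = curve_fit(
                _expectation_curve, self.x, self.u, p0=[ex0, en0], maxfev=10000
            )
        except RuntimeError as err:  # no convergence
            raise EstimationError(f"expectation-curve fit failed: {err}") from err
        ex_se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")
        return float(popt[0]), ex_se

    def fit(self) -> "ReverseCloudResults":
        """Run the four-step reverse generator and return the results."""
        ex_hat, ex_se = self._fit_ex()
        keep = self.u <= U_FILTER
        m = int(keep.sum())
        if m < MIN_DROPS:
            raise EstimationError(
                f"only {m} drops with u <= {U_FILTER}; need {MIN_DROPS} "
                "(drops at the curve top carry no entropy information)"
            )
        x_m = self.x[keep]
        u_m = self.u[keep]
        # u <= 0.999 guarantees ln u < 0 strictly
        en_prime = np.abs(x_m - ex_hat) / np.sqrt(-2.0 * np.log(u_m))
        en_hat = float(en_prime.mean())
        he_hat = float(en_prime.std(ddof=1))
        return ReverseCloudResults(
            model=self,
            ex_hat=ex_hat,
            en_hat=en_hat,
            he_hat=he_hat,
            m=m,
            en_prime=en_prime,
            ex_se=ex_se,
        )


class ReverseCloudResults:
    """Estimates from the reverse cloud generator.

    Attributes
    ----------
    ex_hat, en_hat, he_hat : float
        Estimated expectation, entropy and hyper-entropy.
    m : int
        Drops retained after the u > 0.999 filter.
    en_prime : ndarray
        The m per-drop entropies backed out of the retained drops.
    ex_se : float
        Standard error of ex_hat from the curve-fit covariance.
    en_se : float
        Standard error of en_hat (he_hat / sqrt(m)).
    """

    def __init__(self, model, ex_hat, en_hat, he_hat, m, en_prime, ex_se) -> None:
        self.model = model
        self.ex_hat = ex_hat
        self.en_hat = en_hat
        self.he_hat = he_hat
        self.m = m
        self.en_prime = en_prime
        self.ex_se = ex_se
        self.en_se = he_hat / np.sqrt(m)
        self.n_input = len(model.x)

    @property
    def concept(self) -> CloudConcept1D:
        """The estimated concept as a CloudConcept1D."""
        return CloudConcept1D(self.ex_hat, self.en_hat, self.he_hat)

    def simulate(self, n: int, rng: SeedLike = None) -> pd.DataFrame:
        """Forward-generate n drops from the estimated concept."""
        return forward_cloud_1d(self.concept, n, rng=rng)

    def to_dict(self) -> dict:
        return {
            "ex": self.ex_hat,
            "en": self.en_hat,
            "he": self.he_hat,
            "m": self.m,
        }

    def to_json(self, path: Optional[Union[str, Path]] = None) -> str:
        """Serialise estimates as JSON; write to ``path`` if given."""
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def summary(self) -> str:
        lines = [
            "Reverse cloud generator results",
            "=" * 46,
            f"{'drops (input / retained)':<30}{self.n_input} / {self.m}",
            f"{'Ex (expectation)':<30}{self.ex_hat:>10.4f}  (se {self.ex_se:.4f})",
            f"{'En (entropy)':<30}{self.en_hat:>10.4f}  (se {self.en_se:.4f})",
            f"{'He (hyper-entropy)':<30}{self.he_hat:>10.4f}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ReverseCloudResults ex={self.ex_hat:.4g} en={self.en_hat:.4g} "
            f"he={self.he_hat:.4g} m={self.m}>"
        )
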