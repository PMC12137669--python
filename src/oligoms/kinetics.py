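"""Acid-base speciation, the bell-shaped pH-rate law, and initial-rate estimation.

The oligomerisation of 2',3'-cyclic nucleotides is general acid-base
catalysed: the free amine of an amino acid abstracts the proton from the
attacking 5'-OH while the ammonium form protonates the 2'/3' leaving-group
oxygen.  Both forms are needed simultaneously, so the rate is modelled as

    r(pH) = rate_scale * f_base(pH) * f_acid(pH)

with Henderson-Hasselbalch fractions f_base = 1 / (1 + 10^(pKaH - pH)),
f_acid = 1 - f_base.  The product is maximal at pH = pKaH, where the
amine : ammonium ratio is 1:1 — reproducing the observed pH optimum near the
catalyst's pKaH (9.6 for valine).  The product-of-fractions form is the
minimal bifunctional rate law consistent with that mechanism; no microscopic
rate law is implied beyond it.

:class:`BellRateModel` follows the statsmodels idiom: constructed from
(pH, rate) observations, ``fit()`` returns a :class:`BellRateResults` with
the estimated pKaH and rate scale, their standard errors and a summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

__all__ = [
    "BellRateModel",
    "BellRateResults",
    "Protonatable",
    "RateEstimate",
    "TimeCourse",
    "PKA_TABLE",
    "bell_rate",
    "fit_bell",
    "initial_rate",
    "speciation",
]

#: Amine pKaH / nucleobase pKa values used as condition labels (editable).
#: Amino-acid alpha-amino pKaH ~9.6; lysine side-chain 10.5; the basic sites
#: of G and U sit near 9.3.
PKA_TABLE: dict[str, float] = {
    "valine": 9.6,
    "glycine": 9.6,
    "leucine": 9.6,
    "isoleucine": 9.6,
    "lysine_side_chain": 10.5,
    "guanine": 9.3,
    "uracil": 9.3,
}


@dataclass(frozen=True)
class Protonatable:
    """A protonatable site: an amine (pKaH) or nucleobase site (pKa)."""

    name: str
    pka: float

    def __post_init__(self) -> None:
        if not (0.0 < self.pka < 14.0):
            raise ValueError("pKa must lie in (0, 14) for aqueous use")

    @classmethod
    def from_table(cls, name: str) -> "Protonatable":
        return cls(name, PKA_TABLE[name])


def speciation(p: Protonatable, ph: float) -> tuple[float, float]:
    """Henderson-Hasselbalch fractions (base form, acid form) at *ph*."""
    ph = float(ph)
    if not (0.0 <= ph <= 14.0):
        raise ValueError("pH must lie in [0, 14]")
    f_base = 1.0 / (1.0 + 10.0 ** (p.pka - ph))
    return f_base, 1.0 - f_base


def bell_rate(p: Protonatable, ph, rate_scale: float):
    """Bifunctional acid-base rate: rate_scale * f_base * f_acid.

    Maximal (rate_scale / 4) at pH = pKaH, symmetric about it.
    """
    if rate_scale <= 0:
        raise ValueError("rate_scale must be positive")
    ph = np.asarray(ph, dtype=float)
    f_base = 1.0 / (1.0 + 10.0 ** (p.pka - ph))
    out = rate_scale * f_base * (1.0 - f_base)
    return float(out) if out.ndim == 0 else out


@dataclass
class TimeCourse:
    """Yield (%) against time (h) for one reaction condition; t starts at 0."""

    time_h: np.ndarray
    yield_pct: np.ndarray
    ph: float | None = None
    condition_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_h, dtype=float)
        y = np.asarray(self.yield_pct, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("time and yield must be 1-D arrays of equal length")
        if t.size == 0 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ValueError("time grid must start at 0 and increase")
        self.time_h, self.yield_pct = t, y

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_h": self.time_h, "yield_pct": self.yield_pct}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, **kwargs) -> "TimeCourse":
        df = pd.read_csv(path)
        return cls(df["time_h"].to_numpy(), df["yield_pct"].to_numpy(), **kwargs)


@dataclass(frozen=True)
class RateEstimate:
    """Initial rate of oligomerisation in % yield per hour."""

    rate: float
    stderr: float
    n_points: int
    ph: float | None = None

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a rate estimate needs at least two points")
        if not math.isfinite(self.rate):
            raise ValueError("rate must be finite")


def initial_rate(tc: TimeCourse, window: int | None = None) -> RateEstimate:
    """Initial rate by through-origin regression over the early time window.

    The default window is the first 25% of the time course or the first
    3 points, whichever is larger; it always includes t = 0 (the through-
    origin constraint encodes yield(0) = 0).
    """
    n = tc.time_h.size
    if window is None:
        t_cut = 0.25 * tc.time_h[-1]
        window = max(int(np.sum(tc.time_h <= t_cut)), min(3, n))
    window = int(window)
    if window < 2 or window > n:
        raise ValueError("window must cover at least 2 points including t = 0")
    t = tc.time_h[:window]
    y = tc.yield_pct[:window]
    stt = float(t @ t)
    if stt == 0.0:
        raise ValueError("window must include at least one t > 0 point")
    slope = float(t @ y) / stt
    resid = y - slope * t
    # heteroscedasticity-consistent (HC3) standard error: yield noise is
    # typically multiplicative, so residual variance grows along the course;
    # the leverage correction keeps the estimate honest at small n
    leverage = t**2 / stt
    stderr = float(np.sqrt(t**2 @ (resid**2 / (1.0 - leverage) ** 2)) / stt)
    return RateEstimate(rate=slope, stderr=stderr, n_points=window, ph=tc.ph)


class BellRateModel:
    """pH-rate profile model: fits the acid-base bell to (pH, rate) data.

    Parameters
    ----------
    ph, rate : array-like
        Observed pH values and rates (any consistent rate unit).  At least
        three distinct pH values are required.
    """

    def __init__(self, ph, rate):
        ph = np.asarray(ph, dtype=float)
        rate = np.asarray(rate, dtype=float)
        if ph.shape != rate.shape or ph.ndim != 1:
            raise ValueError("ph and rate must be 1-D arrays of equal length")
        if np.unique(ph).size < 3:
            raise ValueError("need at least 3 distinct pH values")
        self.ph = ph
        self.rate = rate

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, ph_col="ph", rate_col="rate"):
        return cls(df[ph_col].to_numpy(), df[rate_col].to_numpy())

    @staticmethod
    def _bell(ph, pka, scale):
        f = 1.0 / (1.0 + 10.0 ** (pka - ph))
        return scale * f * (1.0 - f)

    def fit(self) -> "BellRateResults":
        pka0 = float(self.ph[np.argmax(self.rate)])
        scale0 = max(4.0 * float(self.rate.max()), 1e-12)
        popt, pcov = scipy.optimize.curve_fit(
            self._bell,
            self.ph,
            self.rate,
            p0=(pka0, scale0),
            bounds=((0.0, 0.0), (14.0, np.inf)),
            maxfev=20000,
        )
        pka, scale = float(popt[0]), float(popt[1])
        bse = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
        resid = self.rate - self._bell(self.ph, *popt)
        extrapolated = not (self.ph.min() <= pka <= self.ph.max())
        return BellRateResults(
            model=self,
            pkah=pka,
            rate_scale=scale,
            bse=(float(bse[0]), float(bse[1])),
            residuals=resid,
            extrapolated=extrapolated,
        )


@dataclass
class BellRateResults:
    """Fitted bell parameters: pH optimum (pKaH) and rate scale."""

    model: BellRateModel
    pkah: float
    rate_scale: float
    bse: tuple[float, float]
    residuals: np.ndarray
    extrapolated: bool

    @property
    def max_rate(self) -> float:
        """Peak rate, attained at pH = pKaH: rate_scale / 4."""
        return self.rate_scale / 4.0

    def predict(self, ph):
        return BellRateModel._bell(np.asarray(ph, dtype=float), self.pkah, self.rate_scale)

    def summary(self) -> str:
        flag = "  [pH optimum outside observed range]" if self.extrapolated else ""
        return "\n".join(
            [
                "Acid-base bell pH-rate fit",
                f"  n observations: {self.model.ph.size}",
                f"  pKaH (pH optimum): {self.pkah:.3f} +/- {self.bse[0]:.3f}{flag}",
                f"  rate scale:        {self.rate_scale:.4g} +/- {self.bse[1]:.3g}",
                f"  peak rate:         {self.max_rate:.4g}",
                f"  residual norm:     {np.linalg.norm(self.residuals):.4g}",
            ]
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = np.linspace(self.model.ph.min() - 1, self.model.ph.max() + 1, 200)
        ax.plot(grid, self.predict(grid), "-", color="C0", label="bell fit")
        ax.plot(self.model.ph, self.model.rate, "o", color="k", label="observed")
        ax.axvline(self.pkah, ls=":", color="C3", label=f"pKaH = {self.pkah:.2f}")
        ax.set_xlabel("pH")
        ax.set_ylabel("rate")
        ax.legend()
        return ax


def fit_bell(observations) -> BellRateResults:
    """Fit the bell rate law to (pH, rate) pairs (functional wrapper)."""
    obs = np.asarray(list(observations), dtype=float)
    return BellRateModel(obs[:, 0], obs[:, 1]).fit()
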