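"""Seeded ground-truth generators: oligomer pools, ESI-TOF spectra, standards, kinetics.

Emulates the structure of dry-state cNMP oligomerisation experiments: a pool
of homo-/hetero-oligomers (lengths 1-7) over a chosen base alphabet with
tunable per-base incorporation efficiencies and geometric length decay,
2',3'-cyclic vs hydrolysed linear termini, negative-mode multi-charge ESI-TOF
peaks with ppm-scale mass error and multiplicative intensity noise, plus
calibration standards and saturating yield time courses.

Composition shares within a length follow the random-copolymerisation model:
composition c of length n receives a share proportional to M(c) * prod_b
p_b^{n_b}, where M(c) = n!/prod n_b! is the number of distinct sequences with
that composition.  Shares are allocated deterministically (expected values)
by default so conservation laws hold exactly; an optional sampled mode draws
molecule counts multinomially.

Every stochastic operation takes an explicit seed; there is no global random
state.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemistry import (
    PROTON_MASS,
    BaseCount,
    OligomerSpecies,
    Terminus,
    isotope_envelope,
    species_formula,
)
from .kinetics import TimeCourse
from .quantify import (
    TOF_RESOLVING_POWER,
    CalibrationModel,
    ConcentrationTable,
    PeakList,
    charge_weights,
)

__all__ = [
    "PoolModel",
    "SpectrumNoise",
    "generate_calibration_standards",
    "generate_pool",
    "generate_time_course",
    "simulate_spectrum",
]

def _multiplicity(c: BaseCount) -> int:
    out = math.factorial(c.n)
    for b in "ACGU":
        out //= math.factorial(c.count(b))
    return out


@dataclass
class PoolModel:
    """Ground-truth model of an oligomerisation product pool.

    Parameters
    ----------
    alphabet : str
        Subset of "ACGU" present in the reaction.
    efficiencies : dict or None
        Per-base incorporation efficiency p_b; normalised to sum to 1.
        None means equal efficiency (the random-copolymerisation null).
    length_decay : float
        q in (0, 1): total nucleotide mass in n-mers falls as q^(n-2).
    c0_mM : float
        Total input monomer concentration (10 mM single-base runs, 40 mM
        copolymerisation runs).
    converted_fraction : float
        phi in [0, 1]: fraction of input nucleotides ending up in oligomers
        (length >= 2); equals the %-yield / 100 of the pool.
    cyclic_fraction : float
        theta in [0, 1]: fraction of each species pool retaining the
        activated 2',3'-cyclic phosphate terminus.
    max_length : int
        Longest oligomer generated.
    """

    alphabet: str = "ACGU"
    efficiencies: dict[str, float] | None = None
    length_decay: float = 0.3
    c0_mM: float = 10.0
    converted_fraction: float = 0.10
    cyclic_fraction: float = 0.33
    max_length: int = 7

    def __post_init__(self) -> None:
        self.alphabet = "".join(sorted(set(self.alphabet)))
        if not self.alphabet or set(self.alphabet) - set("ACGU"):
            raise ValueError("alphabet must be a non-empty subset of ACGU")
        if not (0.0 < self.length_decay < 1.0):
            raise ValueError("length_decay must lie in (0, 1)")
        if not (0.0 <= self.converted_fraction <= 1.0):
            raise ValueError("converted_fraction must lie in [0, 1]")
        if not (0.0 <= self.cyclic_fraction <= 1.0):
            raise ValueError("cyclic_fraction must lie in [0, 1]")
        if self.c0_mM <= 0:
            raise ValueError("c0_mM must be positive")
        if self.max_length < 2:
            raise ValueError("max_length must be >= 2")
        if self.efficiencies is None:
            p = {b: 1.0 / len(self.alphabet) for b in self.alphabet}
        else:
            if set(self.efficiencies) != set(self.alphabet):
                raise ValueError("efficiencies must cover exactly the alphabet")
            if any(v <= 0 for v in self.efficiencies.values()):
                raise ValueError("efficiencies must be positive")
            total = sum(self.efficiencies.values())
            p = {b: v / total for b, v in self.efficiencies.items()}
        self.efficiencies = p

    def compositions(self, n: int) -> list[BaseCount]:
        return [
            BaseCount.from_sequence("".join(combo))
            for combo in itertools.combinations_with_replacement(self.alphabet, n)
        ]

    def composition_share(self, c: BaseCount) -> float:
        """Share of composition c within its length class: M(c) prod p_b^{n_b}."""
        share = float(_multiplicity(c))
        for b in self.alphabet:
            share *= self.efficiencies[b] ** c.count(b)
        return share


def generate_pool(
    model: PoolModel, seed: int | None = None, sampled: bool = False, n_molecules: int = 10**7
) -> ConcentrationTable:
    """Ground-truth ConcentrationTable for a pool model.

    Deterministic by default (expected-value allocation), so nucleotide mass
    is conserved exactly: sum over rows of conc x length = c0_mM.  Residual
    unreacted monomer is carried as length-1 rows.  With ``sampled=True``
    molecule counts are drawn multinomially (seeded) instead.
    """
    q, L = model.length_decay, model.max_length
    # nucleotide mass per length class, geometric in length
    z = sum(q ** (n - 2) for n in range(2, L + 1))
    items: list[tuple[OligomerSpecies, float]] = []

    def add(comp: BaseCount, conc: float) -> None:
        th = model.cyclic_fraction
        if th > 0:
            items.append((OligomerSpecies(comp, Terminus.CYCLIC), conc * th))
        if th < 1:
            items.append((OligomerSpecies(comp, Terminus.LINEAR), conc * (1 - th)))

    # residual monomer, split by efficiency
    monomer_total = (1.0 - model.converted_fraction) * model.c0_mM
    for b in model.alphabet:
        add(BaseCount.from_sequence(b), monomer_total * model.efficiencies[b])
    # oligomers
    for n in range(2, L + 1):
        nucl_n = model.converted_fraction * model.c0_mM * q ** (n - 2) / z
        t_n = nucl_n / n  # total n-mer concentration
        comps = model.compositions(n)
        shares = np.array([model.composition_share(c) for c in comps])
        shares = shares / shares.sum()
        for c, s in zip(comps, shares):
            add(c, t_n * s)
    if sampled:
        rng = np.random.default_rng(seed)
        concs = np.array([c for _, c in items])
        total = concs.sum()
        counts = rng.multinomial(n_molecules, concs / total)
        items = [(sp, total * k / n_molecules) for (sp, _), k in zip(items, counts)]
    items = [(sp, c) for sp, c in items if c > 0]
    return ConcentrationTable.from_species(items)


@dataclass
class SpectrumNoise:
    """Instrument imperfection model for the simulated ESI-TOF.

    Finite resolving power is part of the model: neighbouring peaks closer
    than m/z / resolving_power are centroided into one reported peak, as on
    the real instrument.  ``none()`` is a perfect instrument — no jitter, no
    baseline, infinite resolution.
    """

    mz_ppm_sigma: float = 5.0
    intensity_sigma: float = 0.10  # lognormal sigma (multiplicative, ~10%)
    baseline_peaks: int = 30  # expected count of spurious baseline peaks
    baseline_scale: float = 1e-3  # baseline intensity relative to max signal
    resolving_power: float = TOF_RESOLVING_POWER  # 0 means unlimited

    def __post_init__(self) -> None:
        if min(self.mz_ppm_sigma, self.intensity_sigma, self.baseline_scale) < 0:
            raise ValueError("noise sigmas must be non-negative")
        if self.baseline_peaks < 0 or self.resolving_power < 0:
            raise ValueError("baseline_peaks and resolving_power must be non-negative")

    @classmethod
    def none(cls) -> "SpectrumNoise":
        return cls(0.0, 0.0, 0, 0.0, 0.0)


def simulate_spectrum(
    pool: ConcentrationTable,
    response: CalibrationModel,
    noise: SpectrumNoise | None = None,
    charges=(1, 2, 3),
    seed: int | None = None,
    prune: float = 1e-4,
    min_length: int = 1,
    condition_id: str = "",
) -> PeakList:
    """Negative-mode centroided spectrum of a species pool.

    Each species contributes peaks at its [M - zH]^z- isotopologue positions
    with intensity conc x response(length) x charge weight x isotopologue
    abundance; m/z values are jittered by ppm-scale noise and intensities by
    multiplicative lognormal noise; sparse uniform baseline peaks are added.
    Peaks closer than the centroiding width are merged, as on the real
    instrument.  Reproducible given the seed.
    """
    noise = noise if noise is not None else SpectrumNoise()
    rng = np.random.default_rng(seed)
    mzs: list[float] = []
    intens: list[float] = []
    for sp, conc in pool:
        if conc < 0:
            raise ValueError("concentrations must be non-negative")
        if conc == 0 or sp.length < min_length:
            continue
        env = isotope_envelope(species_formula(sp), prune=prune)
        slope = response(sp.length)
        for z, wz in charge_weights(sp.length, charges).items():
            mz = (env.masses - z * PROTON_MASS) / z
            inten = conc * slope * wz * env.abundances
            if noise.mz_ppm_sigma > 0:
                mz = mz * (1.0 + rng.normal(0.0, noise.mz_ppm_sigma * 1e-6, mz.size))
            if noise.intensity_sigma > 0:
                inten = inten * rng.lognormal(0.0, noise.intensity_sigma, inten.size)
            mzs.extend(mz)
            intens.extend(inten)
    if noise.baseline_peaks > 0 and mzs:
        lo, hi = min(mzs) - 10, max(mzs) + 10
        k = rng.poisson(noise.baseline_peaks)
        mzs.extend(rng.uniform(lo, hi, k))
        intens.extend(
            rng.exponential(noise.baseline_scale * max(intens), k) if k else []
        )
    mz_arr = np.asarray(mzs)
    in_arr = np.asarray(intens)
    # centroiding: merge peaks the TOF cannot resolve
    order = np.argsort(mz_arr)
    mz_arr, in_arr = mz_arr[order], in_arr[order]
    if mz_arr.size:
        # exact coincidences (e.g. the 2-mer at z=1 and the 4-mer at z=2 of
        # the same base, identical by mass additivity) always coalesce, even
        # on a perfect instrument
        if noise.resolving_power > 0:
            width = mz_arr[:-1] / noise.resolving_power
        else:
            width = np.full(mz_arr.size - 1, 1e-6)
        breaks = np.flatnonzero(np.diff(mz_arr) >= width) + 1
        groups = np.split(np.arange(mz_arr.size), breaks)
        mz_arr = np.array([np.average(mz_arr[g], weights=in_arr[g]) for g in groups])
        in_arr = np.array([in_arr[g].sum() for g in groups])
    return PeakList(
        mz_arr,
        in_arr,
        ppm_accuracy=max(noise.mz_ppm_sigma, 1.0),
        condition_id=condition_id,
        seed=seed,
    )


def generate_calibration_standards(
    species,
    ladder_mM,
    response: CalibrationModel,
    noise: SpectrumNoise | None = None,
    seed: int | None = None,
    charges=(1, 2, 3),
) -> list[tuple[PeakList, ConcentrationTable]]:
    """Spectra of known-concentration standards for calibration fitting.

    One spectrum per ladder level, every species at that concentration.
    At least three levels are required — fewer cannot support fitting and
    validating a slope.
    """
    species = list(species)
    ladder = [float(c) for c in ladder_mM]
    if any(c <= 0 for c in ladder):
        raise ValueError("ladder concentrations must be positive")
    if len(set(ladder)) < 3:
        raise ValueError("need at least 3 distinct ladder levels")
    if not species:
        return []
    seeds = np.random.SeedSequence(seed).spawn(len(ladder))
    out = []
    for level, ss in zip(ladder, seeds):
        known = ConcentrationTable.from_species([(sp, level) for sp in species])
        pl = simulate_spectrum(
            known,
            response,
            noise,
            charges=charges,
            seed=int(ss.generate_state(1)[0] % (2**31)),
            condition_id=f"standard_{level:g}mM",
        )
        out.append((pl, known))
    return out


def generate_time_course(
    rate_pct_per_h: float,
    time_grid_h,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    plateau_pct: float = 20.0,
    ph: float | None = None,
) -> TimeCourse:
    """Saturating yield curve with the given initial rate.

    yield(t) = plateau * (1 - exp(-(r/plateau) t)): starts at 0, initial
    slope exactly *rate_pct_per_h*, saturating at *plateau_pct*.  Noise is
    multiplicative lognormal with sigma *noise_sigma* (t = 0 stays exact).
    """
    t = np.asarray(time_grid_h, dtype=float)
    if t.size == 0 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
        raise ValueError("time grid must start at 0 and increase")
    if rate_pct_per_h < 0 or plateau_pct <= 0:
        raise ValueError("rate must be >= 0 and plateau > 0")
    if rate_pct_per_h == 0:
        y = np.zeros_like(t)
    else:
        k = rate_pct_per_h / plateau_pct
        y = plateau_pct * (1.0 - np.exp(-k * t))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        factors = rng.lognormal(0.0, noise_sigma, t.size)
        factors[0] = 1.0
        y = y * factors
    return TimeCourse(t, y, ph=ph)
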