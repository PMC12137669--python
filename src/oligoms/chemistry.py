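"""Elemental formulas, masses, isotope envelopes and charge states for cNMP oligomers.

The monomers are ribonucleoside 2',3'-cyclic monophosphates (cNMP, N = A, C,
G, U).  Oligomerisation proceeds by ring-opening transphosphorylation — the
5'-OH of one nucleotide attacks the cyclic phosphate of another — so no water
is released on condensation: a cyclic-terminated n-mer is the element-wise sum
of its monomer formulas, and hydrolysis of the terminal cyclic phosphate adds
exactly one water.

Atomic masses and isotopic abundances are embedded as a fixed constants table
(IUPAC/CIAAW 2021 recommended values) so results are bit-reproducible.
"""

from __future__ import annotations

import enum
import itertools
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BaseCount",
    "ElementalFormula",
    "IsotopeEnvelope",
    "OligomerSpecies",
    "Terminus",
    "isotope_envelope",
    "monoisotopic_mass",
    "monomer_formula",
    "mz_values",
    "parse_species",
    "species_formula",
]

#: Mass of a proton in Da, used for [M - zH]^z- charge-state arithmetic.
PROTON_MASS = 1.007276

#: (isotope mass in Da, natural abundance) per element, lightest first.
#: IUPAC/CIAAW 2021 recommended values.
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "C": [(12.0, 0.9893), (13.00335483507, 0.0107)],
    "H": [(1.00782503207, 0.999885), (2.01410177785, 0.000115)],
    "N": [(14.00307400425, 0.99636), (15.00010889827, 0.00364)],
    "O": [
        (15.99491461926, 0.99757),
        (16.99913175595, 0.00038),
        (17.99915961214, 0.00205),
    ],
    "P": [(30.97376199768, 1.0)],
}

ELEMENT_ORDER = ("C", "H", "N", "O", "P")

BASES = ("A", "C", "G", "U")


@dataclass(frozen=True)
class ElementalFormula:
    """Integer element counts over C, H, N, O, P; addition is element-wise."""

    counts: tuple[int, int, int, int, int] = (0, 0, 0, 0, 0)

    def __post_init__(self) -> None:
        if len(self.counts) != len(ELEMENT_ORDER):
            raise ValueError("counts must cover C, H, N, O, P")
        if any(c < 0 or int(c) != c for c in self.counts):
            raise ValueError(f"element counts must be non-negative integers: {self.counts}")

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "ElementalFormula":
        unknown = set(d) - set(ELEMENT_ORDER)
        if unknown:
            raise ValueError(f"unsupported elements: {sorted(unknown)}")
        return cls(tuple(int(d.get(e, 0)) for e in ELEMENT_ORDER))

    def as_dict(self) -> dict[str, int]:
        return {e: c for e, c in zip(ELEMENT_ORDER, self.counts) if c}

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        return ElementalFormula(tuple(a + b for a, b in zip(self.counts, other.counts)))

    def __mul__(self, k: int) -> "ElementalFormula":
        if int(k) != k or k < 0:
            raise ValueError("multiplier must be a non-negative integer")
        return ElementalFormula(tuple(int(k) * c for c in self.counts))

    __rmul__ = __mul__

    @property
    def n_atoms(self) -> int:
        return sum(self.counts)

    def __str__(self) -> str:
        return "".join(f"{e}{c}" for e, c in zip(ELEMENT_ORDER, self.counts) if c)


WATER = ElementalFormula.from_dict({"H": 2, "O": 1})

#: Neutral free-acid formulas of the 2',3'-cyclic monophosphates
#: (the 5'-monophosphate formula minus one water).
_MONOMER_FORMULAS: dict[str, ElementalFormula] = {
    "A": ElementalFormula.from_dict({"C": 10, "H": 12, "N": 5, "O": 6, "P": 1}),
    "C": ElementalFormula.from_dict({"C": 9, "H": 12, "N": 3, "O": 7, "P": 1}),
    "G": ElementalFormula.from_dict({"C": 10, "H": 12, "N": 5, "O": 7, "P": 1}),
    "U": ElementalFormula.from_dict({"C": 9, "H": 11, "N": 2, "O": 8, "P": 1}),
}


def monomer_formula(base: str) -> ElementalFormula:
    """Neutral free-acid formula of the 2',3'-cyclic monophosphate of *base*."""
    try:
        return _MONOMER_FORMULAS[base]
    except KeyError:
        raise ValueError(f"unknown base {base!r}; expected one of {BASES}") from None


@dataclass(frozen=True, order=True)
class BaseCount:
    """Base composition of an oligomer: counts of A, C, G, U.

    Identity is composition only; 2'-5' vs 3'-5' regioisomers are
    mass-identical and not distinguished here.
    """

    nA: int = 0
    nC: int = 0
    nG: int = 0
    nU: int = 0

    def __post_init__(self) -> None:
        counts = (self.nA, self.nC, self.nG, self.nU)
        if any(c < 0 or int(c) != c for c in counts):
            raise ValueError("base counts must be non-negative integers")
        if sum(counts) < 1:
            raise ValueError("composition must contain at least one nucleotide")

    @property
    def n(self) -> int:
        """Oligomer length."""
        return self.nA + self.nC + self.nG + self.nU

    def count(self, base: str) -> int:
        return {"A": self.nA, "C": self.nC, "G": self.nG, "U": self.nU}[base]

    def as_dict(self) -> dict[str, int]:
        return {b: self.count(b) for b in BASES if self.count(b)}

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "BaseCount":
        unknown = set(d) - set(BASES)
        if unknown:
            raise ValueError(f"unknown bases: {sorted(unknown)}")
        return cls(d.get("A", 0), d.get("C", 0), d.get("G", 0), d.get("U", 0))

    @classmethod
    def from_sequence(cls, seq: str) -> "BaseCount":
        """Composition of an explicit base string, e.g. ``"AAU"`` -> A2U1."""
        d: dict[str, int] = {}
        for ch in seq:
            d[ch] = d.get(ch, 0) + 1
        return cls.from_dict(d)

    def __add__(self, other: "BaseCount") -> "BaseCount":
        return BaseCount(
            self.nA + other.nA, self.nC + other.nC, self.nG + other.nG, self.nU + other.nU
        )

    def __str__(self) -> str:
        return "".join(f"{b}{self.count(b)}" for b in BASES if self.count(b))


class Terminus(enum.Enum):
    """3'-end chemistry: activated 2',3'-cyclic phosphate or hydrolysed linear phosphate."""

    CYCLIC = "cyclic_phosphate"
    LINEAR = "linear_phosphate"


@dataclass(frozen=True, order=True)
class OligomerSpecies:
    """The unit of quantification: a base composition plus terminus chemistry."""

    composition: BaseCount
    terminus: Terminus = Terminus.CYCLIC

    @property
    def length(self) -> int:
        return self.composition.n

    def __str__(self) -> str:
        suffix = ">p" if self.terminus is Terminus.CYCLIC else "-p"
        return f"{self.composition}{suffix}"


_SPECIES_RE = re.compile(r"^((?:[ACGU]\d+)+)(>p|-p)$")
_PART_RE = re.compile(r"([ACGU])(\d+)")


def parse_species(s: str) -> OligomerSpecies:
    """Parse the species string grammar, e.g. ``"A2U1>p"`` (cyclic), ``"C3-p"`` (linear).

    Round-trips with ``str(species)``.
    """
    m = _SPECIES_RE.match(s.strip())
    if not m:
        raise ValueError(f"cannot parse species string {s!r}")
    d: dict[str, int] = {}
    for base, count in _PART_RE.findall(m.group(1)):
        if base in d:
            raise ValueError(f"duplicate base {base} in {s!r}")
        d[base] = int(count)
    terminus = Terminus.CYCLIC if m.group(2) == ">p" else Terminus.LINEAR
    return OligomerSpecies(BaseCount.from_dict(d), terminus)


def species_formula(s: OligomerSpecies) -> ElementalFormula:
    """Neutral formula: sum of monomer formulas; linear terminus adds one water."""
    f = ElementalFormula()
    for base in BASES:
        f = f + s.composition.count(base) * monomer_formula(base)
    if s.terminus is Terminus.LINEAR:
        f = f + WATER
    return f


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Sum of lightest-isotope atomic masses, in Da."""
    return float(sum(c * ISOTOPES[e][0][0] for e, c in zip(ELEMENT_ORDER, f.counts)))


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Normalised isotopologue distribution of a neutral species.

    ``masses`` are strictly increasing neutral masses in Da; ``abundances``
    sum to 1 after pruning and renormalisation.  Fine structure closer than
    ``merge_tol`` (e.g. the 6 mDa 13C vs 15N splitting, unresolvable on a
    TOF) is centroided into single abundance-weighted peaks.
    """

    masses: np.ndarray
    abundances: np.ndarray
    prune: float
    merge_tol: float = 0.01

    def __post_init__(self) -> None:
        m = np.asarray(self.masses, dtype=float)
        a = np.asarray(self.abundances, dtype=float)
        object.__setattr__(self, "masses", m)
        object.__setattr__(self, "abundances", a)
        if m.shape != a.shape or m.ndim != 1:
            raise ValueError("masses and abundances must be 1-D and equal length")
        if m.size and np.any(np.diff(m) <= 0):
            raise ValueError("masses must be strictly increasing")
        if abs(a.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")

    def __len__(self) -> int:
        return int(self.masses.size)

    @property
    def monoisotopic_mass(self) -> float:
        return float(self.masses[0])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"mass_da": self.masses, "abundance": self.abundances})


def _merge_close(masses: np.ndarray, abundances: np.ndarray, tol: float):
    """Centroid peaks whose consecutive gaps are below *tol* (abundance-weighted)."""
    order = np.argsort(masses)
    m, a = masses[order], abundances[order]
    if m.size == 0:
        return m, a
    breaks = np.flatnonzero(np.diff(m) >= tol) + 1
    groups = np.split(np.arange(m.size), breaks)
    out_m = np.array([np.average(m[g], weights=a[g]) for g in groups])
    out_a = np.array([a[g].sum() for g in groups])
    return out_m, out_a


def _convolve(d1, d2, floor: float, tol: float):
    m = (d1[0][:, None] + d2[0][None, :]).ravel()
    a = (d1[1][:, None] * d2[1][None, :]).ravel()
    keep = a > floor
    return _merge_close(m[keep], a[keep], tol)


def isotope_envelope(
    f: ElementalFormula, prune: float = 1e-6, merge_tol: float = 0.01
) -> IsotopeEnvelope:
    """Isotope envelope of a neutral formula by element-wise convolution.

    Convolves the natural isotope distributions of every atom (exact within
    the 1e-16 floating floor), centroids fine structure within *merge_tol*,
    then prunes isotopologues below relative abundance *prune* and
    renormalises.  The first retained peak is the monoisotopic one.
    """
    if not (0.0 < prune <= 0.01):
        raise ValueError("prune must lie in (0, 0.01]")
    dist = (np.array([0.0]), np.array([1.0]))
    floor = 1e-16  # keep convolution effectively exact; prune only at the end
    for elem, count in zip(ELEMENT_ORDER, f.counts):
        if count == 0:
            continue
        base = (
            np.array([iso[0] for iso in ISOTOPES[elem]]),
            np.array([iso[1] for iso in ISOTOPES[elem]]),
        )
        # binary exponentiation of the per-atom distribution
        power, k = base, count
        acc = None
        while k:
            if k & 1:
                acc = power if acc is None else _convolve(acc, power, floor, merge_tol)
            k >>= 1
            if k:
                power = _convolve(power, power, floor, merge_tol)
        dist = _convolve(dist, acc, floor, merge_tol)
    m, a = dist
    keep = a >= prune * a.sum()
    m, a = m[keep], a[keep]
    a = a / a.sum()
    return IsotopeEnvelope(m, a, prune=prune, merge_tol=merge_tol)


def mz_values(
    s: OligomerSpecies,
    charges,
    prune: float = 1e-6,
) -> list[tuple[int, np.ndarray]]:
    """[M - zH]^z- m/z values of every retained isotopologue, per charge state.

    Returns a list of ``(z, mz_array)`` pairs, one per charge, with
    ``mz = (isotopologue_mass - z * 1.007276) / z``.
    """
    charges = sorted(set(int(z) for z in charges))
    if any(z <= 0 for z in charges):
        raise ValueError("charges must be positive integers")
    if not charges:
        return []
    env = isotope_envelope(species_formula(s), prune=prune)
    return [(z, (env.masses - z * PROTON_MASS) / z) for z in charges]


def envelope_to_csv(env: IsotopeEnvelope, path) -> None:
    """Write an envelope as delimited text (mass_da, abundance)."""
    env.to_frame().to_csv(path, index=False)
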