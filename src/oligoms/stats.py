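"""Headline statistics of oligomerisation experiments.

Yields and fold changes, length distributions, the random-copolymerisation
compositional null model, G-incorporation class averages, terminus and
linkage ratios, and deviation-from-null diagnostics.

The yield of a reaction is the percentage of input nucleotides found in
oligomer form,

    Y = 100 * sum_{length >= 2} conc(s) * length(s) / C0,

i.e. the concentration of each oligomer times its length, relative to the
nominal input monomer concentration.  The random-copolymerisation null says
that if all bases incorporate with efficiency p_b, the expected
concentration of composition c of length n is

    E[c] = T_n * M(c) * prod_b p_b^{n_b},

with T_n the measured total n-mer concentration and M(c) = n!/prod n_b! the
number of distinct sequences sharing c.  The null is anchored to the
measured per-length totals, so sum_c E[c] = T_n exactly: it predicts
composition shares, not overall conversion.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemistry import BASES, BaseCount, Terminus, parse_species
from .quantify import ConcentrationTable

__all__ = [
    "LinkageIntegrals",
    "NullExpectation",
    "ReactionCondition",
    "ReactionRecord",
    "YieldReport",
    "composition_class",
    "composition_class_average",
    "cyclic_terminus_fraction",
    "fold_change",
    "g_fraction",
    "multiplicity",
    "natural_linkage_fraction",
    "null_deviation",
    "null_expectation",
    "total_yield",
    "yield_report",
]


@dataclass(frozen=True)
class ReactionCondition:
    """Metadata for one dry-state oligomerisation reaction."""

    ph: float
    amino_acid: str | None = None
    equivalents: float = 0.0
    temperature_c: float = 25.0
    duration_h: float = 20.0
    input_mM: dict[str, float] = field(default_factory=lambda: {"C": 10.0})

    def __post_init__(self) -> None:
        if self.equivalents < 0:
            raise ValueError("equivalents must be >= 0")
        if not self.input_mM or any(v <= 0 for v in self.input_mM.values()):
            raise ValueError("input concentrations must be positive")
        unknown = set(self.input_mM) - set(BASES)
        if unknown:
            raise ValueError(f"unknown bases in input: {sorted(unknown)}")

    @property
    def total_input_mM(self) -> float:
        return float(sum(self.input_mM.values()))


@dataclass
class ReactionRecord:
    """A reaction condition together with its quantified product table."""

    condition: ReactionCondition
    products: ConcentrationTable


def total_yield(r: ReactionRecord, min_length: int = 2) -> float:
    """Percent of input nucleotides in oligomer form (monomers excluded).

    Y = 100 * sum conc x length over species with length >= min_length,
    divided by the nominal input monomer concentration.  Both cyclic- and
    linear-terminated oligomers count.
    """
    c0 = r.condition.total_input_mM
    olig = r.products.oligomers(min_length)
    return float(100.0 * (olig["conc_mM"] * olig["length"]).sum() / c0)


def fold_change(treated, control, min_length: int = 2) -> float:
    """Yield ratio treated / control.

    Accepts ReactionRecords (same input base system required) or plain
    percent yields.  A zero control yield returns +inf (flagged increase
    from nothing).
    """
    if isinstance(treated, ReactionRecord) and isinstance(control, ReactionRecord):
        if set(treated.condition.input_mM) != set(control.condition.input_mM):
            raise ValueError("records quantify different nucleotide systems")
        y_t = total_yield(treated, min_length)
        y_c = total_yield(control, min_length)
    else:
        y_t, y_c = float(treated), float(control)
    if y_c == 0.0:
        return math.inf
    return y_t / y_c


def multiplicity(c: BaseCount) -> int:
    """Number of distinct sequences with composition c: n! / prod n_b!.

    E.g. A2U has multiplicity 3 (AAU, AUA, UAA); homopolymers have 1.
    """
    out = math.factorial(c.n)
    for b in BASES:
        out //= math.factorial(c.count(b))
    return out


@dataclass
class YieldReport:
    """Per-condition yield summary."""

    total_pct: float
    per_length_pct: dict[int, float]
    long_fraction: float  # fraction of the yield carried by 5-7-mers
    cyclic_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.total_pct <= 100.0 + 1e-9):
            raise ValueError("yield must lie in [0, 100]")
        if abs(sum(self.per_length_pct.values()) - self.total_pct) > 1e-6:
            raise ValueError("per-length yields must sum to the total")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"length": l, "yield_pct": y} for l, y in sorted(self.per_length_pct.items())]
        return pd.DataFrame(rows)


def yield_report(r: ReactionRecord, min_length: int = 2) -> YieldReport:
    c0 = r.condition.total_input_mM
    olig = r.products.oligomers(min_length)
    per_length = {
        int(l): float(100.0 * (g["conc_mM"] * g["length"]).sum() / c0)
        for l, g in olig.groupby("length")
    }
    total = float(sum(per_length.values()))
    long_pct = sum(y for l, y in per_length.items() if 5 <= l <= 7)
    return YieldReport(
        total_pct=total,
        per_length_pct=per_length,
        long_fraction=(long_pct / total) if total > 0 else 0.0,
        cyclic_fraction=cyclic_terminus_fraction(r.products, min_length)
        if len(olig)
        else 0.0,
    )


@dataclass
class NullExpectation:
    """Random-copolymerisation expected concentrations, per composition.

    ``table`` has columns (length, composition, multiplicity, expected_mM);
    within each length the expectations sum exactly to the measured total
    n-mer concentration T_n.
    """

    table: pd.DataFrame
    t_n: dict[int, float]
    efficiencies: dict[str, float]

    def expected(self, c: BaseCount) -> float:
        hit = self.table.loc[self.table["composition"] == str(c), "expected_mM"]
        if hit.empty:
            raise KeyError(f"composition {c} not in null table")
        return float(hit.iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _composition_totals(products: ConcentrationTable, min_length: int = 2) -> pd.DataFrame:
    """Observed concentration per composition (termini summed)."""
    df = products.oligomers(min_length).copy()
    comp = [str(parse_species(s).composition) for s in df["species"]]
    df = df.assign(composition=comp)
    out = df.groupby(["length", "composition"], as_index=False)["conc_mM"].sum()
    return out


def null_expectation(
    products: ConcentrationTable,
    alphabet: str,
    efficiencies: dict[str, float] | None = None,
    min_length: int = 2,
) -> NullExpectation:
    """Null model anchored to the measured per-length totals.

    With equal efficiencies (the default), E[c] = T_n x M(c) / k^n over the
    k-letter alphabet; with explicit efficiencies p_b, E[c] = T_n x M(c) x
    prod p_b^{n_b}.  All compositions of each observed length are tabulated,
    including undetected ones.
    """
    alphabet = "".join(sorted(set(alphabet)))
    if set(alphabet) - set(BASES):
        raise ValueError("alphabet must be a subset of ACGU")
    if efficiencies is None:
        p = {b: 1.0 / len(alphabet) for b in alphabet}
    else:
        if set(efficiencies) != set(alphabet):
            raise ValueError("efficiencies must cover exactly the alphabet")
        tot = sum(efficiencies.values())
        p = {b: v / tot for b, v in efficiencies.items()}
    obs = _composition_totals(products, min_length)
    if obs.empty:
        raise ValueError("product table contains no oligomers")
    bad = {
        b
        for comp in obs["composition"]
        for b, k in BaseCount.from_dict(
            parse_species(comp + ">p").composition.as_dict()
        ).as_dict().items()
        if k and b not in alphabet
    }
    if bad:
        raise ValueError(f"products contain bases outside the alphabet: {sorted(bad)}")
    rows = []
    t_n: dict[int, float] = {}
    for n, grp in obs.groupby("length"):
        n = int(n)
        t = float(grp["conc_mM"].sum())
        t_n[n] = t
        comps = [
            BaseCount.from_sequence("".join(combo))
            for combo in itertools.combinations_with_replacement(alphabet, n)
        ]
        shares = np.array(
            [
                multiplicity(c) * np.prod([p[b] ** c.count(b) for b in alphabet])
                for c in comps
            ]
        )
        shares = shares / shares.sum()  # exact normalisation: sum E = T_n
        for c, s in zip(comps, shares):
            rows.append(
                {
                    "length": n,
                    "composition": str(c),
                    "multiplicity": multiplicity(c),
                    "expected_mM": t * float(s),
                }
            )
    return NullExpectation(pd.DataFrame(rows), t_n, p)


def composition_class(n: int, g_count: int) -> list[BaseCount]:
    """The G-incorporation class: length-n compositions with exactly g_count G.

    The non-G positions run over H = {A, C, U}; e.g. the HH class (n=2,
    g=0) is {AA, AU, AC, CC, CU, UU} and GHHH (n=4, g=1) has 10 members.
    """
    if not (0 <= g_count <= n) or n < 1:
        raise ValueError("need 0 <= g_count <= n and n >= 1")
    h = n - g_count
    out = []
    for combo in itertools.combinations_with_replacement("ACU", h):
        d = {"G": g_count}
        for b in combo:
            d[b] = d.get(b, 0) + 1
        out.append(BaseCount.from_dict({b: k for b, k in d.items() if k}))
    return out


def composition_class_average(
    relative_yields: dict[str, float], n: int, g_count: int
) -> tuple[float, bool, list[str]]:
    """Mean relative yield (treated/control) over a G-incorporation class.

    *relative_yields* maps composition strings (e.g. "A1U1") to ratios.
    Classes with partially missing members average over the detected members
    and return completeness False — non-detections are routine in MS.
    Returns (mean, complete, class member strings).
    """
    members = [str(c) for c in composition_class(n, g_count)]
    present = [relative_yields[m] for m in members if m in relative_yields]
    if not present:
        raise ValueError(f"no member of the class (n={n}, G={g_count}) has a value")
    complete = len(present) == len(members)
    return float(np.mean(present)), complete, members


def g_fraction(products: ConcentrationTable, min_length: int = 2) -> float:
    """Fraction of oligomer nucleotides that are G (the pool's G-bias)."""
    df = products.oligomers(min_length)
    if df.empty:
        raise ValueError("product table contains no oligomers")
    comps = [parse_species(s).composition for s in df["species"]]
    g_nucl = float(sum(c.nG * conc for c, conc in zip(comps, df["conc_mM"])))
    all_nucl = float(sum(c.n * conc for c, conc in zip(comps, df["conc_mM"])))
    return g_nucl / all_nucl


@dataclass(frozen=True)
class LinkageIntegrals:
    """31P-NMR integrals of the 3'-5' (natural) and 2'-5' linkage signals."""

    integral_35: float
    integral_25: float

    def __post_init__(self) -> None:
        if self.integral_35 < 0 or self.integral_25 < 0:
            raise ValueError("integrals must be non-negative")
        if self.integral_35 == 0 and self.integral_25 == 0:
            raise ValueError("at least one integral must be positive")


def natural_linkage_fraction(li: LinkageIntegrals) -> float:
    """Percent of phosphodiester linkages in the natural 3'-5' form."""
    return 100.0 * li.integral_35 / (li.integral_35 + li.integral_25)


def cyclic_terminus_fraction(products: ConcentrationTable, min_length: int = 2) -> float:
    """Fraction of oligomer molecules retaining the activated cyclic terminus."""
    df = products.oligomers(min_length)
    if df.empty:
        raise ValueError("product table contains no oligomers")
    total = float(df["conc_mM"].sum())
    cyc = float(df.loc[df["terminus"] == Terminus.CYCLIC.value, "conc_mM"].sum())
    return cyc / total


def null_deviation(
    products: ConcentrationTable, null: NullExpectation, min_length: int = 2
) -> tuple[pd.DataFrame, float]:
    """Observed-vs-null comparison per composition.

    Returns a table with columns (length, composition, observed_mM,
    expected_mM, log2_ratio, missing) and a chi-square-style summary
    statistic sum (obs - exp)^2 / exp over compositions with exp > 0.
    Compositions absent from the observations enter with observed 0 and a
    missing flag (their log ratio is reported as NaN, not -inf).
    """
    obs = _composition_totals(products, min_length)
    merged = null.table.merge(
        obs.rename(columns={"conc_mM": "observed_mM"}),
        on=["length", "composition"],
        how="left",
    )
    if merged["observed_mM"].isna().all():
        raise ValueError("no overlap between observed and null compositions")
    merged["observed_mM"] = merged["observed_mM"].fillna(0.0)
    with np.errstate(divide="ignore"):
        ratio = merged["observed_mM"] / merged["expected_mM"]
        merged["log2_ratio"] = np.where(ratio > 0, np.log2(ratio), np.nan)
    merged["missing"] = merged["observed_mM"] == 0.0
    valid = merged["expected_mM"] > 0
    chi2 = float(
        (
            (merged.loc[valid, "observed_mM"] - merged.loc[valid, "expected_mM"]) ** 2
            / merged.loc[valid, "expected_mM"]
        ).sum()
    )
    cols = ["length", "composition", "observed_mM", "expected_mM", "log2_ratio", "missing"]
    return merged[cols], chi2
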