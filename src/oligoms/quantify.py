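"""Isotope-envelope quantification: peak lists -> calibrated species concentrations.

The centre of this module is :class:`EnvelopeQuant`, a model object in the
statsmodels idiom: it is constructed from a centroided peak list plus a
candidate species list, and ``fit()`` returns an
:class:`EnvelopeQuantResults` carrying non-negative per-species signal
amplitudes, calibrated concentrations, uncertainties and diagnostics.

Fitting builds a design matrix whose rows are observed peaks and whose
columns are candidate species (predicted isotope envelopes over all charge
states), and solves for non-negative amplitudes by NNLS.  Species whose
predicted envelopes are indistinguishable at the working mass tolerance are
collapsed into an ambiguity group before fitting and the group concentration
is split equally among members — a reporting rule, not an inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .chemistry import (
    PROTON_MASS,
    IsotopeEnvelope,
    OligomerSpecies,
    isotope_envelope,
    parse_species,
    species_formula,
)

__all__ = [
    "AmbiguityGroup",
    "CalibrationModel",
    "ConcentrationTable",
    "EnvelopeQuant",
    "EnvelopeQuantResults",
    "PeakList",
    "charge_weights",
    "detect_ambiguities",
    "fit_calibration",
    "fit_envelopes",
    "match_peaks",
    "quantify",
]

#: Default working mass tolerance (TOF-class instrument).
DEFAULT_TOLERANCE_PPM = 10.0

#: Absolute neutral-mass floor for ambiguity detection: TOF peaks closer than
#: this are not resolvable regardless of ppm tolerance (the A5 / G3C2 case).
AMBIGUITY_FLOOR_DA = 0.05

#: Geometric decay of successive charge states in negative-mode ESI.
CHARGE_DECAY = 0.5

#: Resolving power of the simulated/assumed TOF: peaks closer than
#: m/z / TOF_RESOLVING_POWER are reported as one centroid.
TOF_RESOLVING_POWER = 20000.0

#: Matching floor in ppm used by the envelope fit: centroids of unresolved
#: neighbouring peaks can sit up to ~half the centroiding width
#: (0.5e6 / resolving power ppm) away from any single contributor, so the
#: fit matches at least this loosely even when the stated working tolerance
#: is tighter.
MATCH_FLOOR_PPM = 30.0


@dataclass
class PeakList:
    """A centroided spectrum: sorted m/z values, non-negative intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    ppm_accuracy: float = DEFAULT_TOLERANCE_PPM
    condition_id: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        order = np.argsort(mz)
        self.mz = mz[order]
        self.intensity = inten[order]
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return int(self.mz.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mz": self.mz, "intensity": self.intensity})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "PeakList":
        df = pd.read_csv(path)
        return cls(df["mz"].to_numpy(), df["intensity"].to_numpy(), **kwargs)

    @classmethod
    def from_mzml(cls, path, scan: int = 0, **kwargs) -> "PeakList":
        """Read one centroided scan from an mzML file (requires pyteomics)."""
        from pyteomics import mzml

        with mzml.MzML(str(path)) as reader:
            for i, spectrum in enumerate(reader):
                if i == scan:
                    return cls(
                        np.asarray(spectrum["m/z array"], dtype=float),
                        np.asarray(spectrum["intensity array"], dtype=float),
                        **kwargs,
                    )
        raise IndexError(f"scan {scan} not found in {path}")


_TABLE_COLUMNS = [
    "species",
    "length",
    "terminus",
    "conc_mM",
    "sd_mM",
    "ambiguity_group",
    "detected",
]


class ConcentrationTable:
    """Species -> concentration per reaction condition; the pipeline's central table.

    Wraps a DataFrame with columns (species, length, terminus, conc_mM,
    sd_mM, ambiguity_group, detected).  Species strings are unique and
    concentrations non-negative.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col, default in (
            ("sd_mM", 0.0),
            ("ambiguity_group", None),
            ("detected", True),
        ):
            if col not in df.columns:
                df[col] = default
        if "length" not in df.columns or "terminus" not in df.columns:
            parsed = [parse_species(s) for s in df["species"]]
            df["length"] = [p.length for p in parsed]
            df["terminus"] = [p.terminus.value for p in parsed]
        df = df[_TABLE_COLUMNS].reset_index(drop=True)
        if df["species"].duplicated().any():
            dupes = df.loc[df["species"].duplicated(), "species"].tolist()
            raise ValueError(f"duplicate species rows: {dupes}")
        if (df["conc_mM"] < 0).any():
            raise ValueError("concentrations must be non-negative")
        self.df = df

    @classmethod
    def from_species(cls, items) -> "ConcentrationTable":
        """Build from an iterable of (OligomerSpecies, conc_mM[, sd_mM]) tuples."""
        rows = []
        for item in items:
            sp, conc = item[0], item[1]
            sd = item[2] if len(item) > 2 else 0.0
            rows.append(
                {
                    "species": str(sp),
                    "length": sp.length,
                    "terminus": sp.terminus.value,
                    "conc_mM": float(conc),
                    "sd_mM": float(sd),
                    "ambiguity_group": None,
                    "detected": True,
                }
            )
        return cls(pd.DataFrame(rows, columns=_TABLE_COLUMNS))

    def species(self) -> list[OligomerSpecies]:
        return [parse_species(s) for s in self.df["species"]]

    def concentration(self, sp: OligomerSpecies | str) -> float:
        key = str(sp)
        hit = self.df.loc[self.df["species"] == key, "conc_mM"]
        if hit.empty:
            raise KeyError(f"species {key} not in table")
        return float(hit.iloc[0])

    def oligomers(self, min_length: int = 2) -> pd.DataFrame:
        return self.df[self.df["length"] >= min_length]

    def total_nucleotides(self) -> float:
        """Sum of concentration x length over every row (monomers included)."""
        return float((self.df["conc_mM"] * self.df["length"]).sum())

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for _, row in self.df.iterrows():
            yield parse_species(row["species"]), float(row["conc_mM"])

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ConcentrationTable":
        return cls(pd.read_csv(path))


@dataclass
class CalibrationModel:
    """Per-length instrument response: through-origin slope (intensity per mM).

    Lengths without standards borrow the nearest calibrated length's slope;
    such queries are flagged so downstream tables can mark them.
    """

    slopes: dict[int, float]
    diagnostics: dict[int, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.slopes.values()):
            raise ValueError("calibration slopes must be positive")

    def slope_for(self, length: int) -> tuple[float, bool]:
        """Return (slope, exact) where exact is False for a borrowed slope."""
        if not self.slopes:
            raise ValueError("no calibrated lengths")
        if length in self.slopes:
            return self.slopes[length], True
        nearest = min(self.slopes, key=lambda l: (abs(l - length), l))
        return self.slopes[nearest], False

    def __call__(self, length: int) -> float:
        return self.slope_for(length)[0]

    @classmethod
    def constant(cls, slope: float, lengths=range(1, 8)) -> "CalibrationModel":
        return cls({int(l): float(slope) for l in lengths})

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"length": list(self.slopes), "slope": list(self.slopes.values())}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CalibrationModel":
        df = pd.read_csv(path)
        return cls({int(r.length): float(r.slope) for r in df.itertuples()})


@dataclass(frozen=True)
class AmbiguityGroup:
    """Species whose envelopes coincide within the working mass tolerance.

    Members share one fitted amplitude; the equal-split reporting rule gives
    every member the group concentration divided by the group size.
    """

    members: tuple[OligomerSpecies, ...]
    group_id: int

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("an ambiguity group needs at least two members")

    def __len__(self) -> int:
        return len(self.members)


def charge_weights(length: int, charges) -> dict[int, float]:
    """Geometric charge-state weights over z = 1..min(length, 3), normalised.

    The shared instrument-response assumption of the simulator and the
    fitter: successive charge states decay by :data:`CHARGE_DECAY`, and an
    n-mer supports at most min(n, 3) charges.
    """
    zmax = min(int(length), 3)
    zs = [z for z in charges if 1 <= z <= zmax]
    if not zs:
        return {}
    w = np.array([CHARGE_DECAY ** (z - 1) for z in zs])
    w = w / w.sum()
    return {z: float(wi) for z, wi in zip(zs, w)}


def match_peaks(pl: PeakList, predicted_mz, tolerance_ppm: float) -> np.ndarray:
    """Nearest observed peak within *tolerance_ppm* for each predicted m/z (-1 if none).

    A single observed peak may serve several predictions (the overlap case);
    callers treat shared assignments as overlapped.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    predicted_mz = np.asarray(predicted_mz, dtype=float)
    out = np.full(predicted_mz.shape, -1, dtype=int)
    if len(pl) == 0 or predicted_mz.size == 0:
        return out
    idx = np.searchsorted(pl.mz, predicted_mz)
    for i, (p, j) in enumerate(zip(predicted_mz, idx)):
        best, best_d = -1, np.inf
        for k in (j - 1, j):
            if 0 <= k < len(pl):
                d = abs(pl.mz[k] - p)
                if d < best_d:
                    best, best_d = k, d
        if best >= 0 and best_d <= tolerance_ppm * 1e-6 * p:
            out[i] = best
    return out


def _envelopes_indistinguishable(
    ea: IsotopeEnvelope,
    eb: IsotopeEnvelope,
    tolerance_ppm: float,
    floor_da: float,
    min_abundance: float = 1e-3,
) -> bool:
    """True when every major isotopologue of the two species coincides in mass."""
    ka = ea.abundances >= min_abundance
    kb = eb.abundances >= min_abundance
    ma, mb = ea.masses[ka], eb.masses[kb]
    if ma.size != mb.size:
        return False
    tol = np.maximum(floor_da, tolerance_ppm * 1e-6 * ma)
    return bool(np.all(np.abs(ma - mb) <= tol))


def detect_ambiguities(
    candidates,
    tolerance_ppm: float = DEFAULT_TOLERANCE_PPM,
    floor_da: float = AMBIGUITY_FLOOR_DA,
    prune: float = 1e-6,
) -> list[AmbiguityGroup]:
    """Maximal groups of candidates with mutually indistinguishable envelopes.

    Masses are compared in neutral-mass space (charge-independent) with a
    per-isotopologue tolerance of max(floor_da, ppm x mass): the absolute
    floor captures pseudo-isobars such as A5 vs G3C2 (0.038 Da apart) that a
    TOF cannot separate at any charge.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    candidates = list(candidates)
    envs = [isotope_envelope(species_formula(s), prune=prune) for s in candidates]
    parent = list(range(len(candidates)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    # sort by monoisotopic mass so only near neighbours need comparing
    order = sorted(range(len(candidates)), key=lambda i: envs[i].monoisotopic_mass)
    for a in range(len(order)):
        i = order[a]
        for b in range(a + 1, len(order)):
            j = order[b]
            if envs[j].monoisotopic_mass - envs[i].monoisotopic_mass > max(
                floor_da, tolerance_ppm * 1e-6 * envs[j].monoisotopic_mass
            ):
                break
            if _envelopes_indistinguishable(envs[i], envs[j], tolerance_ppm, floor_da):
                parent[find(i)] = find(j)
    buckets: dict[int, list[int]] = {}
    for i in range(len(candidates)):
        buckets.setdefault(find(i), []).append(i)
    groups = []
    for members in buckets.values():
        if len(members) > 1:
            groups.append(
                AmbiguityGroup(
                    tuple(sorted((candidates[i] for i in members), key=str)),
                    group_id=len(groups) + 1,
                )
            )
    return groups


class EnvelopeQuant:
    """Non-negative isotope-envelope fit of a peak list against candidate species.

    Parameters
    ----------
    peaklist : PeakList
        Centroided spectrum to fit.
    candidates : sequence of OligomerSpecies
        Species whose predicted envelopes form the design columns; typically
        enumerated from the experiment's alphabet, not learned from data.
    charges : iterable of int
        Negative-mode charge states to model ([M - zH]^z-).
    tolerance_ppm : float
        Working mass tolerance for peak matching.
    calibration : CalibrationModel, optional
        Per-length response; without it only amplitudes are available.
    min_signal : float
        Amplitudes at or below this value are reported as not detected.
    """

    def __init__(
        self,
        peaklist: PeakList,
        candidates,
        charges=(1, 2, 3),
        tolerance_ppm: float = DEFAULT_TOLERANCE_PPM,
        calibration: CalibrationModel | None = None,
        ambiguity_floor_da: float = AMBIGUITY_FLOOR_DA,
        prune: float = 1e-4,
        min_signal: float = 0.0,
        match_floor_ppm: float = MATCH_FLOOR_PPM,
    ):
        self.peaklist = peaklist
        self.candidates = list(candidates)
        if not self.candidates:
            raise ValueError("candidate list must be non-empty")
        if len({str(s) for s in self.candidates}) != len(self.candidates):
            raise ValueError("candidate species must be unique")
        self.charges = sorted(set(int(z) for z in charges))
        if any(z <= 0 for z in self.charges):
            raise ValueError("charges must be positive")
        self.tolerance_ppm = float(tolerance_ppm)
        self.calibration = calibration
        self.ambiguity_floor_da = float(ambiguity_floor_da)
        self.prune = float(prune)
        self.min_signal = float(min_signal)
        self.match_floor_ppm = float(match_floor_ppm)

    # -- design ---------------------------------------------------------

    def _columns(self):
        """Collapse ambiguity-group members into single design columns."""
        groups = detect_ambiguities(
            self.candidates, self.tolerance_ppm, self.ambiguity_floor_da
        )
        grouped: dict[str, AmbiguityGroup] = {}
        for g in groups:
            for sp in g.members:
                grouped[str(sp)] = g
        columns: list[tuple[tuple[OligomerSpecies, ...], AmbiguityGroup | None]] = []
        seen: set[int] = set()
        for sp in self.candidates:
            g = grouped.get(str(sp))
            if g is None:
                columns.append(((sp,), None))
            elif g.group_id not in seen:
                seen.add(g.group_id)
                members = tuple(m for m in g.members if str(m) in {str(c) for c in self.candidates})
                columns.append((members, g))
        return columns, groups

    def _design(self):
        columns, groups = self._columns()
        n_rows = len(self.peaklist)
        A = np.zeros((n_rows, len(columns)))
        unmatched = []
        for col, (members, _) in enumerate(columns):
            for sp in members:
                env = isotope_envelope(species_formula(sp), prune=self.prune)
                weights = charge_weights(sp.length, self.charges)
                for z, wz in weights.items():
                    mz = (env.masses - z * PROTON_MASS) / z
                    rows = match_peaks(
                        self.peaklist,
                        mz,
                        max(self.tolerance_ppm, self.match_floor_ppm),
                    )
                    for r, ab in zip(rows, env.abundances):
                        if r >= 0:
                            A[r, col] += wz * ab / len(members)
            if not A[:, col].any():
                unmatched.append(col)
        return A, columns, groups, unmatched

    # -- fit ------------------------------------------------------------

    def fit(self) -> "EnvelopeQuantResults":
        A, columns, groups, unmatched = self._design()
        y = self.peaklist.intensity
        if A.size and A.any():
            amps, rnorm = scipy.optimize.nnls(A, y)
        else:
            amps, rnorm = np.zeros(A.shape[1]), float(np.linalg.norm(y))
        amps = np.asarray(amps)
        resid = y - A @ amps
        # linearised uncertainty on the active set
        active = np.flatnonzero(amps > 0)
        amp_sd = np.zeros_like(amps)
        dof = max(len(y) - active.size, 1)
        sigma2 = float(resid @ resid) / dof
        if active.size:
            gram = A[:, active].T @ A[:, active]
            cov = np.linalg.pinv(gram) * sigma2
            amp_sd[active] = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        return EnvelopeQuantResults(
            model=self,
            amplitudes=amps,
            amplitude_sd=amp_sd,
            columns=columns,
            groups=groups,
            unmatched_columns=unmatched,
            residuals=resid,
            rnorm=float(rnorm),
        )


@dataclass
class EnvelopeQuantResults:
    """Fit output: per-column amplitudes, ambiguity groups, diagnostics."""

    model: EnvelopeQuant
    amplitudes: np.ndarray
    amplitude_sd: np.ndarray
    columns: list
    groups: list[AmbiguityGroup]
    unmatched_columns: list[int]
    residuals: np.ndarray
    rnorm: float

    def species_amplitudes(self) -> pd.DataFrame:
        """Per-species total ion signal; group members share equally."""
        rows = []
        for col, (members, group) in enumerate(self.columns):
            for sp in members:
                rows.append(
                    {
                        "species": str(sp),
                        "amplitude": float(self.amplitudes[col]) / len(members),
                        "amplitude_sd": float(self.amplitude_sd[col]) / len(members),
                        "ambiguity_group": group.group_id if group else None,
                        "detected": bool(
                            self.amplitudes[col] > self.model.min_signal
                            and col not in self.unmatched_columns
                        ),
                    }
                )
        return pd.DataFrame(rows)

    def group_amplitude(self, group: AmbiguityGroup) -> float:
        for col, (_, g) in enumerate(self.columns):
            if g is not None and g.group_id == group.group_id:
                return float(self.amplitudes[col])
        raise KeyError("group not in fit")

    def concentration_table(self) -> ConcentrationTable:
        """Calibrated concentrations: amplitude / slope(length), equal-split in groups."""
        if self.model.calibration is None:
            raise ValueError("model has no calibration; only amplitudes available")
        amps = self.species_amplitudes()
        rows = []
        for rec in amps.itertuples():
            sp = parse_species(rec.species)
            slope, _exact = self.model.calibration.slope_for(sp.length)
            rows.append(
                {
                    "species": rec.species,
                    "length": sp.length,
                    "terminus": sp.terminus.value,
                    "conc_mM": rec.amplitude / slope,
                    "sd_mM": rec.amplitude_sd / slope,
                    "ambiguity_group": rec.ambiguity_group,
                    "detected": rec.detected,
                }
            )
        return ConcentrationTable(pd.DataFrame(rows, columns=_TABLE_COLUMNS))

    def summary(self) -> str:
        lines = [
            "Isotope-envelope quantification (NNLS)",
            f"  peaks fitted:     {len(self.model.peaklist)}",
            f"  candidates:       {len(self.model.candidates)}",
            f"  ambiguity groups: {len(self.groups)}",
            f"  residual norm:    {self.rnorm:.4g}",
        ]
        table = self.species_amplitudes()
        if self.model.calibration is not None:
            table = self.concentration_table().df
        lines.append(table.to_string(index=False))
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Observed spectrum with the fitted model overlaid (stem plot)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        pl = self.model.peaklist
        ax.vlines(pl.mz, 0, pl.intensity, color="0.6", label="observed")
        A, _, _, _ = self.model._design()
        fitted = A @ self.amplitudes
        ax.vlines(pl.mz, 0, fitted, color="C3", lw=0.8, label="fitted")
        ax.set_xlabel("m/z")
        ax.set_ylabel("intensity")
        ax.legend()
        return ax


def fit_envelopes(
    pl: PeakList,
    candidates,
    charges=(1, 2, 3),
    tolerance_ppm: float = DEFAULT_TOLERANCE_PPM,
) -> pd.DataFrame:
    """Per-species signal amplitudes for *candidates* (functional wrapper)."""
    return EnvelopeQuant(pl, candidates, charges, tolerance_ppm).fit().species_amplitudes()


def quantify(
    pl: PeakList,
    candidates,
    calibration: CalibrationModel,
    tolerance_ppm: float = DEFAULT_TOLERANCE_PPM,
    charges=(1, 2, 3),
    min_signal: float = 0.0,
) -> ConcentrationTable:
    """Peak list -> calibrated ConcentrationTable (functional wrapper)."""
    model = EnvelopeQuant(
        pl,
        candidates,
        charges=charges,
        tolerance_ppm=tolerance_ppm,
        calibration=calibration,
        min_signal=min_signal,
    )
    return model.fit().concentration_table()


def fit_calibration(
    standards,
    charges=(1, 2, 3),
    tolerance_ppm: float = DEFAULT_TOLERANCE_PPM,
    min_levels: int = 3,
) -> CalibrationModel:
    """Through-origin response slopes per length from calibration standards.

    *standards* is a sequence of (PeakList, ConcentrationTable) pairs with
    known concentrations.  Each standard is envelope-fitted for amplitudes;
    per length, the slope is the through-origin least-squares fit of
    amplitude against known concentration.  Lengths with fewer than
    *min_levels* distinct concentration levels are left uncalibrated (they
    will borrow the nearest length's slope, flagged).
    """
    points: dict[int, list[tuple[float, float]]] = {}
    for pl, known in standards:
        species = known.species()
        amps = fit_envelopes(pl, species, charges, tolerance_ppm)
        amp_by_species = dict(zip(amps["species"], amps["amplitude"]))
        for sp, conc in known:
            if conc > 0:
                points.setdefault(sp.length, []).append((conc, amp_by_species[str(sp)]))
    slopes: dict[int, float] = {}
    diagnostics: dict[int, dict] = {}
    for length, pts in sorted(points.items()):
        concs = np.array([c for c, _ in pts])
        amps = np.array([a for _, a in pts])
        n_levels = len(np.unique(np.round(concs, 12)))
        if n_levels < min_levels:
            diagnostics[length] = {"calibrated": False, "n_levels": n_levels}
            continue
        slope = float((amps @ concs) / (concs @ concs))
        resid = amps - slope * concs
        slopes[length] = slope
        diagnostics[length] = {
            "calibrated": True,
            "n_points": len(pts),
            "n_levels": n_levels,
            "residual_norm": float(np.linalg.norm(resid)),
        }
    if not slopes:
        raise ValueError(f"no length had >= {min_levels} concentration levels")
    return CalibrationModel(slopes, diagnostics)


def enumerate_candidates(alphabet, max_length: int, termini=None) -> list[OligomerSpecies]:
    """All compositions over *alphabet* up to *max_length*, with both termini."""
    import itertools

    from .chemistry import BaseCount, Terminus

    termini = list(termini) if termini is not None else [Terminus.CYCLIC, Terminus.LINEAR]
    out = []
    for n in range(1, max_length + 1):
        for combo in itertools.combinations_with_replacement(sorted(set(alphabet)), n):
            bc = BaseCount.from_sequence("".join(combo))
            for t in termini:
                out.append(OligomerSpecies(bc, t))
    return out
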