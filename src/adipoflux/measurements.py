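"""GC-MS measurement processing.

Natural-abundance correction of raw mass-isotopomer distributions (MIDs),
mole percent enrichment, extracellular exchange rates from medium
concentration differences, desaturation indices, and absolute de novo
lipogenesis amounts.

Correction follows the classical correction-matrix approach: column ``j``
of the matrix is the mass distribution a fragment would show if exactly
``j`` backbone carbons were 13C and every remaining atom (including
derivatization carbons, H, N, O, Si, S) sat at natural isotope abundance.
The corrected MID is the non-negative least-squares solution of
``observed = M @ corrected``, renormalized to a simplex vector.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

#: Natural isotope abundances (fractional, by mass shift above the
#: monoisotopic species).  NIST standard atomic compositions.
NATURAL_ABUNDANCE: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "Si": (0.92223, 0.04685, 0.03092),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
}

#: Default MID measurement standard deviation (mol fraction).
DEFAULT_MID_SD = 0.003

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str | dict[str, int]) -> dict[str, int]:
    if isinstance(formula, dict):
        return dict(formula)
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        if m.group(1):
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


@dataclass
class MID:
    """Natural-abundance-corrected mass-isotopomer distribution of one
    fragment: fractions M0..Mn over the ``n_backbone`` tracer-relevant
    carbons, with per-channel measurement standard deviations."""

    metabolite: str
    fragment: str
    n_backbone: int
    fractions: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, float)
        if len(self.fractions) != self.n_backbone + 1:
            raise ValueError(
                f"{self.metabolite}/{self.fragment}: expected {self.n_backbone + 1} "
                f"channels, got {len(self.fractions)}"
            )
        if (self.fractions < -1e-9).any():
            raise ValueError(f"{self.metabolite}: negative MID fraction")
        if abs(self.fractions.sum() - 1.0) > 1e-6:
            raise ValueError(f"{self.metabolite}: MID fractions sum to {self.fractions.sum()}")
        if self.sd is None:
            self.sd = np.full(self.n_backbone + 1, DEFAULT_MID_SD)
        else:
            self.sd = np.asarray(self.sd, float)
            if (self.sd <= 0).any():
                raise ValueError("MID sd must be positive")


def _element_dist(element: str, count: int, abundances: dict | None = None) -> np.ndarray:
    dist = np.array([1.0])
    if count == 0:
        return dist
    table = abundances or NATURAL_ABUNDANCE
    single = np.asarray(table[element])
    for _ in range(count):
        dist = np.convolve(dist, single)
    return dist


def correction_matrix(
    elemental_formula: str | dict[str, int],
    n_backbone: int,
    n_rows: int | None = None,
    abundances: dict | None = None,
) -> np.ndarray:
    """Map corrected backbone-label distributions to observed ones.

    Column ``j`` (``j = 0..n_backbone``) is the observed mass distribution
    of the fragment with exactly ``j`` backbone carbons as 13C and all other
    atoms at natural abundance; rows are observed mass shifts (truncated at
    ``n_rows``, default ``n_backbone + 1``).
    """
    counts = parse_formula(elemental_formula)
    n_c = counts.get("C", 0)
    if n_backbone > n_c:
        raise ValueError(f"n_backbone={n_backbone} exceeds {n_c} carbons in formula")
    if n_rows is None:
        n_rows = n_backbone + 1
    non_carbon = np.array([1.0])
    for el, cnt in counts.items():
        if el != "C":
            non_carbon = np.convolve(non_carbon, _element_dist(el, cnt, abundances))
    M = np.zeros((n_rows, n_backbone + 1))
    for j in range(n_backbone + 1):
        dist = np.convolve(_element_dist("C", n_c - j, abundances), non_carbon)
        dist = np.concatenate([np.zeros(j), dist])  # j labeled carbons: +j shift
        M[:, j] = dist[:n_rows] if len(dist) >= n_rows else np.pad(dist, (0, n_rows - len(dist)))
    return M


def correct_mid(
    raw: np.ndarray,
    elemental_formula: str | dict[str, int],
    n_backbone: int,
    metabolite: str = "",
    fragment: str = "",
    neg_tol: float = 0.01,
) -> MID:
    """Natural-abundance-correct a raw observed mass distribution.

    Solves ``observed = M @ corrected`` by non-negative least squares and
    renormalizes the result to a simplex vector.
    """
    raw = np.asarray(raw, float)
    if len(raw) < n_backbone + 1:
        raise ValueError("raw vector shorter than n_backbone + 1")
    if not raw.any():
        raise ValueError("all-zero raw mass distribution")
    if raw.min() < -neg_tol:
        raise ValueError(f"raw entry {raw.min():.4g} below -{neg_tol}")
    raw = np.clip(raw, 0.0, None)
    raw = raw / raw.sum()
    M = correction_matrix(elemental_formula, n_backbone, n_rows=len(raw))
    corrected, _ = scipy.optimize.nnls(M, raw)
    total = corrected.sum()
    if total <= 0:
        raise ValueError("correction produced an all-zero MID")
    return MID(metabolite, fragment, n_backbone, corrected / total)


def mpe(mid: MID | np.ndarray, n_backbone: int | None = None) -> float:
    """Mole percent enrichment: ``100 * sum_i(M_i * i) / n`` over the
    backbone carbons."""
    if isinstance(mid, MID):
        fractions, n = mid.fractions, mid.n_backbone
    else:
        fractions = np.asarray(mid, float)
        n = n_backbone if n_backbone is not None else len(fractions) - 1
    if n == 0:
        raise ValueError("MPE undefined for a fragment with zero backbone carbons")
    i = np.arange(len(fractions))
    return 100.0 * float((fractions * i).sum()) / n


@dataclass
class RateMeasurement:
    """Extracellular exchange rate from fresh/spent medium concentrations.

    ``flux`` is positive for consumption when ``direction == 'uptake'`` and
    positive for release when ``direction == 'secretion'`` (nmol/well/h).
    """

    species: str
    fresh_conc: float  # nmol/ul
    spent_conc: float  # nmol/ul
    volume_ul: float
    hours: float
    direction: str
    flux: float
    sd: float = 0.0


def exchange_rate(
    fresh_conc: float,
    spent_conc: float,
    volume_ul: float,
    hours: float,
    direction: str = "auto",
    species: str = "",
) -> RateMeasurement:
    """Exchange rate (nmol/well/h) from medium concentration change.

    uptake = (fresh - spent) * volume / hours; secretion is its negation.
    ``direction='auto'`` reports whichever is non-negative.
    """
    if hours <= 0:
        raise ValueError("elapsed time must be positive")
    if fresh_conc < 0 or spent_conc < 0:
        raise ValueError("concentrations must be non-negative")
    uptake = (fresh_conc - spent_conc) * volume_ul / hours
    if direction == "auto":
        direction = "uptake" if uptake >= 0 else "secretion"
    if direction == "uptake":
        flux = uptake
    elif direction == "secretion":
        flux = -uptake
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return RateMeasurement(species, fresh_conc, spent_conc, volume_ul, hours, direction, flux)


def desaturation_index(fa_totals: dict[str, float]) -> dict[str, float]:
    """Monounsaturated/saturated abundance ratios C16:1/C16:0 and C18:1/C18:0."""
    out = {}
    for mono, sat in (("C16:1", "C16:0"), ("C18:1", "C18:0")):
        if mono not in fa_totals or sat not in fa_totals:
            raise KeyError(f"missing fatty acid {mono if mono not in fa_totals else sat}")
        if fa_totals[sat] <= 0:
            raise ValueError(f"non-positive denominator abundance for {sat}")
        out[f"{mono}/{sat}"] = fa_totals[mono] / fa_totals[sat]
    return out


def absolute_dnl(
    fraction_new: dict[str, float], pool_nmol: dict[str, float]
) -> dict[str, float]:
    """Absolute amount synthesized de novo over the tracing window:
    fraction-newly-synthesized (D) times pool size, per fatty acid, plus the
    summed total under key ``'total'``."""
    out: dict[str, float] = {}
    for fa, d in fraction_new.items():
        if not 0.0 <= d <= 1.0:
            raise ValueError(f"fraction_new[{fa}] = {d} outside [0, 1]")
        pool = pool_nmol[fa]
        if pool < 0:
            raise ValueError(f"pool_nmol[{fa}] negative")
        out[fa] = d * pool
    out["total"] = sum(out.values())
    return out


# -- CSV interfaces -------------------------------------------------------


def read_mid_table(path) -> list[MID]:
    """Read a corrected-MID CSV (columns: metabolite, fragment, n_backbone,
    m0..mk, optional sd0..sdk)."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        n = int(row["n_backbone"])
        fractions = np.array([row[f"m{i}"] for i in range(n + 1)], float)
        sd = None
        if f"sd0" in df.columns and not pd.isna(row["sd0"]):
            sd = np.array([row[f"sd{i}"] for i in range(n + 1)], float)
        out.append(MID(str(row["metabolite"]), str(row.get("fragment", "")), n, fractions, sd))
    return out


def write_mid_table(mids: list[MID], path) -> None:
    n_max = max(m.n_backbone for m in mids)
    rows = []
    for m in mids:
        row = {"metabolite": m.metabolite, "fragment": m.fragment, "n_backbone": m.n_backbone}
        for i in range(n_max + 1):
            row[f"m{i}"] = m.fractions[i] if i <= m.n_backbone else np.nan
        for i in range(n_max + 1):
            row[f"sd{i}"] = m.sd[i] if i <= m.n_backbone else np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_rate_table(path) -> list[RateMeasurement]:
    """Read a rates CSV (species, fresh_conc, spent_conc, volume_ul, hours,
    optional direction)."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(
            exchange_rate(
                float(row["fresh_conc"]), float(row["spent_conc"]),
                float(row["volume_ul"]), float(row["hours"]),
                direction=str(row["direction"]) if "direction" in df.columns else "auto",
                species=str(row["species"]),
            )
        )
    return out
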