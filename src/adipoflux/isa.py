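"""Isotopomer spectral analysis (ISA) of fatty-acid synthesis.

ISA fits a polymerization model to a corrected fatty-acid MID: a newly
synthesized palmitate molecule is the condensation of 8 acetyl-CoA units,
and an odd-chain fatty acid (C15:0, C17:0) is 1 propionyl-CoA primer plus
6 or 7 acetyl-CoA units.  Under a uniformly labeled tracer each lipogenic
acetyl unit is M2 with probability ``g`` (the fractional enrichment of the
lipogenic acetyl-CoA pool), so the MID of a de novo molecule is a
convolution power of the unit MID.  The measured pool is the mixture
``D * synthesized + (1 - D) * unlabeled`` where ``D`` is the fraction of
the pool newly synthesized during the tracing window.

Confidence intervals follow the SSR-sensitivity (profile likelihood)
construction: each parameter is swept away from its optimum, re-optimizing
the others, until the weighted SSR exceeds its minimum by the 95% chi-square
quantile for one degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.stats

from .measurements import DEFAULT_MID_SD, MID

CHI2_1_95 = float(scipy.stats.chi2.ppf(0.95, 1))  # 3.841: profile-CI threshold

#: acetyl / propionyl unit composition per fatty acid (2*na + 3*np = carbons)
FA_MODELS = {
    "C16:0": (8, 0),
    "C15:0": (6, 1),
    "C17:0": (7, 1),
}


@dataclass(frozen=True)
class ISAModel:
    """Unit composition of one fatty acid: ``n_acetyl`` acetyl-CoA units and
    ``n_propionyl`` (0 or 1) propionyl-CoA primer."""

    fatty_acid: str
    n_acetyl: int
    n_propionyl: int = 0

    def __post_init__(self):
        if self.n_propionyl not in (0, 1):
            raise ValueError("n_propionyl must be 0 or 1")

    @property
    def n_carbons(self) -> int:
        return 2 * self.n_acetyl + 3 * self.n_propionyl


def model_for(fatty_acid: str) -> ISAModel:
    """ISA model inferred from the fatty-acid name (C16:0, C15:0, C17:0)."""
    try:
        na, npr = FA_MODELS[fatty_acid]
    except KeyError:
        raise KeyError(f"no ISA model for {fatty_acid!r}; known: {sorted(FA_MODELS)}") from None
    return ISAModel(fatty_acid, na, npr)


def synthesized_mid(model: ISAModel, g: float, prop_enrichment: float = 0.0) -> np.ndarray:
    """MID of one newly synthesized fatty-acid molecule.

    Each acetyl unit is fully labeled (M2) with probability ``g`` and
    unlabeled otherwise; the optional propionyl primer is M3 with
    probability ``prop_enrichment``.
    """
    if not (0.0 <= g <= 1.0 and 0.0 <= prop_enrichment <= 1.0):
        raise ValueError("ISA parameters must lie in [0, 1]")
    unit = np.array([1.0 - g, 0.0, g])
    out = np.array([1.0])
    for _ in range(model.n_acetyl):
        out = np.convolve(out, unit)
    if model.n_propionyl:
        prop = np.array([1.0 - prop_enrichment, 0.0, 0.0, prop_enrichment])
        out = np.convolve(out, prop)
    return out


@dataclass
class IsaResults:
    """Fitted ISA parameters with SSR-sensitivity confidence intervals."""

    model: ISAModel
    D: float
    g: float
    prop_enrichment: float
    ssr: float
    measured: np.ndarray
    sd: np.ndarray
    fit_propionyl: bool
    degenerate: bool = False
    _ci: dict[str, tuple[float, float, bool]] = field(default_factory=dict)

    @property
    def params(self) -> dict[str, float]:
        p = {"D": self.D, "g": self.g}
        if self.fit_propionyl:
            p["prop_enrichment"] = self.prop_enrichment
        return p

    def conf_int(self, param: str | None = None):
        """95% CI (lower, upper) per parameter; bounds clipped to [0, 1].
        The third element flags a profile that stayed below the threshold up
        to the parameter boundary."""
        if not self._ci:
            self._ci = isa_confidence(self)
        return self._ci[param] if param else dict(self._ci)

    def predicted(self) -> np.ndarray:
        syn = synthesized_mid(self.model, self.g, self.prop_enrichment)
        unl = np.zeros_like(syn)
        unl[0] = 1.0
        return self.D * syn + (1.0 - self.D) * unl

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            f"ISA fit: {self.model.fatty_acid} "
            f"({self.model.n_acetyl} AcCoA + {self.model.n_propionyl} PropCoA)",
            f"  SSR = {self.ssr:.4g}" + ("  [degenerate: unlabeled pool]" if self.degenerate else ""),
        ]
        for name, value in self.params.items():
            lo, hi, flat = ci[name]
            note = " (profile flat to boundary)" if flat else ""
            lines.append(f"  {name:>16s} = {value:.4f}  95% CI [{lo:.4f}, {hi:.4f}]{note}")
        return "\n".join(lines)


class IsaModel:
    """ISA estimation problem for one measured fatty-acid MID.

    Parameters
    ----------
    measured : MID or array of fractions (length carbons + 1)
    fatty_acid : name used to infer the unit composition when ``measured``
        is a bare array
    sd : per-channel measurement standard deviation (defaults to the MID's
        own sd, or 0.003)
    fit_propionyl : also estimate the propionyl-unit enrichment (otherwise
        fixed at ``prop_enrichment``)
    """

    def __init__(
        self,
        measured: MID | np.ndarray,
        fatty_acid: str | None = None,
        sd: np.ndarray | float | None = None,
        fit_propionyl: bool = False,
        prop_enrichment: float = 0.0,
    ):
        if isinstance(measured, MID):
            fatty_acid = fatty_acid or measured.metabolite
            self.measured = measured.fractions
            default_sd = measured.sd
        else:
            self.measured = np.asarray(measured, float)
            default_sd = np.full(len(self.measured), DEFAULT_MID_SD)
        if fatty_acid is None:
            raise ValueError("fatty_acid required when measured is a bare array")
        self.model = model_for(fatty_acid)
        if len(self.measured) != self.model.n_carbons + 1:
            raise ValueError(
                f"{fatty_acid}: expected {self.model.n_carbons + 1} channels, "
                f"got {len(self.measured)}"
            )
        if sd is None:
            self.sd = np.asarray(default_sd, float)
        elif np.isscalar(sd):
            self.sd = np.full(len(self.measured), float(sd))
        else:
            self.sd = np.asarray(sd, float)
        self.fit_propionyl = fit_propionyl
        self.prop_enrichment = prop_enrichment

    # residuals over all channels, weighted by sd
    def _residuals(self, D: float, g: float, prop: float) -> np.ndarray:
        syn = synthesized_mid(self.model, g, prop)
        pred = D * syn
        pred[0] += 1.0 - D
        return (pred - self.measured) / self.sd

    def ssr(self, D: float, g: float, prop: float | None = None) -> float:
        p = self.prop_enrichment if prop is None else prop
        r = self._residuals(D, g, p)
        return float(r @ r)

    def fit(self, grid: int = 11) -> IsaResults:
        """Grid-refined bounded least squares over (D, g[, prop]).

        An initial ``grid x grid`` scan avoids the local minima of the D-g
        trade-off before trust-region refinement.
        """
        free_prop = self.fit_propionyl
        gridpts = np.linspace(0.0, 1.0, grid)
        prop_pts = gridpts[::2] if free_prop else [self.prop_enrichment]
        scored = sorted(
            (self.ssr(d0, g0, p0), (d0, g0, p0))
            for d0 in gridpts for g0 in gridpts for p0 in prop_pts
        )

        def fun(x):
            if free_prop:
                return self._residuals(x[0], x[1], x[2])
            return self._residuals(x[0], x[1], self.prop_enrichment)

        # refine from the few best grid points: the origin is a stationary
        # saddle of the D-g trade-off, so a single start can get trapped there
        res = None
        for _, start in scored[:3]:
            x0 = np.clip(start[: 3 if free_prop else 2], 1e-9, 1 - 1e-9)
            cand = scipy.optimize.least_squares(
                fun, x0, bounds=(0.0, 1.0), xtol=1e-14, ftol=1e-14, gtol=1e-14
            )
            if res is None or cand.cost < res.cost:
                res = cand
        D, g = float(res.x[0]), float(res.x[1])
        prop = float(res.x[2]) if free_prop else self.prop_enrichment
        # all mass at M0: the product D*g is pinned at 0 but D itself is not
        degenerate = bool(self.measured[0] >= 1.0 - 1e-9)
        return IsaResults(
            model=self.model, D=D, g=g, prop_enrichment=prop,
            ssr=float(2 * res.cost), measured=self.measured, sd=self.sd,
            fit_propionyl=free_prop, degenerate=bool(degenerate),
        )


def isa_fit(
    measured: MID | np.ndarray,
    model: ISAModel | str | None = None,
    sd: np.ndarray | float | None = None,
    fit_propionyl: bool = False,
) -> IsaResults:
    """Fit (D, g) to a corrected fatty-acid MID (see :class:`IsaModel`)."""
    fa = model.fatty_acid if isinstance(model, ISAModel) else model
    return IsaModel(measured, fa, sd=sd, fit_propionyl=fit_propionyl).fit()


def _profile_ssr(problem: IsaModel, which: str, value: float, result: IsaResults) -> float:
    """SSR with one parameter fixed and the others re-optimized."""
    free_prop = problem.fit_propionyl
    names = ["D", "g"] + (["prop_enrichment"] if free_prop else [])
    others = [n for n in names if n != which]
    start = np.clip([getattr(result, "prop_enrichment" if n == "prop_enrichment" else n)
                     for n in others], 1e-9, 1 - 1e-9)

    def fun(x):
        vals = {which: value}
        vals.update(dict(zip(others, x)))
        return problem._residuals(
            vals["D"], vals["g"], vals.get("prop_enrichment", problem.prop_enrichment)
        )

    res = scipy.optimize.least_squares(fun, start, bounds=(0.0, 1.0), xtol=1e-12, ftol=1e-12)
    return float(2 * res.cost)


def profile_ssr(result: IsaResults, which: str, value: float) -> float:
    """SSR profiled at ``which = value`` (others re-optimized)."""
    problem = IsaModel(
        result.measured, result.model.fatty_acid, sd=result.sd,
        fit_propionyl=result.fit_propionyl, prop_enrichment=result.prop_enrichment,
    )
    return _profile_ssr(problem, which, value, result)


def isa_confidence(
    result: IsaResults, confidence: float = 0.95
) -> dict[str, tuple[float, float, bool]]:
    """SSR-sensitivity CIs: per parameter (lower, upper, flat_profile_flag).

    Bounds are where the profiled SSR crosses ``SSR_min + chi2(1, confidence)``,
    clipped to [0, 1]; the flag marks a profile that never crossed before the
    parameter boundary (flat / unidentifiable direction).
    """
    thr = result.ssr + float(scipy.stats.chi2.ppf(confidence, 1))
    problem = IsaModel(
        result.measured, result.model.fatty_acid, sd=result.sd,
        fit_propionyl=result.fit_propionyl, prop_enrichment=result.prop_enrichment,
    )
    out: dict[str, tuple[float, float, bool]] = {}
    for name, est in result.params.items():
        bounds = []
        flat = False
        for direction in (-1.0, +1.0):
            limit = 0.0 if direction < 0 else 1.0
            if _profile_ssr(problem, name, limit, result) <= thr:
                bounds.append(limit)
                flat = True
                continue
            lo, hi = sorted((est, limit))
            # bisect for the crossing between estimate and boundary
            a, b = est, limit
            for _ in range(40):
                mid = 0.5 * (a + b)
                if _profile_ssr(problem, name, mid, result) <= thr:
                    a = mid
                else:
                    b = mid
                if abs(b - a) < 1e-5:
                    break
            bounds.append(0.5 * (a + b))
        lo, hi = sorted(bounds)
        out[name] = (lo, hi, flat)
    return out


def results_differ(a: IsaResults, b: IsaResults, param: str = "g") -> bool:
    """True when the 95% CIs of ``param`` do not overlap (the non-overlap
    criterion for calling two fits different)."""
    alo, ahi, _ = a.conf_int(param)
    blo, bhi, _ = b.conf_int(param)
    return ahi < blo or bhi < alo
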