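"""13C metabolic flux analysis: joint nonlinear least squares over tracer
experiments plus measured exchange rates.

The estimation problem is parameterized by the free net fluxes (null-space
coordinates of the stoichiometry + fixed-ratio constraints) and one bounded
exchange coordinate per reversible reaction (``x = t / (1 - t)`` maps
``t in [0, 1)`` onto ``[0, inf)``).  The objective is the variance-weighted
sum of squared residuals (SSR) between simulated and measured MIDs (mass
channels above M0; the simplex constraint removes one channel per fragment)
plus measured exchange-rate residuals.  Irreversibility is enforced by
hinge penalty residuals that vanish on the feasible set.

The best fit over seeded random restarts is assessed by a chi-square test
(SSR inside ``[chi2_{a/2,dof}, chi2_{1-a/2,dof}]``, default ``a = 0.01``) and
per-flux confidence intervals are profiled: the flux is constrained away
from its optimum, all other parameters re-optimized, until the SSR exceeds
its minimum by the 95% chi-square quantile for one degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats

from .emu import EMU, EMUSystem, TracerSpec
from .measurements import MID
from .network import FluxVector, MetabolicNetwork, free_flux_basis

CHI2_1_95 = float(scipy.stats.chi2.ppf(0.95, 1))

_EXCH_T_CAP = 0.999  # exchange coordinate bound; x = t/(1-t) <= 999
_PENALTY_WEIGHT = 100.0


@dataclass
class RateTarget:
    """Measured extracellular rate expressed as a linear combination of net
    fluxes (e.g. net glutamine uptake = v_glnup - v_glnsec)."""

    name: str
    coeffs: dict[str, float]
    value: float
    sd: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError(f"rate {self.name}: sd must be positive")


@dataclass
class TracerExperiment:
    """One tracer condition: corrected measured MIDs (metabolite ids are
    network species) and measured exchange rates."""

    tracer: TracerSpec
    mids: list[MID]
    rates: list[RateTarget] = field(default_factory=list)


@dataclass
class FluxCI:
    reaction: str
    kind: str  # "net" or "exchange"
    lower: float
    upper: float
    threshold_ssr: float
    lower_open: bool = False  # search hit the cap without crossing
    upper_open: bool = False


class FluxModel:
    """Joint MFA estimation problem over one or more tracer experiments."""

    def __init__(self, network: MetabolicNetwork, experiments: list[TracerExperiment]):
        if not experiments:
            raise ValueError("at least one tracer experiment required")
        self.network = network
        self.experiments = list(experiments)
        self.basis = free_flux_basis(network)
        self.exchange_ids = self.basis.exchange_ids
        self.n_free = self.basis.n_free
        self.n_exch = len(self.exchange_ids)
        self.n_params = self.n_free + self.n_exch
        self._rxn_index = {rid: i for i, rid in enumerate(network.reaction_ids)}
        self._irr = np.array([not r.reversible for r in network.reactions])

        self._systems: list[tuple[EMUSystem, list[tuple[MID, EMU]]]] = []
        n_meas = 0
        for exp in self.experiments:
            pairs = []
            for mid in exp.mids:
                nc = network.carbon_counts.get(mid.metabolite)
                if nc is None:
                    raise KeyError(f"measured metabolite {mid.metabolite!r} not in network")
                if mid.n_backbone != nc:
                    raise ValueError(
                        f"{mid.metabolite}: MID has {mid.n_backbone} backbone carbons, "
                        f"network species has {nc}"
                    )
                pairs.append((mid, EMU(mid.metabolite, tuple(range(1, nc + 1)))))
                n_meas += nc  # channels above M0
            targets = sorted({e for _, e in pairs}, key=lambda e: (e.species, e.atoms))
            system = EMUSystem(network, targets)
            self._systems.append((system, pairs))
            n_meas += len(exp.rates)
            for rate in exp.rates:
                for rid in rate.coeffs:
                    if rid not in self._rxn_index:
                        raise KeyError(f"rate {rate.name} references unknown reaction {rid!r}")
        self.n_measurements = n_meas
        self.dof = n_meas - self.n_params

        # constant Jacobian of net fluxes wrt the full parameter vector
        self._dv = np.hstack([self.basis.K, np.zeros((len(network.reactions), self.n_exch))])
        # continuation state for the restart stages: a ridge on the free
        # coordinates damps unbounded futile-cycle directions, and a smoothing
        # width keeps direction-flux gradients alive across sign changes;
        # both are released (None / 0) for the final polish
        self._stage_ridge: float | None = None
        self._stage_eps: float = 0.0

    # -- parameter mapping ------------------------------------------------

    def _flux_vector(self, params: np.ndarray) -> FluxVector:
        theta = params[: self.n_free]
        t = np.clip(params[self.n_free:], 0.0, _EXCH_T_CAP)
        v = self.basis.reconstruct(theta)
        exch = {rid: tj / (1.0 - tj) for rid, tj in zip(self.exchange_ids, t)}
        return FluxVector(dict(zip(self.network.reaction_ids, v)), exch)

    def _dx(self, params: np.ndarray) -> dict[str, np.ndarray]:
        t = np.clip(params[self.n_free:], 0.0, _EXCH_T_CAP)
        out = {}
        for j, rid in enumerate(self.exchange_ids):
            row = np.zeros(self.n_params)
            row[self.n_free + j] = 1.0 / (1.0 - t[j]) ** 2
            out[rid] = row
        return out

    # -- objective --------------------------------------------------------

    def _eval(self, params: np.ndarray, want_jac: bool):
        fv = self._flux_vector(params)
        v = fv.net_array(self.network.reaction_ids)
        dx = self._dx(params) if want_jac else None
        res_blocks, jac_blocks = [], []
        for (system, pairs), exp in zip(self._systems, self.experiments):
            if want_jac:
                mids, sens = system.simulate(fv, exp.tracer, dv=self._dv, dx=dx,
                                             eps=self._stage_eps, check=False)
            else:
                mids = system.simulate(fv, exp.tracer, eps=self._stage_eps, check=False)
            for mid, emu in pairs:
                w = mid.sd[1:]
                res_blocks.append((mids[emu][1:] - mid.fractions[1:]) / w)
                if want_jac:
                    jac_blocks.append(sens[emu][:, 1:].T / w[:, None])
            for rate in exp.rates:
                pred = sum(c * v[self._rxn_index[rid]] for rid, c in rate.coeffs.items())
                res_blocks.append(np.array([(pred - rate.value) / rate.sd]))
                if want_jac:
                    row = np.zeros(self.n_params)
                    for rid, c in rate.coeffs.items():
                        row += c * self._dv[self._rxn_index[rid]]
                    jac_blocks.append(row[None, :] / rate.sd)
        # irreversibility hinge penalties (zero on the feasible set)
        viol = np.minimum(v[self._irr], 0.0)
        res_blocks.append(_PENALTY_WEIGHT * viol)
        if want_jac:
            Jpen = np.where(
                (v[self._irr] < 0.0)[:, None], _PENALTY_WEIGHT * self._dv[self._irr], 0.0
            )
            jac_blocks.append(Jpen)
        if self._stage_ridge is not None:
            w = 1.0 / self._stage_ridge
            res_blocks.append(w * params[: self.n_free])
            if want_jac:
                Jr = np.zeros((self.n_free, self.n_params))
                Jr[:, : self.n_free] = w * np.eye(self.n_free)
                jac_blocks.append(Jr)
        res = np.concatenate(res_blocks)
        return (res, np.vstack(jac_blocks)) if want_jac else (res, None)

    def residuals(self, params: np.ndarray) -> np.ndarray:
        return self._eval(np.asarray(params, float), False)[0]

    def ssr_at(self, fluxes: FluxVector) -> float:
        """Measurement SSR of an explicit flux vector (no penalties)."""
        res_blocks = []
        v = fluxes.net_array(self.network.reaction_ids)
        for (system, pairs), exp in zip(self._systems, self.experiments):
            mids = system.simulate(fluxes, exp.tracer)
            for mid, emu in pairs:
                res_blocks.append((mids[emu][1:] - mid.fractions[1:]) / mid.sd[1:])
            for rate in exp.rates:
                pred = sum(c * v[self._rxn_index[rid]] for rid, c in rate.coeffs.items())
                res_blocks.append(np.array([(pred - rate.value) / rate.sd]))
        r = np.concatenate(res_blocks)
        return float(r @ r)

    # -- optimization -----------------------------------------------------

    def _solve(
        self,
        x0: np.ndarray,
        transform: tuple[np.ndarray, np.ndarray] | None = None,
        ftol: float = 1e-10,
        xtol: float = 1e-10,
        max_nfev: int | None = None,
    ):
        """Bounded trust-region least squares, optionally in an affine
        subspace ``full = b + A @ sub`` (used for profile likelihood)."""
        if transform is None:
            A = np.eye(self.n_params)
            b = np.zeros(self.n_params)
        else:
            A, b = transform
        memo: dict[bytes, tuple[np.ndarray, np.ndarray]] = {}

        def eval_at(sub):
            key = np.asarray(sub).tobytes()
            if key not in memo:
                memo.clear()
                full = b + A @ sub
                res, jac = self._eval(full, True)
                memo[key] = (res, jac @ A)
            return memo[key]

        lb = np.full(A.shape[0], -np.inf)
        ub = np.full(A.shape[0], np.inf)
        lb[self.n_free:] = 0.0
        ub[self.n_free:] = _EXCH_T_CAP
        # subspace bounds: only valid when A keeps exchange coords separable,
        # which holds for the transforms used here (identity blocks)
        sub_lb = np.full(A.shape[1], -np.inf)
        sub_ub = np.full(A.shape[1], np.inf)
        for j in range(A.shape[1]):
            col = A[:, j]
            nz = np.nonzero(col)[0]
            if len(nz) == 1 and nz[0] >= self.n_free:
                sub_lb[j] = (lb[nz[0]] - b[nz[0]]) / col[nz[0]]
                sub_ub[j] = (ub[nz[0]] - b[nz[0]]) / col[nz[0]]
        x0 = np.clip(x0, sub_lb + 1e-12, sub_ub - 1e-12)
        # scale trust-region steps to the disparate parameter magnitudes:
        # net-flux coordinates live on tens-hundreds, exchange coords in [0,1)
        x_scale = np.ones(A.shape[1])
        for j in range(A.shape[1]):
            nz = np.nonzero(A[:, j])[0]
            x_scale[j] = 0.2 if (len(nz) == 1 and nz[0] >= self.n_free) else 25.0
        res = scipy.optimize.least_squares(
            lambda x: eval_at(x)[0], x0, jac=lambda x: eval_at(x)[1],
            bounds=(sub_lb, sub_ub), method="trf", x_scale=x_scale,
            ftol=ftol, xtol=xtol, gtol=1e-12, max_nfev=max_nfev,
        )
        full = b + A @ res.x
        meas_ssr = self._measurement_ssr(full)
        return full, meas_ssr, res

    def _measurement_ssr(self, params: np.ndarray) -> float:
        r = self._eval(params, False)[0][: self.n_measurements]
        return float(r @ r)

    def fit(
        self,
        n_restarts: int = 20,
        seed: int | None = None,
        alpha: float = 0.01,
        vmax: float = 500.0,
        ftol: float = 1e-10,
        xtol: float = 1e-10,
    ) -> "FluxResults":
        """Best local fit over ``n_restarts`` seeded random starting points.

        Free net fluxes start from hit-and-run samples of the bounded
        feasible polytope; exchanges start log-uniform in [0.1, 1000].
        """
        rng = np.random.default_rng(seed)
        # random initial guesses: the minimum-norm solution of the (linear)
        # measured-rate equations anchors the scale, and gaussian draws in
        # the rate null space randomize the internal flux distribution;
        # without rate measurements, hit-and-run polytope samples are used
        rate_rows, rate_vals = [], []
        for exp in self.experiments:
            for rate in exp.rates:
                row = np.zeros(self.n_free)
                for rid, c in rate.coeffs.items():
                    row += c * self.basis.K[self._rxn_index[rid]]
                rate_rows.append(row / rate.sd)
                rate_vals.append(rate.value / rate.sd)
        if rate_rows:
            R, r = np.array(rate_rows), np.array(rate_vals)
            base, *_ = np.linalg.lstsq(R, r, rcond=None)
            NR = scipy.linalg.null_space(R)
            z = rng.normal(0.0, 20.0, size=(n_restarts, NR.shape[1]))
            thetas = base[None, :] + z @ NR.T
        else:
            thetas = self.basis.sample_feasible(rng, n_restarts, vmax=vmax)
        x_start = 10.0 ** rng.uniform(-1.0, 2.0, size=(n_restarts, self.n_exch))
        t_start = x_start / (1.0 + x_start)

        # graduated continuation per restart: a damped, smoothed presolve
        # escapes the flat futile-cycle basins, then the smoothing and ridge
        # are released and the exact objective polished.  Every restart runs
        # the presolve; the most promising presolved points (up to three)
        # carry through the exact polish.
        presolved: list[tuple[float, int, np.ndarray]] = []
        failures = []
        restart_ssrs = [np.inf] * n_restarts
        for k in range(n_restarts):
            x0 = np.concatenate([thetas[k], t_start[k]])
            try:
                self._stage_ridge, self._stage_eps = 150.0, 2.0
                x, s1, _ = self._solve(x0, ftol=1e-7, xtol=1e-7, max_nfev=50)
                presolved.append((s1, k, x))
            except Exception as exc:  # singular simulation from a bad start
                failures.append(f"restart {k}: {exc}")
            finally:
                self._stage_ridge, self._stage_eps = None, 0.0
        best = None
        presolved.sort(key=lambda t: t[0])
        for rank, (s1, k, x) in enumerate(presolved):
            if rank >= 4:
                # exact measurement SSR where this restart's presolve ended
                restart_ssrs[k] = self._measurement_ssr(x)
                continue
            try:
                self._stage_ridge, self._stage_eps = None, 0.3
                x, _, _ = self._solve(x, ftol=1e-8, xtol=1e-8, max_nfev=100)
                self._stage_eps = 1e-6
                full, ssr, res = self._solve(x, ftol=ftol, xtol=xtol, max_nfev=150)
            except Exception as exc:
                failures.append(f"restart {k}: {exc}")
                continue
            finally:
                self._stage_ridge, self._stage_eps = None, 0.0
            restart_ssrs[k] = ssr
            if best is None or ssr < best[1]:
                best = (full, ssr)
        if best is None:
            raise RuntimeError("no restart converged:\n" + "\n".join(failures))
        return FluxResults(self, best[0], best[1], alpha=alpha,
                           n_restarts=n_restarts, restart_ssrs=restart_ssrs, seed=seed)

    # -- profile likelihood ----------------------------------------------

    def _profile_transform(self, reaction: str, kind: str, value: float):
        """Affine map onto the subspace where one flux is held fixed."""
        if kind == "net":
            k = self.basis.K[self._rxn_index[reaction]]
            nk = np.linalg.norm(k)
            if nk < 1e-12:
                return None  # flux structurally pinned; no profile direction
            M = scipy.linalg.null_space(k[None, :])
            theta_p = k * (value / (nk * nk))
            A = np.zeros((self.n_params, self.n_free - 1 + self.n_exch))
            A[: self.n_free, : self.n_free - 1] = M
            A[self.n_free:, self.n_free - 1:] = np.eye(self.n_exch)
            b = np.concatenate([theta_p, np.zeros(self.n_exch)])
            return A, b
        if kind == "exchange":
            j = self.exchange_ids.index(reaction)
            t_fixed = value / (1.0 + value)
            A = np.delete(np.eye(self.n_params), self.n_free + j, axis=1)
            b = np.zeros(self.n_params)
            b[self.n_free + j] = t_fixed
            return A, b
        raise ValueError(f"kind must be 'net' or 'exchange', got {kind!r}")

    def profile_ssr(
        self, reaction: str, value: float, start: np.ndarray,
        kind: str = "net", ftol: float = 1e-8, robust_above: float | None = None,
    ) -> tuple[float, np.ndarray]:
        """Measurement SSR with one flux fixed, all other parameters
        re-optimized from ``start`` (a full parameter vector).

        When the warm-started solve lands above ``robust_above`` — i.e. it
        would decide an SSR-threshold crossing — the re-optimization is
        repeated with the graduated continuation used by :meth:`fit`, which
        escapes the trapped warm path on weakly identified ridges.
        """
        tr = self._profile_transform(reaction, kind, value)
        if tr is None:
            return self._measurement_ssr(start), start
        A, b = tr
        sub0, *_ = np.linalg.lstsq(A, start - b, rcond=None)
        self._stage_eps = 1e-6  # keep gradients smooth across sign changes
        try:
            full, ssr, _ = self._solve(sub0, transform=(A, b), ftol=ftol, xtol=1e-8,
                                       max_nfev=120)
            if robust_above is not None and ssr > robust_above:
                self._stage_ridge, self._stage_eps = 150.0, 2.0
                _, _, r = self._solve(sub0, transform=(A, b), ftol=1e-7, xtol=1e-7,
                                      max_nfev=50)
                self._stage_ridge, self._stage_eps = None, 0.3
                _, _, r = self._solve(r.x, transform=(A, b), ftol=1e-8, xtol=1e-8,
                                      max_nfev=100)
                self._stage_eps = 1e-6
                full2, ssr2, _ = self._solve(r.x, transform=(A, b), ftol=ftol,
                                             xtol=1e-9, max_nfev=150)
                if ssr2 < ssr:
                    full, ssr = full2, ssr2
        finally:
            self._stage_ridge, self._stage_eps = None, 0.0
        return ssr, full


def fit_fluxes(
    network: MetabolicNetwork,
    experiments: list[TracerExperiment],
    n_restarts: int = 20,
    seed: int | None = None,
    alpha: float = 0.01,
) -> "FluxResults":
    """Estimate fluxes by joint least squares with random restarts."""
    return FluxModel(network, experiments).fit(n_restarts=n_restarts, seed=seed, alpha=alpha)


def ssr(network: MetabolicNetwork, fluxes: FluxVector, experiments: list[TracerExperiment]) -> float:
    """Variance-weighted SSR of a flux vector against the measurements."""
    return FluxModel(network, experiments).ssr_at(fluxes)


class FluxResults:
    """Fitted fluxes, goodness of fit and profile confidence intervals."""

    def __init__(self, model: FluxModel, params, ssr, alpha, n_restarts, restart_ssrs, seed):
        self.model = model
        self.params = np.asarray(params, float)
        self.ssr = float(ssr)
        self.alpha = float(alpha)
        self.n_restarts = int(n_restarts)
        self.restart_ssrs = list(restart_ssrs)
        self.seed = seed
        self.fluxes = model._flux_vector(self.params)
        self.dof = model.dof
        lo, hi = scipy.stats.chi2.ppf([alpha / 2.0, 1.0 - alpha / 2.0], self.dof)
        self.chi2_interval = (float(lo), float(hi))
        self.accepted = bool(lo <= self.ssr <= hi)

    # -- chi-square -------------------------------------------------------

    def chi2_test(self, alpha: float | None = None) -> tuple[bool, tuple[float, float]]:
        if self.dof < 1:
            raise ValueError(f"over-parameterized model: dof = {self.dof}")
        a = self.alpha if alpha is None else alpha
        lo, hi = scipy.stats.chi2.ppf([a / 2.0, 1.0 - a / 2.0], self.dof)
        return bool(lo <= self.ssr <= hi), (float(lo), float(hi))

    # -- profile CIs -------------------------------------------------------

    def profile_ssr_at(self, reaction: str, value: float, kind: str = "net") -> float:
        """SSR with ``reaction``'s flux fixed at ``value`` and everything
        else re-optimized (profile likelihood slice)."""
        return self.model.profile_ssr(
            reaction, value, self.params, kind=kind,
            robust_above=self.ssr + CHI2_1_95,
        )[0]

    def confidence_interval(
        self, reaction: str, confidence: float = 0.95, kind: str = "net",
        vcap: float = 1e4,
    ) -> FluxCI:
        """Profile-likelihood CI: expand from the optimum until the profiled
        SSR crosses ``SSR_min + chi2(1, confidence)``, then bisect.  A bound
        that never crosses within ``vcap`` is reported open (unbounded)."""
        thr = self.ssr + float(scipy.stats.chi2.ppf(confidence, 1))
        est = (self.fluxes.net if kind == "net" else self.fluxes.exchange)[reaction]
        rxn = self.model.network.reaction(reaction)
        irreversible = not rxn.reversible
        bounds, open_flags = [], []
        for direction in (-1.0, +1.0):
            start = self.params.copy()
            # hard floor at zero for irreversible nets and all exchanges
            floor = 0.0 if (kind == "exchange" or (kind == "net" and irreversible)) else -vcap
            limit = floor if direction < 0 else vcap
            if direction < 0 and est <= floor + 1e-12:
                bounds.append(floor)
                open_flags.append(False)
                continue
            step = max(0.05 * abs(est), 0.25)
            inside, outside = est, None
            val = est
            while True:
                val = val + direction * step
                if (direction < 0 and val <= limit) or (direction > 0 and val >= limit):
                    val = limit
                s, start = self.model.profile_ssr(reaction, val, start, kind=kind,
                                                  robust_above=thr)
                if s > thr:
                    outside = val
                    break
                inside = val
                if val == limit:
                    break
                step *= 1.7
            if outside is None:
                bounds.append(limit)
                open_flags.append(abs(limit) >= vcap)  # unbounded within the cap
                continue
            a, b = inside, outside
            for _ in range(12):
                mid = 0.5 * (a + b)
                s, start = self.model.profile_ssr(reaction, mid, start, kind=kind,
                                                  robust_above=thr)
                if s <= thr:
                    a = mid
                else:
                    b = mid
                if abs(b - a) <= max(1e-3, 5e-3 * abs(est)):
                    break
            bounds.append(0.5 * (a + b))
            open_flags.append(False)
        lo, hi = bounds
        lo_open, hi_open = open_flags
        return FluxCI(reaction, kind, float(lo), float(hi), thr, lo_open, hi_open)

    # -- reporting ---------------------------------------------------------

    def flux_table(self) -> pd.DataFrame:
        rows = []
        for rxn in self.model.network.reactions:
            rows.append({
                "reaction": rxn.id,
                "net": self.fluxes.net[rxn.id],
                "exchange": self.fluxes.exchange.get(rxn.id, np.nan) if rxn.reversible else np.nan,
                "reversible": rxn.reversible,
                "kind": rxn.kind,
            })
        return pd.DataFrame(rows).set_index("reaction")

    def summary(self) -> str:
        ok, (lo, hi) = self.chi2_test()
        lines = [
            "Metabolic flux analysis fit",
            f"  experiments: {len(self.model.experiments)}  "
            f"measurements: {self.model.n_measurements}  parameters: {self.model.n_params}",
            f"  SSR = {self.ssr:.2f}  dof = {self.dof}  "
            f"chi2 acceptance [{lo:.1f}, {hi:.1f}] at alpha={self.alpha:g} -> "
            f"{'ACCEPTED' if ok else 'REJECTED'}",
            f"  restarts: {self.n_restarts} (best of {sum(np.isfinite(self.restart_ssrs))} "
            f"converged)  seed: {self.seed}",
            "",
            "  reaction        net (exchange)  [nmol/well/h]",
        ]
        for rxn in self.model.network.reactions:
            net = self.fluxes.net[rxn.id]
            if rxn.reversible:
                lines.append(f"  {rxn.id:<14s} {net:9.2f} ({self.fluxes.exchange.get(rxn.id, 0.0):.2f})")
            else:
                lines.append(f"  {rxn.id:<14s} {net:9.2f}")
        return "\n".join(lines)


def chi2_interval(dof: int, alpha: float = 0.01) -> tuple[float, float]:
    """Two-sided chi-square SSR acceptance interval at significance ``alpha``."""
    if dof < 1:
        raise ValueError(f"over-parameterized model: dof = {dof}")
    lo, hi = scipy.stats.chi2.ppf([alpha / 2.0, 1.0 - alpha / 2.0], dof)
    return float(lo), float(hi)


def chi2_goodness_of_fit(fit: FluxResults, alpha: float = 0.01) -> tuple[bool, tuple[float, float]]:
    """Chi-square acceptance test of a fit's SSR at significance ``alpha``."""
    return fit.chi2_test(alpha)


def flux_confidence_interval(
    fit: FluxResults, reaction: str, confidence: float = 0.95, kind: str = "net"
) -> FluxCI:
    """95% (by default) profile-likelihood CI for one flux."""
    return fit.confidence_interval(reaction, confidence=confidence, kind=kind)
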