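"""Steady-state label simulation via elementary metabolite units (EMUs).

An EMU is a specific subset of a metabolite's carbon atoms.  At isotopic
steady state the mass-isotopomer distribution (MID) of every EMU of size
``s`` satisfies a linear balance: flux-weighted mixing of same-size EMUs
plus convolution inputs assembled from strictly smaller EMUs, so the whole
network reduces to a cascade of small linear systems solved in order of
increasing EMU size.

Simulation operates in natural-abundance-corrected MID space (the 12C
backbone contributes no mass shift); dilution species and non-tracer
boundary substrates enter as unlabeled pools, and structurally symmetric
metabolites are consumed as the average of their two carbon orientations.

The module also provides forward sensitivities of every simulated MID with
respect to an arbitrary parameterization of the fluxes, obtained by
differentiating each balance system against the prefactorized operator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse

from .network import BOUNDARY_IN, FluxVector, MetabolicNetwork, Occurrence


class EMUSimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class EMU:
    """A subset of one metabolite's carbon atoms (1-based, sorted)."""

    species: str
    atoms: tuple[int, ...]

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("EMU atom subset must be nonempty")
        object.__setattr__(self, "atoms", tuple(sorted(self.atoms)))

    @property
    def size(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:
        return f"{self.species}[{','.join(map(str, self.atoms))}]"


@dataclass(frozen=True)
class TracerSpec:
    """Isotopic tracer: substrate species, labeled carbon positions, the
    per-position 13C enrichment (isotopic purity) and the fraction of the
    substrate pool that is tracer (1.0 = full replacement)."""

    substrate: str
    positions: tuple[int, ...]
    purity: float = 0.99
    fraction: float = 1.0
    name: str = ""

    def __post_init__(self):
        if not 0.0 <= self.purity <= 1.0 or not 0.0 <= self.fraction <= 1.0:
            raise ValueError("purity and fraction must lie in [0, 1]")

    def emu_mid(self, emu: EMU) -> np.ndarray:
        """Corrected-space MID of an EMU of the (boundary) substrate pool."""
        out = np.zeros(emu.size + 1)
        if emu.species != self.substrate or self.fraction == 0.0:
            out[0] = 1.0
            return out
        k = sum(1 for a in emu.atoms if a in self.positions)
        # tracer molecules: each labeled position is 13C with prob `purity`
        dist = np.array([1.0])
        for _ in range(k):
            dist = np.convolve(dist, [1.0 - self.purity, self.purity])
        out[: k + 1] += self.fraction * dist
        out[0] += 1.0 - self.fraction
        return out


def natural_mid(size: int) -> np.ndarray:
    """Unlabeled corrected-space MID (all mass at M0)."""
    out = np.zeros(size + 1)
    out[0] = 1.0
    return out


# -- reaction expansion ---------------------------------------------------


@dataclass(frozen=True)
class _Variant:
    """One flux-bearing direction of a reaction, with symmetric-metabolite
    orientations expanded (weights sum to 1 per direction)."""

    dir_idx: int
    weight: float
    reactants: tuple[Occurrence, ...]
    products: tuple[Occurrence, ...]


def _expand_variants(net: MetabolicNetwork) -> tuple[list[_Variant], list[tuple[int, bool]]]:
    """All reaction directions with symmetric consumption orientations.

    Returns (variants, dirs) where dirs[k] = (reaction index, is_backward).
    """
    dirs: list[tuple[int, bool]] = []
    variants: list[_Variant] = []
    for ri, rxn in enumerate(net.reactions):
        directions = [(rxn.reactants, rxn.products, False)]
        if rxn.reversible:
            directions.append((rxn.products, rxn.reactants, True))
        for reac, prod, back in directions:
            dir_idx = len(dirs)
            dirs.append((ri, back))
            # enumerate orientations of symmetric reactants
            choices: list[list[Occurrence]] = []
            for occ in reac:
                if occ.species in net.symmetric:
                    choices.append([occ, Occurrence(occ.species, occ.atoms[::-1])])
                else:
                    choices.append([occ])
            combos: list[tuple[Occurrence, ...]] = [()]
            for opts in choices:
                combos = [c + (o,) for c in combos for o in opts]
            w = 1.0 / len(combos) if combos else 1.0
            for combo in combos:
                variants.append(_Variant(dir_idx, w, combo, tuple(prod)))
    return variants, dirs


def direction_fluxes(net: MetabolicNetwork, fluxes: FluxVector) -> np.ndarray:
    """Per-direction flux vector: forward = max(net,0)+exchange, backward =
    max(-net,0)+exchange for reversible reactions, forward = max(net,0)
    otherwise (directions ordered as in the EMU system)."""
    _, dirs = _expand_variants(net)
    return _phi_from(net, dirs, fluxes.net_array(net.reaction_ids), fluxes.exchange)


_PHI_FLOOR = 1e-12  # keeps zero-throughput balances regular (limiting MIDs)


def _pos(net_flux: float, eps: float) -> float:
    """Smoothed positive part: (net + sqrt(net^2 + eps^2))/2.

    ``eps`` = 0 recovers max(net, 0) exactly; a small positive value keeps
    gradients alive across the sign change (used for optimizer continuation).
    """
    if eps == 0.0:
        return max(net_flux, 0.0)
    return 0.5 * (net_flux + np.hypot(net_flux, eps))


def _phi_from(net, dirs, v: np.ndarray, exchange: dict[str, float], eps: float = 0.0) -> np.ndarray:
    phi = np.empty(len(dirs))
    for k, (ri, back) in enumerate(dirs):
        rxn = net.reactions[ri]
        x = exchange.get(rxn.id, 0.0) if rxn.reversible else 0.0
        net_flux = -v[ri] if back else v[ri]
        phi[k] = max(_pos(net_flux, eps) + x, _PHI_FLOOR)
    return phi


def _dphi_from(net, dirs, v, dv: np.ndarray, dx: dict[str, np.ndarray], eps: float = 0.0) -> np.ndarray:
    """Derivative of the direction-flux vector wrt parameters (p columns)."""
    p = dv.shape[1]
    dphi = np.zeros((len(dirs), p))
    for k, (ri, back) in enumerate(dirs):
        rxn = net.reactions[ri]
        g = -1.0 if back else 1.0
        nf = g * v[ri]
        if eps == 0.0:
            slope = 1.0 if nf > 0.0 else 0.0
        else:
            slope = 0.5 * (1.0 + nf / np.hypot(nf, eps))
        if slope:
            dphi[k] += slope * g * dv[ri]
        if rxn.reversible and rxn.id in dx:
            dphi[k] += dx[rxn.id]
    return dphi


# -- decomposition --------------------------------------------------------


@dataclass
class _Term:
    row: int
    dir_idx: int
    weight: float
    sources: tuple[EMU, ...]  # >1 entries = convolution of smaller EMUs

    @property
    def groups(self) -> list[tuple[EMU, int]]:
        """Sources grouped with multiplicity (e.g. 8x the same acetyl EMU
        for palmitate), cached: repeated sources share one sensitivity
        contribution scaled by their count."""
        if not hasattr(self, "_groups"):
            seen: dict[EMU, int] = {}
            for s in self.sources:
                seen[s] = seen.get(s, 0) + 1
            self._groups = list(seen.items())
        return self._groups


@dataclass
class _Level:
    size: int
    emus: list[EMU]
    transfers: list[tuple[int, int, int, float]] = field(default_factory=list)  # (i, j, dir, w)
    inputs: list[_Term] = field(default_factory=list)
    # assembled sparse operators (filled by _compile)
    diag_op: scipy.sparse.csr_matrix | None = None
    trans_op: scipy.sparse.csr_matrix | None = None


def _is_input(species: str) -> bool:
    return Occurrence(species, "").compartment in BOUNDARY_IN


class EMUSystem:
    """Compiled size-ordered EMU reaction graph for a fixed target set."""

    def __init__(self, net: MetabolicNetwork, targets: list[EMU]):
        self.network = net
        self.targets = list(targets)
        self.variants, self.dirs = _expand_variants(net)
        self._consumption: dict[str, list[tuple[int, float]]] = {}
        self._production_count: dict[str, list[tuple[int, float]]] = {}
        for var in self.variants:
            for occ in var.reactants:
                self._consumption.setdefault(occ.species, []).append((var.dir_idx, var.weight))
            for occ in var.products:
                self._production_count.setdefault(occ.species, []).append((var.dir_idx, var.weight))
        self._decompose()
        self._compile()

    # decomposition ------------------------------------------------------

    def _producers(self, emu: EMU) -> list[tuple[int, float, tuple[EMU, ...]]]:
        """Production terms (dir, weight, source EMUs) for one EMU."""
        out = []
        for var in self.variants:
            for occ in var.products:
                if occ.species != emu.species:
                    continue
                letters = [occ.atoms[a - 1] for a in emu.atoms]
                per_source: dict[Occurrence, list[int]] = {}
                missing = []
                for letter in letters:
                    hit = None
                    for r in var.reactants:
                        pos = r.atoms.find(letter)
                        if pos >= 0:
                            hit = (r, pos + 1)
                            break
                    if hit is None:
                        missing.append(letter)
                    else:
                        per_source.setdefault(hit[0], []).append(hit[1])
                if missing:
                    raise EMUSimulationError(
                        f"atoms {missing} of {emu} are created at a non-boundary species "
                        f"in reaction variant of dir {var.dir_idx}"
                    )
                sources = tuple(
                    EMU(r.species, tuple(ps)) for r, ps in sorted(
                        per_source.items(), key=lambda kv: (kv[0].species, kv[0].atoms)
                    )
                )
                out.append((var.dir_idx, var.weight, sources))
        return out

    def _decompose(self):
        todo = [t for t in self.targets if not _is_input(t.species)]
        self._prod_terms: dict[EMU, list[tuple[int, float, tuple[EMU, ...]]]] = {}
        while todo:
            emu = todo.pop()
            if emu in self._prod_terms:
                continue
            terms = self._producers(emu)
            if not terms:
                raise EMUSimulationError(f"{emu} has no producing reactions (untraceable)")
            self._prod_terms[emu] = terms
            for _, _, sources in terms:
                for src in sources:
                    if not _is_input(src.species) and src not in self._prod_terms:
                        todo.append(src)

        sizes = sorted({e.size for e in self._prod_terms})
        self.levels: list[_Level] = []
        for s in sizes:
            emus = sorted((e for e in self._prod_terms if e.size == s),
                          key=lambda e: (e.species, e.atoms))
            level = _Level(size=s, emus=emus)
            index = {e: i for i, e in enumerate(emus)}
            for emu in emus:
                i = index[emu]
                for dir_idx, w, sources in self._prod_terms[emu]:
                    if len(sources) == 1 and sources[0].size == s and not _is_input(sources[0].species):
                        level.transfers.append((i, index[sources[0]], dir_idx, w))
                    else:
                        level.inputs.append(_Term(i, dir_idx, w, sources))
            self.levels.append(level)

    def _compile(self):
        """Assemble sparse (row*n+col, dir) scatter operators per level."""
        n_dirs = len(self.dirs)
        for level in self.levels:
            n = len(level.emus)
            # diagonal: total consumption flux of the parent metabolite
            # (total production for sink species that are never consumed)
            rows, cols, vals = [], [], []
            for i, emu in enumerate(level.emus):
                entries = self._consumption.get(emu.species) or self._production_count.get(emu.species, [])
                if not entries:
                    raise EMUSimulationError(f"{emu.species} has neither consumers nor producers")
                for dir_idx, w in entries:
                    rows.append(i)
                    cols.append(dir_idx)
                    vals.append(w)
            level.diag_op = scipy.sparse.csr_matrix(
                (vals, (rows, cols)), shape=(n, n_dirs)
            )
            rows, cols, vals = [], [], []
            for i, j, dir_idx, w in level.transfers:
                rows.append(i * n + j)
                cols.append(dir_idx)
                vals.append(w)
            level.trans_op = scipy.sparse.csr_matrix(
                (vals, (rows, cols)), shape=(n * n, n_dirs)
            )

    # simulation ---------------------------------------------------------

    def _input_mid(self, emu: EMU, tracer: TracerSpec) -> np.ndarray:
        if tracer is not None and emu.species == tracer.substrate:
            return tracer.emu_mid(emu)
        return natural_mid(emu.size)

    def _static_ops(self, tracer: TracerSpec):
        """Per-level sparse operators for input terms whose sources are all
        boundary pools: their RHS contribution is linear in the direction
        fluxes with tracer-fixed coefficients, so the per-term python loop
        collapses to one sparse matmul (cached per tracer)."""
        if not hasattr(self, "_static_cache"):
            self._static_cache: dict[TracerSpec, list] = {}
        if tracer in self._static_cache:
            return self._static_cache[tracer]
        ops = []
        n_dirs = len(self.dirs)
        for level in self.levels:
            n = len(level.emus)
            width = level.size + 1
            rows, cols, vals = [], [], []
            dynamic = []
            for term in level.inputs:
                if all(_is_input(s.species) for s in term.sources):
                    vec = self._input_mid(term.sources[0], tracer)
                    for src in term.sources[1:]:
                        vec = np.convolve(vec, self._input_mid(src, tracer))
                    for col, val in enumerate(vec):
                        if val != 0.0:
                            rows.append(term.row * width + col)
                            cols.append(term.dir_idx)
                            vals.append(term.weight * val)
                else:
                    dynamic.append(term)
            op = scipy.sparse.csr_matrix((vals, (rows, cols)), shape=(n * width, n_dirs))
            ops.append((op, dynamic))
        self._static_cache[tracer] = ops
        return ops

    def simulate(
        self,
        fluxes: FluxVector,
        tracer: TracerSpec,
        dv: np.ndarray | None = None,
        dx: dict[str, np.ndarray] | None = None,
        eps: float = 0.0,
        check: bool = True,
    ) -> dict[EMU, np.ndarray] | tuple[dict[EMU, np.ndarray], dict[EMU, np.ndarray]]:
        """Simulate MIDs of all decomposed EMUs for one tracer.

        With ``dv`` (per-reaction net-flux Jacobian, shape n_rxn x p) and
        ``dx`` (per-exchange Jacobians), also returns d(MID)/d(params).
        ``eps`` smooths the net-flux direction split (optimizer continuation);
        ``check=False`` skips the ill-posedness guard (optimizers reject bad
        trial points through their huge residuals instead).
        """
        v = fluxes.net_array(self.network.reaction_ids)
        phi = _phi_from(self.network, self.dirs, v, fluxes.exchange, eps)
        want_sens = dv is not None
        dphi = _dphi_from(self.network, self.dirs, v, dv, dx or {}, eps) if want_sens else None
        p = dphi.shape[1] if want_sens else 0

        mids: dict[EMU, np.ndarray] = {}
        sens: dict[EMU, np.ndarray] = {}

        def value(emu: EMU) -> tuple[np.ndarray, np.ndarray | None]:
            if emu in mids:
                return mids[emu], sens.get(emu)
            m = self._input_mid(emu, tracer)
            d = np.zeros((p, emu.size + 1)) if want_sens else None
            return m, d

        static_ops = self._static_ops(tracer)
        for level, (static_op, dynamic_terms) in zip(self.levels, static_ops):
            n = len(level.emus)
            width = level.size + 1
            denom = level.diag_op @ phi
            T = (level.trans_op @ phi).reshape(n, n)
            A = np.diag(denom) - T
            rhs = (static_op @ phi).reshape(n, width)
            if want_sens:
                drhs = np.ascontiguousarray(
                    (static_op @ dphi).reshape(n, width, p).transpose(2, 0, 1))
            else:
                drhs = None
            for term in dynamic_terms:
                f = phi[term.dir_idx] * term.weight
                groups = term.groups
                gvals = [value(e) for e, _ in groups]
                # convolution powers per distinct source
                powers = []
                for (e, cnt), (q, _) in zip(groups, gvals):
                    pw = q
                    for _ in range(cnt - 1):
                        pw = np.convolve(pw, q)
                    powers.append(pw)
                vec = powers[0]
                for pw in powers[1:]:
                    vec = np.convolve(vec, pw)
                rhs[term.row] += f * vec
                if want_sens:
                    df = dphi[term.dir_idx] * term.weight  # (p,)
                    drhs[:, term.row, :] += df[:, None] * vec[None, :]
                    for gi, ((e, cnt), (q, dq)) in enumerate(zip(groups, gvals)):
                        if dq is None or not dq.any():
                            continue
                        # d(q^cnt * rest)/dq = cnt * q^(cnt-1) * rest; apply
                        # the sensitivity rows via one Toeplitz matmul
                        rest = np.array([1.0])
                        for gj, pw in enumerate(powers):
                            if gj != gi:
                                rest = np.convolve(rest, pw)
                        if cnt > 1:
                            pw1 = q
                            for _ in range(cnt - 2):
                                pw1 = np.convolve(pw1, q)
                            rest = np.convolve(rest, pw1)
                        a = dq.shape[1]
                        M = np.zeros((a, width))
                        for i in range(a):
                            M[i, i : i + len(rest)] = rest
                        drhs[:, term.row, :] += (cnt * f) * (dq @ M)
            try:
                lu, piv = scipy.linalg.lu_factor(A)
                X = scipy.linalg.lu_solve((lu, piv), rhs)
            except (scipy.linalg.LinAlgError, ValueError) as exc:
                raise EMUSimulationError(
                    f"singular EMU balance at size {level.size} "
                    f"(EMUs: {level.emus[:6]}...)"
                ) from exc
            # a well-posed balance returns simplex rows; gross violations mean
            # the system was singular (e.g. a zero-flux trapped cycle).  The
            # smoothed continuation intentionally unbalances irreversible
            # reactions by O(eps), so the tolerance scales with it.
            if not np.isfinite(X).all() or (
                check and np.abs(X.sum(axis=1) - 1.0).max() > 0.2 + 0.5 * eps
            ):
                raise EMUSimulationError(
                    f"singular or ill-posed EMU balance at size {level.size} "
                    f"(zero-flux trapped cycle among {level.emus[:6]}...)"
                )
            if want_sens:
                ddiag = (level.diag_op @ dphi)  # (n, p)
                dT = (level.trans_op @ dphi).reshape(n, n, p)
                # batch all parameter directions into one triangular solve
                B = drhs - ddiag.T[:, :, None] * X[None, :, :] + np.einsum(
                    "ijp,jw->piw", dT, X)
                dX = scipy.linalg.lu_solve(
                    (lu, piv), B.transpose(1, 0, 2).reshape(n, p * width),
                    check_finite=False,
                ).reshape(n, p, width)
                for i, emu in enumerate(level.emus):
                    sens[emu] = dX[i]
            for i, emu in enumerate(level.emus):
                mids[emu] = X[i]

        if want_sens:
            return mids, sens
        return mids


def _as_emus(net: MetabolicNetwork, targets) -> list[EMU]:
    out = []
    for t in targets:
        if isinstance(t, EMU):
            out.append(t)
        elif isinstance(t, str):
            nc = net.carbon_counts.get(t)
            if nc is None:
                raise KeyError(f"unknown species {t!r}")
            out.append(EMU(t, tuple(range(1, nc + 1))))
        else:
            species, atoms = t
            out.append(EMU(species, tuple(atoms)))
    return out


def emu_decompose(net: MetabolicNetwork, targets) -> EMUSystem:
    """Build the size-ordered EMU reaction graph reaching ``targets``.

    Targets may be :class:`EMU` objects, species ids (full carbon backbone),
    or ``(species, atom_indices)`` pairs.
    """
    return EMUSystem(net, _as_emus(net, targets))


def simulate_mids(
    net: MetabolicNetwork, fluxes: FluxVector, tracer: TracerSpec, targets
) -> dict[EMU, np.ndarray]:
    """Steady-state corrected-space MIDs of the target EMUs under a tracer."""
    system = emu_decompose(net, targets)
    mids = system.simulate(fluxes, tracer)
    return {t: mids[t] for t in system.targets}
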