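"""Brute-force positional-isotopomer oracle for small networks.

Independent cross-check for the EMU simulator: solves the full cumomer
cascade (for every balanced metabolite, the probability that each subset of
its carbons is entirely 13C), recovers positional-isotopomer distributions
by inclusion-exclusion, and marginalizes to MIDs.  Cumomer balances are
linear within each labeling weight because condensation products factorize
into products of lower-weight cumomers of independent reactant pools.

Deliberately shares no solver code with :mod:`adipoflux.emu`; only the
network containers and tracer definition are common.
"""

from __future__ import annotations

import itertools

import numpy as np

from .emu import EMU, TracerSpec, _as_emus
from .network import BOUNDARY_IN, FluxVector, MetabolicNetwork, Occurrence


class NetworkTooLargeError(RuntimeError):
    pass


def _is_boundary_in(species: str) -> bool:
    return Occurrence(species, "").compartment in BOUNDARY_IN


def _substrate_cumomer(tracer: TracerSpec, species: str, positions: tuple[int, ...]) -> float:
    """P(all listed carbons of the boundary pool are 13C)."""
    if tracer is None or species != tracer.substrate:
        return 1.0 if not positions else 0.0
    if not positions:
        return 1.0
    if any(p not in tracer.positions for p in positions):
        return 0.0
    return tracer.fraction * tracer.purity ** len(positions)


def brute_force_isotopomer_sim(
    net: MetabolicNetwork,
    fluxes: FluxVector,
    tracer: TracerSpec,
    targets,
    max_states: int = 2**16,
) -> dict[EMU, np.ndarray]:
    """Exact steady-state MIDs by direct solution of the cumomer cascade.

    Guarded to networks whose balanced metabolites carry at most
    ``max_states`` positional isotopomers in total.
    """
    balanced = net.balanced_species
    n_states = sum(2 ** net.carbon_counts[s] for s in balanced)
    if n_states > max_states:
        raise NetworkTooLargeError(
            f"{n_states} positional isotopomers exceed the oracle guard ({max_states})"
        )

    # direction fluxes with symmetric-consumption orientation expansion
    variants: list[tuple[float, list[Occurrence], list[Occurrence]]] = []
    v = fluxes.net_array(net.reaction_ids)
    for ri, rxn in enumerate(net.reactions):
        x = fluxes.exchange.get(rxn.id, 0.0) if rxn.reversible else 0.0
        dir_fluxes = [(max(v[ri], 0.0) + x, rxn.reactants, rxn.products)]
        if rxn.reversible:
            dir_fluxes.append((max(-v[ri], 0.0) + x, rxn.products, rxn.reactants))
        for f, reac, prod in dir_fluxes:
            if f <= 0.0:
                continue
            opts = [
                [occ, Occurrence(occ.species, occ.atoms[::-1])]
                if occ.species in net.symmetric else [occ]
                for occ in reac
            ]
            for combo in itertools.product(*opts):
                w = f / np.prod([len(o) for o in opts]) if opts else f
                variants.append((w, list(combo), list(prod)))

    consumption = {s: 0.0 for s in balanced}
    production = {s: 0.0 for s in balanced}
    for w, reac, prod in variants:
        for occ in reac:
            if occ.species in consumption:
                consumption[occ.species] += w
        for occ in prod:
            if occ.species in production:
                production[occ.species] += w

    # unknown cumomers: (species, frozenset of 1-based positions), weight >= 1
    unknowns: list[tuple[str, frozenset[int]]] = []
    for s in balanced:
        nc = net.carbon_counts[s]
        for r in range(1, nc + 1):
            for comb in itertools.combinations(range(1, nc + 1), r):
                unknowns.append((s, frozenset(comb)))
    index = {u: i for i, u in enumerate(unknowns)}
    y = np.zeros(len(unknowns))

    def cumomer(species: str, positions: frozenset[int]) -> float:
        if not positions:
            return 1.0
        if _is_boundary_in(species):
            return _substrate_cumomer(tracer, species, tuple(sorted(positions)))
        return y[index[(species, positions)]]

    max_w = max((len(p) for _, p in unknowns), default=0)
    for weight in range(1, max_w + 1):
        level = [u for u in unknowns if len(u[1]) == weight]
        li = {u: i for i, u in enumerate(level)}
        n = len(level)
        if n == 0:
            continue
        A = np.zeros((n, n))
        b = np.zeros(n)
        for i, (species, positions) in enumerate(level):
            denom = consumption[species] if consumption[species] > 0 else production[species]
            A[i, i] += denom
            for w, reac, prod in variants:
                for occ in prod:
                    if occ.species != species:
                        continue
                    # map the cumomer positions back onto reactant occurrences
                    per_source: dict[int, set[int]] = {}
                    ok = True
                    for pos in positions:
                        letter = occ.atoms[pos - 1]
                        hit = None
                        for k, r in enumerate(reac):
                            j = r.atoms.find(letter)
                            if j >= 0:
                                hit = (k, j + 1)
                                break
                        if hit is None:
                            ok = False  # atom created at boundary: unlabeled
                            break
                        per_source.setdefault(hit[0], set()).add(hit[1])
                    if not ok:
                        continue
                    parts = [
                        (reac[k].species, frozenset(ps)) for k, ps in sorted(per_source.items())
                    ]
                    if len(parts) == 1 and not _is_boundary_in(parts[0][0]):
                        # all positions trace to one balanced reactant: an
                        # in-level linear transfer term
                        A[i, li[parts[0]]] -= w
                    else:
                        val = 1.0
                        for sp, ps in parts:
                            val *= cumomer(sp, ps)
                        b[i] += w * val
        sol = np.linalg.solve(A, b)
        for u, i in li.items():
            y[index[u]] = sol[i]

    # cumomers -> positional isotopomer distributions per balanced species
    iso: dict[str, np.ndarray] = {}
    for s in balanced:
        nc = net.carbon_counts[s]
        dist = np.zeros(2 ** nc)
        for bits in range(2 ** nc):
            base = frozenset(p + 1 for p in range(nc) if bits >> p & 1)
            rest = [p + 1 for p in range(nc) if not bits >> p & 1]
            total = 0.0
            for r in range(len(rest) + 1):
                for extra in itertools.combinations(rest, r):
                    total += (-1.0) ** r * cumomer(s, base | frozenset(extra))
            dist[bits] = total
        iso[s] = dist

    def emu_mid(emu: EMU) -> np.ndarray:
        if _is_boundary_in(emu.species):
            mid = np.zeros(emu.size + 1)
            for labeled in range(emu.size + 1):
                for comb in itertools.combinations(emu.atoms, labeled):
                    on = frozenset(comb)
                    val = 0.0
                    for r in range(emu.size - labeled + 1):
                        for extra in itertools.combinations(
                            [a for a in emu.atoms if a not in on], r
                        ):
                            val += (-1.0) ** r * _substrate_cumomer(
                                tracer, emu.species, tuple(sorted(on | frozenset(extra)))
                            )
                    mid[labeled] += val
            return mid
        if emu.species in iso:
            nc = net.carbon_counts[emu.species]
            dist = iso[emu.species]
            mid = np.zeros(emu.size + 1)
            mask = sum(1 << (a - 1) for a in emu.atoms)
            for bits in range(2 ** nc):
                mid[bin(bits & mask).count("1")] += dist[bits]
            return mid
        # sink species: flux-weighted convolution of source-part MIDs
        num = np.zeros(emu.size + 1)
        den = 0.0
        for w, reac, prod in variants:
            for occ in prod:
                if occ.species != emu.species:
                    continue
                per_source: dict[int, list[int]] = {}
                for a in emu.atoms:
                    letter = occ.atoms[a - 1]
                    for k, r in enumerate(reac):
                        j = r.atoms.find(letter)
                        if j >= 0:
                            per_source.setdefault(k, []).append(j + 1)
                            break
                vec = np.array([1.0])
                for k, ps in sorted(per_source.items()):
                    vec = np.convolve(vec, emu_mid(EMU(reac[k].species, tuple(ps))))
                num[: len(vec)] += w * vec
                den += w
        if den <= 0:
            raise RuntimeError(f"{emu.species} has no producing flux")
        return num / den

    return {t: emu_mid(t) for t in _as_emus(net, targets)}
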