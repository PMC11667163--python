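"""Atom-mapped, compartmentalized metabolic networks.

A network is a list of carbon-mapped reactions plus three kinds of
annotations: structurally symmetric metabolites (their consumers see the
average of both carbon orientations), dilution species (boundary pools with
a fixed, unlabeled isotope distribution), and fixed flux ratios (e.g. the
oxidative PPP branch pinned to a fraction of glucose uptake).

The plain-text reaction grammar is one reaction per line::

    id: MET.cmp (atoms) + MET.cmp (atoms) -> MET.cmp (atoms) ...

with ``<->`` for reversible reactions, ``#`` comments, and the directives
``#symmetric SPECIES``, ``#dilution SPECIES`` and ``#ratio id_a id_b r``
(constraining ``v_a = r * v_b``).  One letter per carbon; metabolites in the
boundary compartments (``ext``, ``dil``, ``out``, ``snk``) are not balanced.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize

BOUNDARY_IN = frozenset({"ext", "dil"})
BOUNDARY_OUT = frozenset({"out", "snk"})
BOUNDARY = BOUNDARY_IN | BOUNDARY_OUT

_DEFAULT_COMPARTMENT = "c"


class NetworkError(ValueError):
    """Structural error in a metabolic network definition."""


class NetworkParseError(NetworkError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class Occurrence:
    """One instance of a metabolite on a reaction side, with its atom map."""

    species: str  # e.g. "PYR.c"
    atoms: str  # one letter per carbon, e.g. "abc"

    @property
    def compartment(self) -> str:
        return self.species.rsplit(".", 1)[1] if "." in self.species else _DEFAULT_COMPARTMENT

    @property
    def n_carbons(self) -> int:
        return len(self.atoms)


@dataclass
class AtomMappedReaction:
    id: str
    reactants: list[Occurrence]
    products: list[Occurrence]
    reversible: bool = False

    @property
    def kind(self) -> str:
        r_cmp = {o.compartment for o in self.reactants}
        p_cmp = {o.compartment for o in self.products}
        if self.reactants and r_cmp <= BOUNDARY_IN:
            return "dilution" if r_cmp == {"dil"} else "uptake"
        if self.products and p_cmp <= BOUNDARY_OUT:
            return "biomass-sink" if p_cmp == {"snk"} else "secretion"
        return "internal"

    def atom_balance_issue(self) -> str | None:
        """Return a description of an atom-mapping defect, or None."""
        for side, occs in (("reactant", self.reactants), ("product", self.products)):
            letters = [a for o in occs for a in o.atoms]
            if len(letters) != len(set(letters)):
                dup = sorted({a for a in letters if letters.count(a) > 1})
                return f"{self.id}: duplicate {side} atom label(s) {dup}"
        r_atoms = {a: o for o in self.reactants for a in o.atoms}
        p_atoms = {a: o for o in self.products for a in o.atoms}
        # Atoms may be created/destroyed only on boundary species.
        for a, occ in p_atoms.items():
            if a not in r_atoms and occ.compartment not in BOUNDARY:
                return f"{self.id}: product atom '{a}' of {occ.species} unmatched on reactant side"
        for a, occ in r_atoms.items():
            if a not in p_atoms and occ.compartment not in BOUNDARY:
                return f"{self.id}: reactant atom '{a}' of {occ.species} unmatched on product side"
        return None


@dataclass
class ValidationReport:
    atom_balance_failures: list[str] = field(default_factory=list)
    dead_ends: list[str] = field(default_factory=list)
    unreachable: list[str] = field(default_factory=list)
    feasible: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.atom_balance_failures or self.dead_ends or self.unreachable) and self.feasible

    def __str__(self) -> str:
        lines = []
        for name in ("atom_balance_failures", "dead_ends", "unreachable", "warnings"):
            for item in getattr(self, name):
                lines.append(f"{name.rstrip('s').replace('_', ' ')}: {item}")
        lines.append(f"strictly positive feasible flux: {'yes' if self.feasible else 'NO'}")
        lines.append(f"overall: {'OK' if self.ok else 'INVALID'}")
        return "\n".join(lines)


class MetabolicNetwork:
    """Atom-mapped reaction set with symmetry, dilution and ratio annotations."""

    def __init__(
        self,
        reactions: list[AtomMappedReaction],
        symmetric: set[str] | frozenset[str] = frozenset(),
        dilution: set[str] | frozenset[str] = frozenset(),
        fixed_ratios: list[tuple[str, str, float]] = (),
        strict: bool = True,
    ):
        self.reactions = list(reactions)
        self.symmetric = frozenset(symmetric)
        self.dilution = frozenset(dilution)
        self.fixed_ratios = list(fixed_ratios)

        ids = [r.id for r in self.reactions]
        for rid in ids:
            if ids.count(rid) > 1:
                raise NetworkError(f"duplicate reaction id {rid!r}")
        self._by_id = {r.id: r for r in self.reactions}

        self.carbon_counts: dict[str, int] = {}
        for rxn in self.reactions:
            for occ in rxn.reactants + rxn.products:
                prev = self.carbon_counts.setdefault(occ.species, occ.n_carbons)
                if prev != occ.n_carbons:
                    raise NetworkError(
                        f"{occ.species} appears with {prev} and {occ.n_carbons} carbons"
                    )
        for a, b, _ in self.fixed_ratios:
            for rid in (a, b):
                if rid not in self._by_id:
                    raise NetworkError(f"ratio constraint references unknown reaction {rid!r}")
        for s in self.symmetric | self.dilution:
            if s not in self.carbon_counts:
                raise NetworkError(f"annotation references unknown species {s!r}")
        if strict:
            for rxn in self.reactions:
                issue = rxn.atom_balance_issue()
                if issue is not None:
                    raise NetworkError(f"unbalanced atom map: {issue}")

    # -- basic queries ---------------------------------------------------

    def reaction(self, rid: str) -> AtomMappedReaction:
        return self._by_id[rid]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def reversible_ids(self) -> list[str]:
        return [r.id for r in self.reactions if r.reversible]

    @property
    def species(self) -> list[str]:
        return sorted(self.carbon_counts)

    @property
    def balanced_species(self) -> list[str]:
        def boundary(s: str) -> bool:
            cmp = s.rsplit(".", 1)[1] if "." in s else _DEFAULT_COMPARTMENT
            return cmp in BOUNDARY

        return sorted(s for s in self.carbon_counts if not boundary(s))

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Net stoichiometric matrix over balanced species; returns (S, rows)."""
        rows = self.balanced_species
        idx = {s: i for i, s in enumerate(rows)}
        S = np.zeros((len(rows), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for occ in rxn.reactants:
                if occ.species in idx:
                    S[idx[occ.species], j] -= 1.0
            for occ in rxn.products:
                if occ.species in idx:
                    S[idx[occ.species], j] += 1.0
        return S, rows

    def constraint_matrix(self) -> np.ndarray:
        """Stoichiometry plus fixed-ratio rows (right null space = free fluxes)."""
        S, _ = self.stoichiometric_matrix()
        extra = np.zeros((len(self.fixed_ratios), len(self.reactions)))
        order = {rid: j for j, rid in enumerate(self.reaction_ids)}
        for i, (a, b, r) in enumerate(self.fixed_ratios):
            extra[i, order[a]] = 1.0
            extra[i, order[b]] = -r
        return np.vstack([S, extra])

    # -- validation ------------------------------------------------------

    def validate(self) -> ValidationReport:
        rep = ValidationReport()
        for rxn in self.reactions:
            issue = rxn.atom_balance_issue()
            if issue is not None:
                rep.atom_balance_failures.append(issue)

        produced: dict[str, int] = {}
        consumed: dict[str, int] = {}
        for rxn in self.reactions:
            for occ in rxn.reactants:
                consumed[occ.species] = consumed.get(occ.species, 0) + 1
                if rxn.reversible:
                    produced[occ.species] = produced.get(occ.species, 0) + 1
            for occ in rxn.products:
                produced[occ.species] = produced.get(occ.species, 0) + 1
                if rxn.reversible:
                    consumed[occ.species] = consumed.get(occ.species, 0) + 1
        for s in self.balanced_species:
            if not produced.get(s):
                rep.dead_ends.append(f"{s} is never produced")
            elif not consumed.get(s):
                rep.dead_ends.append(f"{s} is produced but never consumed")

        # reachability from boundary inflows
        reached = {s for s in self.carbon_counts if Occurrence(s, "").compartment in BOUNDARY_IN}
        changed = True
        while changed:
            changed = False
            for rxn in self.reactions:
                sides = [(rxn.reactants, rxn.products)]
                if rxn.reversible:
                    sides.append((rxn.products, rxn.reactants))
                for src, dst in sides:
                    if src and any(o.species in reached for o in src):
                        for o in dst:
                            if o.species not in reached:
                                reached.add(o.species)
                                changed = True
        rep.unreachable = [s for s in self.balanced_species if s not in reached]

        # a CO2-like pool that is consumed but not declared as an unlabeled
        # dilution inflow would reincorporate label released by decarboxylation
        for rxn in self.reactions:
            for occ in rxn.reactants:
                if occ.species.split(".")[0].upper().startswith("CO2") and (
                    occ.species not in self.dilution and occ.compartment not in BOUNDARY_IN
                ):
                    rep.warnings.append(
                        f"{rxn.id} consumes {occ.species}, which is not an unlabeled dilution "
                        "pool: carboxylation would reincorporate labeled CO2"
                    )

        rep.feasible = self._positive_feasible()
        return rep

    def _positive_feasible(self, vmax: float = 1e6) -> bool:
        A = self.constraint_matrix()
        bounds = [
            (-vmax, vmax) if rxn.reversible else (1.0, vmax) for rxn in self.reactions
        ]
        res = scipy.optimize.linprog(
            c=np.zeros(A.shape[1]), A_eq=A, b_eq=np.zeros(A.shape[0]), bounds=bounds,
            method="highs",
        )
        return bool(res.success)

    # -- serialization ---------------------------------------------------

    def serialize(self) -> str:
        def side(occs: list[Occurrence]) -> str:
            return " + ".join(f"{o.species} ({o.atoms})" for o in occs)

        lines = []
        for rxn in self.reactions:
            arrow = "<->" if rxn.reversible else "->"
            lines.append(f"{rxn.id}: {side(rxn.reactants)} {arrow} {side(rxn.products)}")
        for s in sorted(self.symmetric):
            lines.append(f"#symmetric {s}")
        for s in sorted(self.dilution):
            lines.append(f"#dilution {s}")
        for a, b, r in self.fixed_ratios:
            lines.append(f"#ratio {a} {b} {r:g}")
        return "\n".join(lines) + "\n"

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetabolicNetwork):
            return NotImplemented
        return (
            self.reactions == other.reactions
            and self.symmetric == other.symmetric
            and self.dilution == other.dilution
            and self.fixed_ratios == other.fixed_ratios
        )


# -- parsing -------------------------------------------------------------

_OCC_RE = re.compile(r"^\s*(?P<name>[A-Za-z0-9_.:]+)\s*\(\s*(?P<atoms>\S+)\s*\)\s*$")


def _parse_side(text: str, line_no: int) -> list[Occurrence]:
    text = text.strip()
    if not text:
        return []
    occs = []
    for chunk in text.split("+"):
        m = _OCC_RE.match(chunk)
        if not m:
            raise NetworkParseError(f"cannot parse species term {chunk.strip()!r}", line_no)
        name = m.group("name")
        if "." not in name:
            name = f"{name}.{_DEFAULT_COMPARTMENT}"
        occs.append(Occurrence(name, m.group("atoms")))
    return occs


def parse_network(text: str, strict: bool = True) -> MetabolicNetwork:
    """Parse the reaction grammar into a :class:`MetabolicNetwork`.

    Malformed lines raise :class:`NetworkParseError` carrying the line number;
    with ``strict=True`` (default) structurally unbalanced atom maps on
    non-boundary species are also rejected.
    """
    reactions: list[AtomMappedReaction] = []
    symmetric: set[str] = set()
    dilution: set[str] = set()
    ratios: list[tuple[str, str, float]] = []

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if not parts:
                continue
            directive = parts[0].lower()
            if directive == "symmetric" and len(parts) == 2:
                symmetric.add(parts[1] if "." in parts[1] else f"{parts[1]}.{_DEFAULT_COMPARTMENT}")
            elif directive == "dilution" and len(parts) == 2:
                dilution.add(parts[1] if "." in parts[1] else f"{parts[1]}.{_DEFAULT_COMPARTMENT}")
            elif directive == "ratio" and len(parts) == 4:
                try:
                    ratios.append((parts[1], parts[2], float(parts[3])))
                except ValueError:
                    raise NetworkParseError(f"bad ratio value {parts[3]!r}", line_no) from None
            # other # lines are comments
            continue
        line = line.split("#", 1)[0].strip()  # inline comments
        if ":" not in line:
            raise NetworkParseError("expected 'id: reactants -> products'", line_no)
        rid, rest = line.split(":", 1)
        rid = rid.strip()
        if not rid:
            raise NetworkParseError("empty reaction id", line_no)
        reversible = "<->" in rest
        arrow = "<->" if reversible else "->"
        if arrow not in rest:
            raise NetworkParseError("missing reaction arrow '->'", line_no)
        lhs, rhs = rest.split(arrow, 1)
        rxn = AtomMappedReaction(
            id=rid,
            reactants=_parse_side(lhs, line_no),
            products=_parse_side(rhs, line_no),
            reversible=reversible,
        )
        if strict:
            issue = rxn.atom_balance_issue()
            if issue is not None:
                raise NetworkParseError(f"unbalanced atom map: {issue}", line_no)
        reactions.append(rxn)

    try:
        return MetabolicNetwork(reactions, symmetric, dilution, ratios, strict=strict)
    except NetworkError as exc:
        raise NetworkParseError(str(exc)) from exc


def validate_network(net: MetabolicNetwork) -> ValidationReport:
    """Structural validation report (atom balance, dead ends, reachability,
    existence of a strictly positive feasible net flux)."""
    return net.validate()


def load_network(name: str) -> MetabolicNetwork:
    """Load a network shipped with the package (``adipocyte_core``, ``toy_*``)."""
    ref = importlib.resources.files("adipoflux.networks").joinpath(f"{name}.txt")
    return parse_network(ref.read_text())


def reference_adipocyte_network() -> MetabolicNetwork:
    """The shipped core adipocyte network (glycolysis, oxPPP branch at 0.3% of
    glucose uptake, compartmentalized TCA, pyruvate cycling, glutamine and
    glutamate medium exchange, BCKDH-gated BCAA oxidation, propionyl-CoA
    anaplerosis, and C15:0/C16:0/C17:0 fatty-acid synthesis sinks)."""
    return load_network("adipocyte_core")


def shipped_toy_networks() -> dict[str, MetabolicNetwork]:
    return {name: load_network(name) for name in
            ("toy_linear", "toy_diamond", "toy_cycle", "toy_reversible")}


# -- flux vectors and the free-flux parameterization ---------------------


@dataclass
class FluxVector:
    """Net fluxes per reaction (nmol/well/h; negative only for reversible
    reactions) and non-negative exchange fluxes per reversible reaction."""

    net: dict[str, float]
    exchange: dict[str, float] = field(default_factory=dict)

    def net_array(self, order: list[str]) -> np.ndarray:
        return np.array([self.net[rid] for rid in order], float)

    def scaled(self, k: float) -> "FluxVector":
        return FluxVector(
            {r: k * v for r, v in self.net.items()},
            {r: k * v for r, v in self.exchange.items()},
        )

    def validate(self, net: MetabolicNetwork, tol: float = 1e-6) -> None:
        A = net.constraint_matrix()
        v = self.net_array(net.reaction_ids)
        resid = np.abs(A @ v).max() if A.size else 0.0
        scale = max(1.0, np.abs(v).max())
        if resid > tol * scale:
            raise NetworkError(f"flux vector violates balance: |S v| = {resid:.3g}")
        for rxn in net.reactions:
            if not rxn.reversible and self.net[rxn.id] < -tol:
                raise NetworkError(f"irreversible reaction {rxn.id} has negative net flux")
        for rid, x in self.exchange.items():
            if x < 0:
                raise NetworkError(f"exchange flux of {rid} is negative")


class FluxBasis:
    """Null-space parameterization of feasible net fluxes.

    Any assignment of the free parameters reconstructs a full net-flux vector
    satisfying the stoichiometric balance and fixed-ratio constraints exactly;
    non-negativity of irreversible reactions bounds the feasible polytope.
    """

    def __init__(self, net: MetabolicNetwork):
        self.network = net
        self.reaction_ids = net.reaction_ids
        A = net.constraint_matrix()
        self.K = scipy.linalg.null_space(A)
        if self.K.shape[1] == 0:
            raise NetworkError("network admits no nonzero balanced flux (trivial null space)")
        self._irr = np.array([not r.reversible for r in net.reactions])
        self.exchange_ids = net.reversible_ids

    @property
    def n_free(self) -> int:
        return self.K.shape[1]

    def reconstruct(self, theta: np.ndarray) -> np.ndarray:
        """Net-flux vector (reaction order) for free parameters ``theta``."""
        return self.K @ np.asarray(theta, float)

    def flux_vector(self, theta: np.ndarray, exchange: dict[str, float] | None = None) -> FluxVector:
        v = self.reconstruct(theta)
        return FluxVector(dict(zip(self.reaction_ids, v)), dict(exchange or {}))

    def project(self, target: FluxVector | dict[str, float]) -> np.ndarray:
        """Least-squares free parameters reproducing ``target`` as closely as
        the balance constraints allow."""
        t = target.net if isinstance(target, FluxVector) else target
        v = np.array([t.get(rid, 0.0) for rid in self.reaction_ids])
        theta, *_ = np.linalg.lstsq(self.K, v, rcond=None)
        return theta

    def _polytope(self, vmax: float) -> tuple[np.ndarray, np.ndarray]:
        A = np.vstack([-self.K[self._irr], self.K, -self.K])
        b = np.concatenate([
            np.zeros(int(self._irr.sum())),
            np.full(len(self.reaction_ids), vmax),
            np.full(len(self.reaction_ids), vmax),
        ])
        return A, b

    def interior_point(self, vmax: float = 500.0) -> np.ndarray:
        """A strictly feasible point (max-slack Chebyshev-style LP)."""
        A, b = self._polytope(vmax)
        n = self.n_free
        A_ub = np.hstack([A, np.ones((A.shape[0], 1))])
        res = scipy.optimize.linprog(
            c=np.concatenate([np.zeros(n), [-1.0]]),
            A_ub=A_ub, b_ub=b,
            bounds=[(None, None)] * n + [(0, 0.05 * vmax)],
            method="highs",
        )
        if not res.success or res.x[-1] <= 0:
            raise NetworkError("no strictly feasible flux vector within bounds")
        return res.x[:n]

    def sample_feasible(
        self, rng: np.random.Generator, n: int = 1, vmax: float = 500.0, thin: int = 15
    ) -> np.ndarray:
        """Hit-and-run samples from the bounded feasible polytope (seeded)."""
        A, b = self._polytope(vmax)
        x = self.interior_point(vmax)
        out = np.empty((n, self.n_free))
        n_steps = 50 + thin * n  # burn-in plus thinned draws
        k = 0
        for step in range(n_steps):
            d = rng.standard_normal(self.n_free)
            d /= np.linalg.norm(d)
            ad = A @ d
            slack = b - A @ x
            with np.errstate(divide="ignore"):
                lam = np.where(np.abs(ad) > 1e-12, slack / ad, np.inf)
            hi = lam[ad > 1e-12].min(initial=np.inf)
            lo = -(-lam[ad < -1e-12]).min(initial=np.inf)
            if not np.isfinite(hi) or not np.isfinite(lo):
                continue
            x = x + d * rng.uniform(0.999 * lo, 0.999 * hi)
            if step >= 50 and (step - 50) % thin == 0 and k < n:
                out[k] = x
                k += 1
        while k < n:  # pad in the unlikely event of skipped steps
            out[k] = x
            k += 1
        return out


def free_flux_basis(net: MetabolicNetwork) -> FluxBasis:
    """Minimal free-parameter basis for balanced net fluxes (see FluxBasis)."""
    return FluxBasis(net)
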