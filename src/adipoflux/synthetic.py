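"""Ground-truth-known synthetic datasets emulating the tracing study.

Every pipeline stage is testable without external data: a feasible flux
vector on the reference adipocyte network (a "control" scenario and a
BCKDH-knockout scenario with BCAA oxidation ablated and compensatory
pyruvate cycling), noisy three-tracer MID datasets of the measured
fragments, ISA fatty-acid MIDs, and medium concentration time courses
consistent with chosen uptake/secretion rates.

Scenario magnitudes are anchored to the two printed glutamine fluxes
(uptake 56, secretion 43 nmol/well/h in control; 45 and 39 after knockout)
so fixtures live on a realistic nmol/well/h scale; all other ground-truth
values are documented choices, not measurements.  MID noise is independent
Gaussian (sd 0.003 mol fraction) applied in corrected-MID space, clipped at
zero and renormalized; rates carry 5% relative noise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .emu import TracerSpec, emu_decompose
from .measurements import MID, RateMeasurement, exchange_rate
from .mfa import RateTarget, TracerExperiment
from .network import FluxVector, MetabolicNetwork, reference_adipocyte_network

DEFAULT_MID_NOISE_SD = 0.003  # mol fraction, typical GC-MS precision
DEFAULT_RATE_REL_SD = 0.05
DEFAULT_HOURS = 48.0
DEFAULT_VOLUME_UL = 1000.0
DEFAULT_N_REPLICATES = 3

#: the three tracers of the study design
TRACERS = {
    "glucose": TracerSpec("GLC.ext", (1, 2, 3, 4, 5, 6), purity=0.99, name="[U-13C6]glucose"),
    "leucine": TracerSpec("LEU.ext", (1, 2, 3, 4, 5, 6), purity=0.99, name="[U-13C6]leucine"),
    "valine": TracerSpec("VAL.ext", (1, 2, 3, 4, 5), purity=0.99, name="[U-13C5]valine"),
}

#: measured fragments per tracer: the shared panel of pyruvate, TCA
#: intermediates, glutamine/glutamate and the three fatty acids, plus the
#: tracer-specific amino-acid fragments; fragments with no carbon path from
#: a tracer are not entered for that tracer
_COMMON_PANEL = ["CIT.m", "AKG.m", "SUC.m", "FUM.m", "MAL.m", "GLN.c", "GLU.c",
                 "C15.snk", "C16.snk", "C17.snk"]
MEASUREMENT_PANELS = {
    "glucose": ["PYR.c"] + _COMMON_PANEL,
    "leucine": _COMMON_PANEL + ["LEU.c", "KIC.c"],
    "valine": _COMMON_PANEL + ["VAL.c"],
}

#: measured net exchange rates as linear combinations of reaction nets
RATE_DEFINITIONS = {
    "glucose": {"v_glcup": 1.0},
    "lactate": {"v_lac": 1.0},
    "alanine": {"v_ala": 1.0},
    "valine": {"v_valup": 1.0},
    "leucine": {"v_leuup": 1.0},
    "glutamine_net": {"v_glnup": 1.0, "v_glnsec": -1.0},
    "glutamate_net": {"v_gluup": 1.0, "v_glusec": -1.0},
}

# target net fluxes (nmol/well/h) reconciled onto the balance manifold by
# sample_feasible_fluxes; unlisted reactions are left to the reconciliation
_CONTROL_TARGETS = {
    "v_glcup": 150.0, "v_lac": 210.0, "v_ala": 15.0, "v_pyrt": 75.0,
    "v_pdh": 83.5, "v_pc": 10.0, "v_me": 18.5, "v_pcc": 0.5,
    "v_glnup": 56.0, "v_glnsec": 43.0, "v_gls": 20.0, "v_gs": 7.0,
    "v_gluup": 5.0, "v_glusec": 10.0,
    "v_leuup": 5.0, "v_bckdh_leu": 5.0, "v_valup": 4.0, "v_bckdh_val": 4.0,
    "v_ileup": 2.0, "v_ilet": 2.0,
    "v_fas16": 4.0, "v_fas15": 0.15, "v_fas17": 0.2,
}
_KO_TARGETS = {
    "v_glcup": 120.0, "v_lac": 140.0, "v_ala": 12.0, "v_pyrt": 88.0,
    "v_pdh": 91.5, "v_pc": 22.0, "v_me": 25.5, "v_pcc": 0.5,
    "v_glnup": 45.0, "v_glnsec": 39.0, "v_gls": 11.0, "v_gs": 5.0,
    "v_gluup": 5.0, "v_glusec": 8.0,
    "v_leuup": 0.04, "v_bckdh_leu": 0.04, "v_valup": 0.03, "v_bckdh_val": 0.03,
    "v_ileup": 2.0, "v_ilet": 2.0,
    "v_fas16": 4.5, "v_fas15": 0.05, "v_fas17": 0.07,
}
_CONTROL_EXCHANGE = {
    "v_fh": 30.0, "v_mdh": 40.0, "v_mdhc": 10.0, "v_malt": 15.0,
    "v_glnt": 5.0, "v_gdh": 20.0, "v_glut": 5.0,
}
# knockout: dramatically higher glutamate/AKG exchange
_KO_EXCHANGE = {**_CONTROL_EXCHANGE, "v_gdh": 200.0}

#: ISA ground truth per fatty acid under the glucose tracer: (D, g)
DEFAULT_ISA_TRUTH = {
    "C16:0": (0.35, 0.45),
    "C15:0": (0.30, 0.40),
    "C17:0": (0.25, 0.40),
}

#: fresh-medium concentrations (nmol/ul), DMEM-like
DEFAULT_FRESH_CONC = {
    "glucose": 25.0, "lactate": 0.0, "alanine": 0.1, "glutamine": 4.0,
    "glutamate": 0.2, "valine": 0.8, "leucine": 0.8,
}


@dataclass
class SyntheticScenario:
    """Complete description of one simulated tracing study."""

    seed: int
    scenario: str
    truth: FluxVector
    tracers: dict[str, TracerSpec] = field(default_factory=lambda: dict(TRACERS))
    noise_sd: float = DEFAULT_MID_NOISE_SD
    rate_rel_sd: float = DEFAULT_RATE_REL_SD
    isa_truth: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ISA_TRUTH))
    volume_ul: float = DEFAULT_VOLUME_UL
    hours: float = DEFAULT_HOURS
    n_replicates: int = DEFAULT_N_REPLICATES


def sample_feasible_fluxes(
    net: MetabolicNetwork | None = None,
    seed: int | None = None,
    scenario: str = "control",
) -> FluxVector:
    """Ground-truth flux vector for a scenario, reconciled to exact balance.

    Scenario targets are projected onto the constraint manifold by an L1
    reconciliation LP (minimize total deviation from the targets subject to
    stoichiometric balance, fixed ratios and irreversibility); the result is
    deterministic.  ``scenario='bckdha_ko'`` ablates BCKDH flux (< 1% of
    control) with compensatory pyruvate cycling.
    """
    if net is None:
        net = reference_adipocyte_network()
    if scenario == "control":
        targets, exchange = _CONTROL_TARGETS, _CONTROL_EXCHANGE
    elif scenario == "bckdha_ko":
        targets, exchange = _KO_TARGETS, _KO_EXCHANGE
    else:
        raise ValueError(f"unknown scenario {scenario!r}")

    A_eq = net.constraint_matrix()
    rids = net.reaction_ids
    n = len(rids)
    tgt_ids = [rid for rid in rids if rid in targets]
    m = len(tgt_ids)
    # variables: v (n) then slack s (m) with s >= |v_i - t_i|
    c = np.concatenate([np.zeros(n), np.ones(m)])
    A_ub, b_ub = [], []
    for k, rid in enumerate(tgt_ids):
        i = rids.index(rid)
        t = targets[rid]
        row = np.zeros(n + m); row[i] = 1.0; row[n + k] = -1.0
        A_ub.append(row); b_ub.append(t)
        row = np.zeros(n + m); row[i] = -1.0; row[n + k] = -1.0
        A_ub.append(row); b_ub.append(-t)
    A_eq_full = np.hstack([A_eq, np.zeros((A_eq.shape[0], m))])
    floor = {rid: min(0.2 * targets.get(rid, 1.0), 0.01) for rid in rids}
    bounds = [
        (None, None) if rxn.reversible else (max(floor[rxn.id], 1e-3), None)
        for rxn in net.reactions
    ] + [(0, None)] * m
    res = scipy.optimize.linprog(
        c, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
        A_eq=A_eq_full, b_eq=np.zeros(A_eq.shape[0]), bounds=bounds, method="highs",
    )
    if not res.success:
        raise RuntimeError(f"scenario {scenario!r} reconciliation infeasible: {res.message}")
    fv = FluxVector(dict(zip(rids, res.x[:n])), dict(exchange))
    fv.validate(net)
    return fv


def _noisy_mid(mid: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0.0:
        return mid.copy()
    noisy = np.clip(mid + rng.normal(0.0, sd, size=mid.shape), 0.0, None)
    return noisy / noisy.sum()


def _channel_rms_sd(mid: np.ndarray, noise_sd: float, n_draws: int = 3000) -> np.ndarray:
    """Per-channel RMS deviation of the clip-and-renormalize noise process.

    Clipping at zero and renormalization make the per-channel error smaller
    than the raw Gaussian sd (strongly so for near-empty channels), so the
    generator reports the true uncertainty of each measured channel — the
    role replicate-derived sds play for real data.  The inner Monte Carlo is
    seeded from the MID itself, so the reported sds are deterministic and
    shared across datasets.
    """
    seed = np.abs(np.round(mid * 1e7).astype(np.int64)) % (2**31 - 1)
    local = np.random.default_rng([int(noise_sd * 1e9) % (2**31 - 1), *seed.tolist()])
    draws = np.clip(mid[None, :] + local.normal(0.0, noise_sd, (n_draws, len(mid))), 0.0, None)
    draws /= draws.sum(axis=1, keepdims=True)
    rms = np.sqrt(np.mean((draws - mid[None, :]) ** 2, axis=0))
    return np.maximum(rms, 0.1 * noise_sd)


def generate_tracer_dataset(
    net: MetabolicNetwork,
    fluxes: FluxVector,
    tracers: dict[str, TracerSpec] | None = None,
    noise_sd: float = DEFAULT_MID_NOISE_SD,
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int | None = None,
    rate_rel_sd: float = DEFAULT_RATE_REL_SD,
    panels: dict[str, list[str]] | None = None,
) -> tuple[list[TracerExperiment], dict]:
    """Noisy replicate MID + rate measurements for each tracer.

    Returns the experiments and a ground-truth record (true fluxes, true
    MIDs per tracer, true rates).
    """
    tracers = dict(tracers or TRACERS)
    panels = dict(panels or MEASUREMENT_PANELS)
    rng = np.random.default_rng(seed)
    v = fluxes.net_array(net.reaction_ids)
    idx = {rid: i for i, rid in enumerate(net.reaction_ids)}

    true_rates = {
        name: sum(c * v[idx[rid]] for rid, c in coeffs.items())
        for name, coeffs in RATE_DEFINITIONS.items()
        if all(rid in idx for rid in coeffs)
    }
    experiments = []
    truth = {"fluxes": fluxes, "rates": true_rates, "mids": {}}
    for tname, tracer in tracers.items():
        panel = panels[tname]
        system = emu_decompose(net, panel)
        sim = system.simulate(fluxes, tracer)
        truth["mids"][tname] = {t.species: sim[t].copy() for t in system.targets}
        channel_sd = {
            t: _channel_rms_sd(sim[t], noise_sd) if noise_sd > 0
            else np.full(len(sim[t]), DEFAULT_MID_NOISE_SD)
            for t in system.targets
        }
        mids = []
        for _ in range(n_replicates):
            for target in system.targets:
                noisy = _noisy_mid(sim[target], noise_sd, rng)
                mids.append(MID(target.species, "full", len(noisy) - 1, noisy,
                                channel_sd[target].copy()))
        rates = []
        for name, coeffs in RATE_DEFINITIONS.items():
            if not all(rid in idx for rid in coeffs):
                continue
            true = true_rates[name]
            sd = max(rate_rel_sd * abs(true), 0.25)
            rates.append(RateTarget(name, dict(coeffs), true + rng.normal(0.0, sd)
                                    if rate_rel_sd > 0 else true, sd))
        experiments.append(TracerExperiment(tracer, mids, rates))
    return experiments, truth


def generate_isa_dataset(
    truth: dict[str, tuple[float, float]] | None = None,
    noise_sd: float = DEFAULT_MID_NOISE_SD,
    seed: int | None = None,
    n_replicates: int = 1,
) -> tuple[list[MID], dict[str, tuple[float, float]]]:
    """Measured fatty-acid MIDs from the ISA forward model plus noise."""
    from .isa import model_for, synthesized_mid

    truth = dict(truth or DEFAULT_ISA_TRUTH)
    rng = np.random.default_rng(seed)
    mids = []
    for fa, (d, g) in truth.items():
        if not (0.0 <= d <= 1.0 and 0.0 <= g <= 1.0):
            raise ValueError(f"ISA truth for {fa} outside [0, 1]")
        model = model_for(fa)
        clean = d * synthesized_mid(model, g)
        clean[0] += 1.0 - d
        sd = (_channel_rms_sd(clean, noise_sd) if noise_sd > 0
              else np.full(len(clean), 1e-9))
        for _ in range(n_replicates):
            noisy = _noisy_mid(clean, noise_sd, rng)
            mids.append(MID(fa, "FAME", model.n_carbons, noisy, sd.copy()))
    return mids, truth


def generate_medium_timecourse(
    rates: dict[str, float],
    volume_ul: float = DEFAULT_VOLUME_UL,
    hours: float = DEFAULT_HOURS,
    seed: int | None = None,
    fresh_conc: dict[str, float] | None = None,
    rel_noise: float = DEFAULT_RATE_REL_SD,
) -> pd.DataFrame:
    """Fresh/spent medium concentration table consistent with net rates.

    ``rates`` are net uptake rates in nmol/well/h (negative = net secretion);
    spent = fresh - rate * hours / volume, plus noise proportional to the
    concentration change.  Raises if a drawdown would exceed the fresh
    concentration.
    """
    fresh_conc = dict(fresh_conc or DEFAULT_FRESH_CONC)
    rng = np.random.default_rng(seed)
    rows = []
    for species, rate in rates.items():
        fresh = fresh_conc.get(species, 0.0)
        delta = rate * hours / volume_ul  # nmol/ul removed from medium
        spent = fresh - delta
        if spent < 0:
            raise ValueError(
                f"{species}: uptake {rate} nmol/well/h exhausts the medium "
                f"({fresh} nmol/ul) within {hours} h"
            )
        noise_sd = rel_noise * max(abs(delta), 1e-3)
        spent_noisy = max(spent + rng.normal(0.0, noise_sd), 0.0)
        rows.append({
            "species": species, "fresh_conc": fresh, "spent_conc": spent_noisy,
            "volume_ul": volume_ul, "hours": hours,
        })
    return pd.DataFrame(rows)


def rates_from_timecourse(df: pd.DataFrame) -> dict[str, RateMeasurement]:
    """Apply :func:`adipoflux.measurements.exchange_rate` to a time course."""
    out = {}
    for _, row in df.iterrows():
        out[row["species"]] = exchange_rate(
            row["fresh_conc"], row["spent_conc"], row["volume_ul"], row["hours"],
            direction="uptake", species=row["species"],
        )
    return out


def make_scenario(seed: int, scenario: str = "control", **kwargs) -> SyntheticScenario:
    """Bundle a ground-truth flux vector with the default study design."""
    net = reference_adipocyte_network()
    truth = sample_feasible_fluxes(net, seed=seed, scenario=scenario)
    return SyntheticScenario(seed=seed, scenario=scenario, truth=truth, **kwargs)
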