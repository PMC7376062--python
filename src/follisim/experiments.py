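"""End-to-end scripted experiments.

Two pipelines: the immobilized-vs-soluble model comparison (equal-total-mass
model 1 and model 2 fields on one synthesized follicle, replicate agent runs,
Vargha–Delaney A on emergent scanning rates) and the emulate-then-optimize
campaign (Latin-hypercube design → replicate simulations → per-output
surrogates → NSGA-II Pareto front). Desk-scale defaults use a reduced
follicle and replicate count; the full-fidelity profile matches the original
study sizes (3000 parameter sets × 100 replicates) and is compute-heavy.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .agents import SimulationConfig, run_simulation
from .emulator import LHCDesign, latin_hypercube, train_emulator
from .field import make_grid_for_network, model_parameterization, \
    rasterize_sources, steady_state_direct
from .moea import ObjectiveSpec, ParetoResult, conflict_analysis, nsga2, \
    vargha_delaney_A, a_test_magnitude
from .network import ReticularNetwork
from .stats import MigrationSummary, summarize
from .synthesis import SynthesisParams, synthesize_follicle_network

log = logging.getLogger("follisim")

#: 13-parameter box used for emulation and optimization (desk-scale profile).
DEFAULT_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "D": (0.02, 2.0),  # µm²/s, spans the measured immobile→soluble medians
    "lam": (1e-4, 2e-3),  # 1/s
    "secretion_fdc": (0.5, 2.0),  # ambient concentration crosses receptor K
    "secretion_rc": (0.1, 1.0),   # over the box only at fast decay rates
    "k_on_ecm": (0.0, 5e-3),
    "k_on": (0.3, 3.0),
    "k_off": (0.03, 0.3),
    "k_i": (0.02, 0.2),
    "k_re": (0.002, 0.02),
    "R_total": (5e3, 2e4),
    "v_mean": (4.0, 10.0),  # µm/min
    "persistence": (0.5, 4.0),
    "chi": (0.0, 60.0),
}


@dataclass
class ExperimentConfig:
    """Configuration shared by the scripted experiments."""

    name: str = "experiment"
    seed: int = 0
    replicates: int = 50
    out_dir: str | None = None
    synthesis: SynthesisParams = field(default_factory=SynthesisParams)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    grid_spacing: float = 8.0  # µm
    # mean steady concentration == default receptor half-saturation (k_off+k_i)/k_on;
    # chemotaxis is most sensitive when ambient ligand sits near K
    reference_concentration: float = 0.15
    dt_sample: float = 30.0  # s, track resampling cadence
    # emulate–optimize settings (desk scale)
    lhc_samples: int = 60
    lhc_replicates: int = 3
    param_ranges: dict = field(default_factory=lambda: dict(DEFAULT_PARAM_RANGES))
    objective: ObjectiveSpec = field(default_factory=ObjectiveSpec)
    pop: int = 60
    gens: int = 60
    hidden_sizes_grid: tuple = ((24, 16, 8), (16, 8, 4))
    cv_folds: int = 3

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates >= 1")

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def paper_scale_config(**overrides) -> ExperimentConfig:
    """Full-fidelity profile: study-size design and replicate counts."""
    cfg = ExperimentConfig(
        replicates=200,
        lhc_samples=3000,
        lhc_replicates=100,
        pop=100,
        gens=250,
        hidden_sizes_grid=tuple(
            (a, b, c) for a in (8, 16, 24) for b in (8, 16, 24) for c in (8, 16, 24)
        ),
        cv_folds=5,
    )
    return replace(cfg, **overrides)


def _steady_field(net, params, spacing):
    grid = make_grid_for_network(net, spacing=spacing, params=params)
    grid = rasterize_sources(net, grid)
    return steady_state_direct(grid)


def _domain_volume(net: ReticularNetwork) -> float:
    lo, hi = np.asarray(net.bounds[0]), np.asarray(net.bounds[1])
    return float(np.prod(hi - lo))


def run_model_comparison(cfg: ExperimentConfig) -> dict:
    """Immobilized (model 1) vs soluble (model 2) chemokine at equal total mass.

    Synthesizes one follicle network, converges both steady fields, runs
    ``cfg.replicates`` agent simulations per model and compares the emergent
    per-run median scanning rates with the Vargha–Delaney A-test.
    """
    net = synthesize_follicle_network(replace(cfg.synthesis, seed=cfg.seed))
    reference_mass = cfg.reference_concentration * _domain_volume(net)
    scanning: dict[int, list[float]] = {1: [], 2: []}
    summaries: dict[int, list[MigrationSummary]] = {1: [], 2: []}
    seeds_used = []
    for model in (1, 2):
        params = model_parameterization(
            model, reference_mass, net=net, spacing=cfg.grid_spacing
        )
        ss = _steady_field(net, params, cfg.grid_spacing)
        for r in range(cfg.replicates):
            seed = cfg.seed * 10_000 + r  # matched seeds across models
            sim_cfg = replace(
                cfg.sim,
                D=params.D,
                lam=params.lam,
                k_on_ecm=params.k_on_ecm,
                secretion_fdc=params.secretion_fdc,
                secretion_rc=params.secretion_rc,
                seed=seed,
            )
            tracks = run_simulation(sim_cfg, net, grid=ss)
            summ = summarize(tracks, dt_sample=cfg.dt_sample,
                             duration=sim_cfg.duration)
            scanning[model].append(summ.scanning_rate)
            summaries[model].append(summ)
            seeds_used.append(seed)
    a = vargha_delaney_A(scanning[1], scanning[2])
    report = {
        "experiment": cfg.name,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "replicate_seeds": sorted(set(seeds_used)),
        "n_replicates": cfg.replicates,
        "A_model1_vs_model2": a,
        "effect_size": a_test_magnitude(a),
        "scanning_rate": {
            str(m): {
                "median": float(np.median(scanning[m])),
                "iqr": [float(np.percentile(scanning[m], 25)),
                        float(np.percentile(scanning[m], 75))],
                "values": [float(v) for v in scanning[m]],
            }
            for m in (1, 2)
        },
    }
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "model_comparison.json").write_text(json.dumps(report, indent=2))
    return report


def simulate_parameter_set(
    vec: np.ndarray,
    net: ReticularNetwork,
    base_sim: SimulationConfig,
    n_replicates: int,
    seed: int,
    grid_spacing: float = 8.0,
    dt_sample: float = 30.0,
) -> dict:
    """Replicate-median emergent statistics for one 13-parameter vector."""
    from .field import FieldParams

    sim0 = SimulationConfig.from_param_vector(
        vec,
        dt=base_sim.dt,
        duration=base_sim.duration,
        n_cells=base_sim.n_cells,
        contact_radius=base_sim.contact_radius,
        seed=seed,
    )
    params = FieldParams(
        D=sim0.D, lam=sim0.lam, k_on_ecm=sim0.k_on_ecm,
        k_off_ecm=1e-3 if sim0.k_on_ecm > 0 else 0.0,
        secretion_fdc=sim0.secretion_fdc, secretion_rc=sim0.secretion_rc,
    )
    ss = _steady_field(net, params, grid_spacing)
    per_metric: dict[str, list[float]] = {
        m: [] for m in MigrationSummary.METRIC_NAMES
    }
    for r in range(n_replicates):
        sim_cfg = replace(sim0, seed=seed + r)
        tracks = run_simulation(sim_cfg, net, grid=ss)
        summ = summarize(tracks, dt_sample=dt_sample, duration=sim_cfg.duration)
        for m in MigrationSummary.METRIC_NAMES:
            per_metric[m].append(getattr(summ, m))
    return {m: float(np.median(v)) for m, v in per_metric.items()}


def run_emulate_optimize(cfg: ExperimentConfig) -> dict:
    """LHC design → replicate simulations → per-output surrogates → NSGA-II."""
    rng = np.random.default_rng(cfg.seed)
    net = synthesize_follicle_network(replace(cfg.synthesis, seed=cfg.seed))
    names = list(cfg.param_ranges)
    ranges = np.array([cfg.param_ranges[k] for k in names], float)
    design = latin_hypercube(cfg.lhc_samples, ranges, seed=cfg.seed)

    responses: dict[str, list[float]] = {
        m: [] for m in MigrationSummary.METRIC_NAMES
    }
    for i, vec in enumerate(design.matrix):
        med = simulate_parameter_set(
            vec, net, cfg.sim, cfg.lhc_replicates,
            seed=int(rng.integers(0, 2**31 - 1)),
            grid_spacing=cfg.grid_spacing, dt_sample=cfg.dt_sample,
        )
        for m, v in med.items():
            responses[m].append(v)
        log.info("LHC sample %d/%d done", i + 1, cfg.lhc_samples)

    emulators, reports = {}, {}
    for m in MigrationSummary.METRIC_NAMES:
        em, rep = train_emulator(
            design, responses[m],
            hidden_sizes_grid=cfg.hidden_sizes_grid,
            k=cfg.cv_folds, seed=cfg.seed, max_iter=2000,
        )
        emulators[m] = em
        reports[m] = rep

    spec = cfg.objective
    front = nsga2(
        lambda X: spec.evaluate(emulators, X),
        bounds=ranges,
        pop=cfg.pop,
        gens=cfg.gens,
        seed=cfg.seed,
        senses=ObjectiveSpec.SENSES,
        param_names=tuple(names),
        objective_names=ObjectiveSpec.OBJECTIVE_NAMES,
    )
    conflict = conflict_analysis(front)

    result = {
        "experiment": cfg.name,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "design": design,
        "responses": pd.DataFrame(responses),
        "emulators": emulators,
        "training_reports": reports,
        "front": front,
        "conflict": conflict,
    }
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(design.matrix, columns=names).to_csv(
            out / "design.csv", index=False
        )
        pd.DataFrame(responses).to_csv(out / "responses.csv", index=False)
        front.to_frame().to_csv(out / "pareto.csv", index=False)
        conflict.to_csv(out / "conflict.csv", index=False)
        for m, em in emulators.items():
            em.save(out / f"emulator_{m}.json")
        meta = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
        (out / "meta.json").write_text(json.dumps(meta, indent=2))
    return result


def scaled_down_config(seed: int = 0, **overrides) -> ExperimentConfig:
    """Desk-scale profile: small follicle, short runs, few replicates."""
    synth = SynthesisParams(
        n_fdc=27, n_rc=33, follicle_radius=75.0, connect_radius=38.0,
        connect_decay=400.0, shortcut_fraction=0.004,
    )
    sim = SimulationConfig(duration=1200.0, dt=5.0, n_cells=10)
    cfg = ExperimentConfig(
        name="desk_scale", seed=seed, replicates=50, synthesis=synth, sim=sim,
    )
    return replace(cfg, **overrides)


def emulation_config(seed: int = 0, **overrides) -> ExperimentConfig:
    """Desk-scale emulate-then-optimize profile.

    The follicle keeps its measured full size (gradient length scales are
    what the campaign is about) while the design size, replicate count and
    run duration are reduced from the full-fidelity campaign.
    """
    sim = SimulationConfig(duration=1200.0, dt=5.0, n_cells=10)
    cfg = ExperimentConfig(
        name="emulate_optimize", seed=seed, replicates=3,
        synthesis=SynthesisParams(), sim=sim,
        lhc_samples=100, pop=80, gens=80,
    )
    return replace(cfg, **overrides)
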