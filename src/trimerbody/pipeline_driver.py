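"""End-to-end comparison pipeline and run configuration.

One run builds (or loads) the core and payload templates, samples clash-free
ensembles for *both* architectures (multi-chain and tandem) with identical
geometry, aligns every configuration onto the core reference frame, merges
occupied space on one shared voxel lattice, and reports the envelope metrics
and their cross-architecture ratios. Sharing one lattice is mandatory:
area/volume ratios across differing grids are meaningless.

Two relations are asserted on every run because they are properties of the
construction, not empirical outcomes: the merged payload area never exceeds
the sum of the per-domain areas, and every double-tethered payload anchor
stays inside both of its contour balls (the tandem support is a subset of
the multi-chain support arm by arm). The tandem envelope area is *expected*
below the multi-chain area for the same reason, but at finite ensemble size
a sparser, patchier envelope can transiently exceed it, so that comparison
is reported and warned about rather than asserted.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .assembly_stoichiometry import enumerate_trimer_species, trispecific_fraction
from .envelope_metrics import (
    DEFAULT_PADDING,
    DEFAULT_PROBE_RADIUS,
    DEFAULT_SPACING,
    EnvelopeMetrics,
    bead_bounds,
    compute_envelope_metrics,
    ensemble_payload_beads,
)
from .ensemble_sampler import (
    DEFAULT_CLASH_SCALE,
    DEFAULT_ENSEMBLE_SIZE,
    Ensemble,
    LinkerSpec,
    make_architecture,
    sample_ensemble,
)
from .structure_io import (
    BeadModel,
    DomainLabel,
    read_pdb_coarse,
    write_ensemble_pdb,
    write_grid_map,
)
from .superposition import align_ensemble
from .synthetic_structures import (
    CoreTemplate,
    PayloadTemplate,
    make_ideal_core,
    make_sphere_payload,
)

logger = logging.getLogger("trimerbody")

EXIT_CONFIG_ERROR = 2
EXIT_SAMPLING_EXHAUSTED = 3
EXIT_IO_ERROR = 4


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class CoreSource:
    """Synthetic core parameters, or a PDB file to coarse-grain."""

    anchor_radius: float = 8.0
    n_beads_per_chain: int = 10
    axial_offset: float = 25.0
    seed: int = 0
    pdb_path: str | None = None
    pdb_chains: list[str] | None = None


@dataclass
class PayloadSource:
    """Synthetic payload parameters, or a PDB chain to coarse-grain."""

    radius: float = 14.0
    n_beads: int = 200
    seed: int = 1
    pdb_path: str | None = None
    pdb_chain: str | None = None


@dataclass
class SamplerConfig:
    primary_linker_residues: int = 7
    extra_tether_residues: list[int] = field(default_factory=lambda: [17, 17])
    bond_length: float = 3.8
    linker_bead_radius: float = 1.0
    clash_scale: float = DEFAULT_CLASH_SCALE
    n_accepted: int = DEFAULT_ENSEMBLE_SIZE
    per_arm_retry: bool = True
    max_arm_attempts: int = 300
    max_total_attempts: int = 2_000_000


@dataclass
class GridConfig:
    spacing: float = DEFAULT_SPACING
    probe_radius: float = DEFAULT_PROBE_RADIUS
    padding: float = DEFAULT_PADDING


@dataclass
class RunConfig:
    core: CoreSource = field(default_factory=CoreSource)
    payload: PayloadSource = field(default_factory=PayloadSource)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    seed: int = 0
    output_dir: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        return cls(
            core=CoreSource(**data.pop("core", {})),
            payload=PayloadSource(**data.pop("payload", {})),
            sampler=SamplerConfig(**data.pop("sampler", {})),
            grid=GridConfig(**data.pop("grid", {})),
            **data,
        )

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of problems; empty iff the configuration is runnable."""
    problems: list[str] = []
    if config.grid.spacing <= 0:
        problems.append("grid.spacing must be positive")
    if config.grid.probe_radius < 0:
        problems.append("grid.probe_radius must be non-negative")
    if config.grid.padding < 0:
        problems.append("grid.padding must be non-negative")
    if config.sampler.n_accepted < 1:
        problems.append("sampler.n_accepted must be at least 1")
    if config.sampler.primary_linker_residues < 0:
        problems.append("sampler.primary_linker_residues must be non-negative")
    if len(config.sampler.extra_tether_residues) != 2:
        problems.append(
            "sampler.extra_tether_residues must list exactly 2 linkers "
            "(the tandem topology has exactly two extra tethers)"
        )
    if any(n < 0 for n in config.sampler.extra_tether_residues):
        problems.append("sampler.extra_tether_residues must be non-negative")
    if config.sampler.bond_length <= 0:
        problems.append("sampler.bond_length must be positive")
    if config.sampler.clash_scale <= 0:
        problems.append("sampler.clash_scale must be positive")
    if config.core.pdb_path is None and config.core.anchor_radius <= 0:
        problems.append("core.anchor_radius must be positive")
    if config.payload.pdb_path is None and config.payload.radius <= 0:
        problems.append("payload.radius must be positive")
    if config.core.pdb_path is not None and not os.path.exists(config.core.pdb_path):
        problems.append(f"core.pdb_path does not exist: {config.core.pdb_path}")
    if config.payload.pdb_path is not None and not os.path.exists(config.payload.pdb_path):
        problems.append(f"payload.pdb_path does not exist: {config.payload.pdb_path}")
    return problems


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------

def core_from_bead_model(model: BeadModel) -> CoreTemplate:
    """Derive a core template from a coarse-grained three-chain structure.

    The N-anchor of each chain is its first bead (chain N-terminus), the
    C-anchor its last. Symmetry is whatever the structure has; only ideal
    synthetic cores are expected to pass the exact C3 check.
    """
    chain_names = list(dict.fromkeys(model.chain_ids.tolist()))
    if len(chain_names) != 3:
        raise ValueError(f"a trimerization core needs 3 chains, got {len(chain_names)}")
    n_anchors, c_anchors = [], []
    for cid in chain_names:
        idx = np.flatnonzero(model.chain_ids == cid)
        n_anchors.append(model.positions[idx[0]])
        c_anchors.append(model.positions[idx[-1]])
    return CoreTemplate(
        model=model,
        n_anchor_points=np.asarray(n_anchors),
        c_anchor_points=np.asarray(c_anchors),
        symmetry_order=3,
    )


def payload_from_bead_model(model: BeadModel) -> PayloadTemplate:
    """Derive a payload template from a coarse-grained single-domain structure.

    Anchors are the first (N) and last (C) bead; coordinates are recentred on
    the centroid.
    """
    centered = model.transformed(np.eye(3), -model.positions.mean(axis=0))
    return PayloadTemplate(
        model=centered,
        n_anchor=centered.positions[0],
        c_anchor=centered.positions[-1],
    )


def build_templates(config: RunConfig) -> tuple[CoreTemplate, list[PayloadTemplate]]:
    if config.core.pdb_path is not None:
        chains = set(config.core.pdb_chains) if config.core.pdb_chains else None
        core = core_from_bead_model(read_pdb_coarse(config.core.pdb_path, chains))
    else:
        core = make_ideal_core(
            anchor_radius=config.core.anchor_radius,
            n_beads_per_chain=config.core.n_beads_per_chain,
            seed=config.core.seed,
            axial_offset=config.core.axial_offset,
        )
    if config.payload.pdb_path is not None:
        chains = {config.payload.pdb_chain} if config.payload.pdb_chain else None
        payload = payload_from_bead_model(
            read_pdb_coarse(config.payload.pdb_path, chains)
        )
    else:
        payload = make_sphere_payload(
            radius=config.payload.radius,
            n_beads=config.payload.n_beads,
            seed=config.payload.seed,
        )
    return core, [payload, payload, payload]


def build_architectures(config: RunConfig):
    """Both architectures on identical core/payload geometry."""
    core, payloads = build_templates(config)
    s = config.sampler
    primary = [
        LinkerSpec(s.primary_linker_residues, s.bond_length, s.linker_bead_radius)
    ] * 3
    tethers = [
        LinkerSpec(n, s.bond_length, s.linker_bead_radius)
        for n in s.extra_tether_residues
    ]
    multi = make_architecture("multi_chain", core, payloads, primary)
    tandem = make_architecture("tandem", core, payloads, primary, tethers)
    return core, multi, tandem


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    metrics: dict[str, EnvelopeMetrics]  # keyed by topology
    area_ratio_tandem_over_multi: float
    tandem_n_over_i: float
    tandem_n_over_c: float
    per_label_tandem_over_multi: dict[str, float]
    acceptance_rates: dict[str, float]
    seed: int
    config: dict
    config_hash: str
    versions: dict[str, str]

    def to_dict(self) -> dict:
        return {
            "metrics": {k: m.to_dict() for k, m in self.metrics.items()},
            "area_ratio_tandem_over_multi": self.area_ratio_tandem_over_multi,
            "tandem_n_over_i": self.tandem_n_over_i,
            "tandem_n_over_c": self.tandem_n_over_c,
            "per_label_tandem_over_multi": self.per_label_tandem_over_multi,
            "acceptance_rates": self.acceptance_rates,
            "seed": self.seed,
            "config": self.config,
            "config_hash": self.config_hash,
            "versions": self.versions,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def per_domain_frame(self) -> pd.DataFrame:
        rows = []
        for topo, m in self.metrics.items():
            for label, area in m.per_domain_area.items():
                rows.append(
                    {"architecture": topo, "domain": label.name, "area_A2": area}
                )
        return pd.DataFrame(rows)


def _assert_support_containment(tandem_ensemble: Ensemble) -> None:
    """Abort if a double-tethered payload anchor escapes its contour balls.

    Each tandem arm-2/3 payload anchor must lie within the primary linker's
    reach of its core N-anchor (plus the payload's own span, since the linker
    attaches at the opposite terminus) and within the extra tether's contour
    length of the donor C-anchor. These bounds hold by construction; a
    violation indicates an implementation defect, not a sampling fluctuation.
    """
    arch = tandem_ensemble.architecture
    core = arch.core
    for conf in tandem_ensemble.configurations:
        for k in (1, 2):
            arm = arch.arms[k]
            span = np.linalg.norm(arm.payload.n_anchor - arm.payload.c_anchor)
            reach = arm.primary_linker.n_residues * arm.primary_linker.bond_length
            anchor_pos = conf.payload_anchor_positions[k]
            d_primary = np.linalg.norm(anchor_pos - core.n_anchor_points[k])
            d_tether = np.linalg.norm(anchor_pos - core.c_anchor_points[k - 1])
            if d_primary > reach + span + 1e-6:
                raise AssertionError(
                    f"arm {k + 1} payload anchor {d_primary:.2f} Å from its "
                    f"N-anchor exceeds the primary-linker reach {reach + span:.2f} Å"
                )
            if d_tether > arch.extra_tethers[k - 1].contour_length + 1e-6:
                raise AssertionError(
                    f"arm {k + 1} payload anchor {d_tether:.2f} Å from its donor "
                    "exceeds the extra tether's contour length"
                )


def _sub_seed(seed: int, index: int) -> int:
    state = np.random.SeedSequence(seed).generate_state(index + 1)
    return int(state[index]) % (2**31)


def run_comparison(config: RunConfig) -> ComparisonReport:
    """Sample, align and measure both architectures; emit the comparison.

    Deterministic for a fixed config (the two ensembles use child seeds
    derived from ``config.seed``). Writes JSON/CSV reports, multi-model PDB
    ensembles and CCP4 envelope maps to ``config.output_dir`` if set.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))

    core, multi_arch, tandem_arch = build_architectures(config)
    s = config.sampler

    ensembles: dict[str, Ensemble] = {}
    for index, (name, arch) in enumerate(
        [("multi_chain", multi_arch), ("tandem", tandem_arch)]
    ):
        t0 = time.perf_counter()
        ens = sample_ensemble(
            arch,
            n_accepted=s.n_accepted,
            seed=_sub_seed(config.seed, index),
            max_total_attempts=s.max_total_attempts,
            per_arm_retry=s.per_arm_retry,
            clash_scale=s.clash_scale,
            max_arm_attempts=s.max_arm_attempts,
        )
        ensembles[name] = align_ensemble(ens, core.model)
        logger.info(
            "%s: %d/%d accepted (rate %.3g) in %.1f s",
            name, ens.accepted, ens.attempts, ens.acceptance_rate,
            time.perf_counter() - t0,
        )

    # one shared lattice across both architectures
    clouds = [ensemble_payload_beads(e) for e in ensembles.values()]
    bounds = bead_bounds(clouds, config.grid.padding)

    metrics: dict[str, EnvelopeMetrics] = {}
    diags: dict[str, dict] = {}
    for name, ens in ensembles.items():
        m, d = compute_envelope_metrics(
            ens, spacing=config.grid.spacing,
            probe_radius=config.grid.probe_radius, bounds=bounds,
        )
        metrics[name], diags[name] = m, d
        # construction property: merging can only hide area
        if m.surface_area > d["sum_of_individual"] * (1 + 1e-9):
            raise AssertionError(
                f"{name}: merged area {m.surface_area:.1f} exceeds the sum of "
                f"per-domain areas {d['sum_of_individual']:.1f}"
            )

    # construction property: every double-tethered payload anchor stays inside
    # both contour balls (the tandem support is a subset of the multi-chain
    # support arm by arm)
    _assert_support_containment(ensembles["tandem"])

    area_ratio = metrics["tandem"].surface_area / metrics["multi_chain"].surface_area
    if area_ratio > 1.0:
        # expected to fall below 1 (double tethering restricts the support),
        # but finite ensembles of patchy envelopes can fluctuate above it
        logger.warning(
            "tandem/multi-chain area ratio %.3f > 1; increase n_accepted for "
            "a stable comparison", area_ratio,
        )

    tandem_areas = metrics["tandem"].per_domain_area
    report = ComparisonReport(
        metrics=metrics,
        area_ratio_tandem_over_multi=area_ratio,
        tandem_n_over_i=tandem_areas[DomainLabel.PAYLOAD_N]
        / tandem_areas[DomainLabel.PAYLOAD_I],
        tandem_n_over_c=tandem_areas[DomainLabel.PAYLOAD_N]
        / tandem_areas[DomainLabel.PAYLOAD_C],
        per_label_tandem_over_multi={
            label.name: tandem_areas[label] / metrics["multi_chain"].per_domain_area[label]
            for label in tandem_areas
        },
        acceptance_rates={
            name: ens.acceptance_rate for name, ens in ensembles.items()
        },
        seed=config.seed,
        config=config.to_dict(),
        config_hash=config.config_hash(),
        versions={"trimerbody": _pkg_version, "numpy": np.__version__},
    )

    if config.output_dir:
        _write_outputs(config, ensembles, diags, report)
    return report


def _write_outputs(config, ensembles, diags, report) -> None:
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    with open(os.path.join(out, "report.json"), "w") as fh:
        fh.write(report.to_json())
    report.per_domain_frame().to_csv(
        os.path.join(out, "per_domain_areas.csv"), index=False
    )
    for name, ens in ensembles.items():
        write_ensemble_pdb(ens, os.path.join(out, f"ensemble_{name}.pdb"))
        write_grid_map(
            diags[name]["merged_grid"], os.path.join(out, f"envelope_{name}.ccp4")
        )
    logger.info("outputs written to %s", out)


def species_report(n_chain_types: int = 3, mode: str = "multiset_uniform",
                   abundances=None) -> dict:
    """Trimer species table plus the trispecific fraction, as plain data."""
    table = enumerate_trimer_species(n_chain_types, mode, abundances)
    return {
        "mode": mode,
        "n_chain_types": n_chain_types,
        "n_species": len(table.compositions),
        "trispecific_fraction": trispecific_fraction(table),
        "species": table.as_records(),
    }
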