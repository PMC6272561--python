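"""Study orchestration: run every analysis stage for one or two arms.

An "arm" is one conformational ensemble (e.g. one-ligand normal binding vs
two-ligand cooperative binding).  The pipeline runs RMSD, ring stacking,
close contacts, hydrogen bonds, binding energy breakdowns and per-residue
decomposition per arm, compares arms by a seeded permutation test, and
writes a deterministic JSON report plus tidy TSV tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path

import numpy as np
import yaml

import coopbind
from coopbind import energetics, geometry
from coopbind.energetics import EnergyBreakdown, SolventParams
from coopbind.model_io import read_ensemble, read_topology

logger = logging.getLogger(__name__)

TABLE_ROW_ORDER = (
    "dE_ele",
    "dE_vdw",
    "dE_gas",
    "dG_nonpolar",
    "dG_sol",
    "dG_ele_total",
    "dG_bind",
)


class PipelineError(RuntimeError):
    """Wraps a stage failure with the stage name and offending input."""


# ---------------------------------------------------------------------------
# bookkeeping identities and formatting
# ---------------------------------------------------------------------------

def gas_phase_total(e_ele: float, e_vdw: float) -> float:
    """Gas-phase interaction energy: electrostatic plus van der Waals."""
    return e_ele + e_vdw


def binding_total(e_gas: float, g_sol: float) -> float:
    """Binding free energy under the entropy-neglected identity."""
    return e_gas + g_sol


def electrostatic_total(e_ele: float, g_sol: float, g_nonpolar: float) -> float:
    """Gas electrostatics plus polar solvation (solvation minus nonpolar)."""
    return e_ele + (g_sol - g_nonpolar)


def round_half_even(value: float, decimals: int = 2) -> float:
    """Banker's rounding on the decimal literal of ``value``."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_EVEN))


def fold_change(cooperative: float, normal: float, decimals: int = 2) -> float:
    """cooperative/normal contribution ratio, banker's-rounded."""
    if normal == 0:
        raise ZeroDivisionError("normal-arm contribution is zero")
    return round_half_even(cooperative / normal, decimals)


def format_value(mean: float, std: float) -> str:
    """Render "mean ± std" at two decimals with banker's rounding."""
    return f"{round_half_even(mean):.2f} ± {round_half_even(std):.2f}"


def format_breakdown_table(breakdown: EnergyBreakdown) -> list[tuple[str, str]]:
    """Component rows in canonical order, formatted "mean ± std"."""
    rows = []
    for term in TABLE_ROW_ORDER:
        s = breakdown.summary(term)
        rows.append((f"{term}/{breakdown.solvent_model}", format_value(s.mean, s.sample_std)))
    return rows


def format_contact_figure_data(
    profile: geometry.ContactProfile,
) -> list[tuple[int, str, str]]:
    """(residue number, residue name, percentage) rows sorted by number."""
    rows = []
    for (chain, resnum, resname), frac in sorted(
        profile.fractions.items(), key=lambda kv: (kv[0][0], kv[0][1])
    ):
        rows.append((resnum, resname, f"{100.0 * frac:.1f}"))
    return rows


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Everything the pipeline needs; all cutoffs/thresholds surfaced."""

    arms: dict[str, dict[str, str]]  # name -> {"ensemble": ..., "topology": ...}
    output_dir: str = "."
    ligand_partition: str = "ligand1"
    solvent_models: list[str] = field(default_factory=lambda: ["GB"])
    other_ligand_as_receptor: bool = True
    stacking_cutoff: float = geometry.STACKING_CUTOFF
    contact_cutoff: float = geometry.CONTACT_CUTOFF
    hbond_distance: float = 3.5
    hbond_angle: float = 120.0
    parallel_max_angle: float = geometry.PARALLEL_MAX_ANGLE
    perpendicular_min_angle: float = geometry.PERPENDICULAR_MIN_ANGLE
    planarity_tolerance: float = geometry.PLANARITY_TOLERANCE
    n_resamples: int = 999
    seed: int = 0
    run_decomposition: bool = True
    solvent: dict = field(default_factory=dict)  # SolventParams overrides

    def __post_init__(self) -> None:
        if not self.arms:
            raise PipelineError("config must define at least one arm")
        for cut in (self.stacking_cutoff, self.contact_cutoff, self.hbond_distance):
            if cut <= 0:
                raise PipelineError("cutoffs must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)

    def to_dict(self) -> dict:
        return {
            "arms": self.arms,
            "output_dir": self.output_dir,
            "ligand_partition": self.ligand_partition,
            "solvent_models": self.solvent_models,
            "other_ligand_as_receptor": self.other_ligand_as_receptor,
            "stacking_cutoff": self.stacking_cutoff,
            "contact_cutoff": self.contact_cutoff,
            "hbond_distance": self.hbond_distance,
            "hbond_angle": self.hbond_angle,
            "parallel_max_angle": self.parallel_max_angle,
            "perpendicular_min_angle": self.perpendicular_min_angle,
            "planarity_tolerance": self.planarity_tolerance,
            "n_resamples": self.n_resamples,
            "seed": self.seed,
            "run_decomposition": self.run_decomposition,
            "solvent": self.solvent,
        }

    def solvent_params(self) -> SolventParams:
        return SolventParams(**self.solvent)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class StudyReport:
    """All per-arm results, cross-arm comparisons, and provenance."""

    config: AnalysisConfig
    arm_results: dict[str, dict]
    comparisons: dict[str, dict]
    breakdowns: dict[str, dict[str, EnergyBreakdown]]

    def to_dict(self) -> dict:
        return {
            "provenance": {
                "package_version": coopbind.__version__,
                "config_hash": self.config.config_hash(),
                "seed": self.config.seed,
                "config": self.config.to_dict(),
            },
            "arms": self.arm_results,
            "comparisons": self.comparisons,
        }


def _summary_dict(s: geometry.SeriesSummary) -> dict:
    return {"mean": s.mean, "sample_std": s.sample_std, "n_frames": s.n_frames}


def _residue_label(key) -> str:
    if isinstance(key, str):
        return key
    chain, resnum, resname = key
    return f"{chain}/{resnum}/{resname}"


def _analyze_arm(name: str, paths: dict[str, str], config: AnalysisConfig):
    def stage(label: str):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(
                        f"arm {name!r}, stage {label!r} failed "
                        f"(inputs: {paths}): {exc}"
                    ) from exc
                logger.info(
                    "arm %s: stage %s done in %.2f s",
                    name, label, time.perf_counter() - self_inner.t0,
                )
                return False

        return _Ctx()

    result: dict = {}
    with stage("load"):
        topology = read_topology(paths["topology"])
        ensemble = read_ensemble(paths["ensemble"], topology)
        logger.info("arm %s: %d frames, %d atoms", name, ensemble.n_frames,
                    topology.n_atoms)

    with stage("rmsd"):
        sel = geometry.backbone_selection(topology)
        series, summary = geometry.backbone_rmsd_series(
            ensemble, ensemble.frames[0], sel
        )
        result["rmsd"] = {
            "selection_size": int(len(sel)),
            "series": [float(v) for v in series],
            "summary": _summary_dict(summary),
        }

    with stage("stacking"):
        rings = geometry.perceive_rings(
            topology, ensemble.frames[0], config.planarity_tolerance
        )
        records, summaries = geometry.detect_stacking(
            ensemble,
            rings,
            cutoff=config.stacking_cutoff,
            parallel_max=config.parallel_max_angle,
            perpendicular_min=config.perpendicular_min_angle,
        )
        result["rings"] = [
            {
                "ring_id": r.ring_id,
                "member_atoms": list(r.member_atoms),
                "owner_partition": r.owner_partition,
            }
            for r in rings
        ]
        result["stacking"] = [
            {
                "ring_a": s.ring_a,
                "ring_b": s.ring_b,
                "occupancy": s.occupancy,
                "distance_qualifying": (
                    _summary_dict(s.distance_qualifying)
                    if s.distance_qualifying else None
                ),
                "angle_qualifying": (
                    _summary_dict(s.angle_qualifying)
                    if s.angle_qualifying else None
                ),
                "distance_all": _summary_dict(s.distance_all),
                "angle_all": _summary_dict(s.angle_all),
            }
            for s in summaries
        ]

    with stage("contacts"):
        profile = geometry.close_contact_fraction(
            ensemble, config.ligand_partition, config.contact_cutoff
        )
        result["contacts"] = {
            "cutoff": profile.cutoff,
            "n_frames": profile.n_frames,
            "fractions": {
                _residue_label(k): v for k, v in profile.fractions.items()
            },
        }

    with stage("hbonds"):
        heavy_donors = [
            i
            for i, a in enumerate(topology.atoms)
            if a.element.upper() in ("N", "O")
            and a.partition == "receptor"
            and geometry._bonded_hydrogens(topology, i)
        ]
        acceptors = [
            i
            for i, a in enumerate(topology.atoms)
            if a.element.upper() in ("N", "O")
            and a.partition == config.ligand_partition
        ]
        records = (
            geometry.hydrogen_bonds(
                ensemble,
                heavy_donors,
                acceptors,
                d_cut=config.hbond_distance,
                angle_cut=config.hbond_angle,
            )
            if heavy_donors and acceptors
            else []
        )
        result["hbonds"] = [
            {
                "donor_serial": topology.atoms[r.donor_atom].serial,
                "acceptor_serial": topology.atoms[r.acceptor_atom].serial,
                "mean_distance": r.heavy_atom_distance,
                "mean_angle": r.donor_angle,
                "occupancy": r.occupancy,
            }
            for r in records
        ]

    breakdowns: dict[str, EnergyBreakdown] = {}
    params = config.solvent_params()
    for model in config.solvent_models:
        with stage(f"energetics/{model}"):
            breakdowns[model] = energetics.single_trajectory_mmgbsa(
                ensemble,
                params,
                solvent_model=model,
                ligand_partition=config.ligand_partition,
                other_ligand_as_receptor=config.other_ligand_as_receptor,
            )
    result["energy"] = {
        model: {
            term: _summary_dict(b.summary(term)) for term in energetics.TERMS
        }
        for model, b in breakdowns.items()
    }
    result["energy_tables"] = {
        model: format_breakdown_table(b) for model, b in breakdowns.items()
    }

    if config.run_decomposition and "GB" in config.solvent_models:
        with stage("decomposition"):
            contributions = energetics.per_residue_decomposition(
                ensemble,
                params,
                ligand_partition=config.ligand_partition,
                other_ligand_as_receptor=config.other_ligand_as_receptor,
            )
            result["decomposition"] = [
                {
                    "residue": _residue_label(c.residue_id),
                    "summary": _summary_dict(c.summary),
                }
                for c in contributions
            ]
    return result, breakdowns


def run_analysis(config: AnalysisConfig) -> StudyReport:
    """Run every stage for every arm, then cross-arm comparisons.

    Deterministic for a fixed config (the permutation seed is part of the
    config), so two runs write byte-identical reports.
    """
    arm_results: dict[str, dict] = {}
    breakdowns: dict[str, dict[str, EnergyBreakdown]] = {}
    for name, paths in config.arms.items():
        arm_results[name], breakdowns[name] = _analyze_arm(name, paths, config)

    comparisons: dict[str, dict] = {}
    names = list(config.arms)
    if len(names) == 2:
        a, b = names
        for model in config.solvent_models:
            ddg, p = energetics.compare_breakdowns(
                breakdowns[a][model],
                breakdowns[b][model],
                n_resamples=config.n_resamples,
                seed=config.seed,
            )
            comparisons[model] = {
                "arm_a": a,
                "arm_b": b,
                "ddG_bind": ddg,
                "p_value": p,
                "n_resamples": config.n_resamples,
            }
    return StudyReport(
        config=config,
        arm_results=arm_results,
        comparisons=comparisons,
        breakdowns=breakdowns,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_report(report: StudyReport, output_dir: str | Path) -> dict[str, Path]:
    """Write report.json plus one TSV per analysis; returns written paths."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    path = out / "report.json"
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    written["report"] = path

    def tsv(name: str, header: list[str], rows: list[list]) -> None:
        p = out / name
        with open(p, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for row in rows:
                fh.write("\t".join(str(c) for c in row) + "\n")
        written[name] = p

    rows = []
    for arm, res in report.arm_results.items():
        for model, table in res["energy_tables"].items():
            for label, value in table:
                rows.append([arm, model, label, value])
    tsv("table1.tsv", ["arm", "solvent_model", "term", "value"], rows)

    rows = []
    for arm, res in report.arm_results.items():
        for entry in res.get("decomposition", []):
            s = entry["summary"]
            rows.append([
                arm, entry["residue"],
                format_value(s["mean"], s["sample_std"]), s["n_frames"],
            ])
    tsv("decomposition.tsv", ["arm", "residue", "dG_contribution", "n_frames"], rows)

    rows = []
    for arm, res in report.arm_results.items():
        for label, frac in sorted(res["contacts"]["fractions"].items()):
            rows.append([arm, label, f"{100.0 * frac:.1f}"])
    tsv("contacts.tsv", ["arm", "residue", "contact_percent"], rows)

    rows = []
    for arm, res in report.arm_results.items():
        for s in res["stacking"]:
            dq = s["distance_qualifying"]
            aq = s["angle_qualifying"]
            rows.append([
                arm, s["ring_a"], s["ring_b"], f"{s['occupancy']:.3f}",
                "" if dq is None else format_value(dq["mean"], dq["sample_std"]),
                "" if aq is None else format_value(aq["mean"], aq["sample_std"]),
            ])
    tsv(
        "stacking.tsv",
        ["arm", "ring_a", "ring_b", "occupancy", "distance", "angle"],
        rows,
    )

    rows = []
    for arm, res in report.arm_results.items():
        for h in res["hbonds"]:
            rows.append([
                arm, h["donor_serial"], h["acceptor_serial"],
                f"{h['mean_distance']:.2f}",
                "nan" if math.isnan(h["mean_angle"]) else f"{h['mean_angle']:.1f}",
                f"{h['occupancy']:.3f}",
            ])
    tsv(
        "hbonds.tsv",
        ["arm", "donor_serial", "acceptor_serial", "distance", "angle", "occupancy"],
        rows,
    )

    rows = []
    for arm, res in report.arm_results.items():
        for i, v in enumerate(res["rmsd"]["series"]):
            rows.append([arm, i, f"{v:.4f}"])
    tsv("rmsd.tsv", ["arm", "frame", "rmsd"], rows)

    return written
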