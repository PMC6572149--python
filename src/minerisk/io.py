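"""Study configuration, accident-table I/O and pipeline orchestration.

A study configuration (YAML or JSON) aggregates everything one assessment
needs: the accident sample size, per-working-type factor elicitation
ranges and per-behavior citation counts with hazard-index normals, the
correction-model coefficients and the simulation settings. Validation is
exhaustive — every violation is reported with its config path, not just
the first.

``run_pipeline`` executes the whole chain — tabulate, correct, simulate,
summarize, sensitivity — and returns a JSON-serializable report that
reproduces byte-for-byte under the same seed (timestamp aside).
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalog import (
    BEHAVIOR_CLASSES,
    WORKING_TYPES,
    AccidentRecord,
    OccurrenceTable,
    occurrence_probability,
    tabulate_occurrences,
    working_type_share,
)
from .correction import (
    FACTORS,
    FactorProfile,
    FactorRange,
    ModelCoefficients,
    correction_factor_mean,
    revised_probability,
)
from .hazard import HazardIndexSpec
from .mc import (
    SimulationConfig,
    assess_working_type,
    total_risk_samples,
    simulate_working_type,
    summarize,
)
from .sensitivity import pooled_sensitivity, rank_sensitivities

__all__ = [
    "StudyConfig",
    "WorkingTypeBlock",
    "BehaviorBlock",
    "ConfigError",
    "read_study_config",
    "study_config_from_dict",
    "study_config_to_dict",
    "write_study_config",
    "read_accidents_csv",
    "write_accidents_csv",
    "run_pipeline",
    "write_report",
    "read_report",
]

ACCIDENT_CSV_COLUMNS = ("accident_id", "working_type", "behavior_code")


class ConfigError(ValueError):
    """Raised with the full list of configuration violations."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__(
            "invalid study configuration:\n" + "\n".join(f"  - {e}" for e in self.errors)
        )


@dataclass
class BehaviorBlock:
    code: str
    count: int = 0
    hazard: Optional[HazardIndexSpec] = None


@dataclass
class WorkingTypeBlock:
    id: str
    name: str
    is_key: bool = False
    profile: Optional[FactorProfile] = None
    behaviors: Dict[str, BehaviorBlock] = field(default_factory=dict)


@dataclass
class StudyConfig:
    n_accidents: int
    coefficients: ModelCoefficients
    simulation: SimulationConfig
    working_types: Dict[str, WorkingTypeBlock] = field(default_factory=dict)

    def counts(self) -> Dict[Tuple[str, str], int]:
        return {
            (wt.id, b.code): b.count
            for wt in self.working_types.values()
            for b in wt.behaviors.values()
        }

    def key_working_types(self) -> List[WorkingTypeBlock]:
        return [wt for wt in self.working_types.values() if wt.is_key]


def _parse_factor_range(factor: str, raw, path: str, errors: List[str]):
    if not isinstance(raw, (list, tuple)) or len(raw) not in (2, 3):
        errors.append(f"{path}: expected [lower, upper] or [lower, mode, upper]")
        return None
    try:
        vals = [float(v) for v in raw]
    except (TypeError, ValueError):
        errors.append(f"{path}: non-numeric entries {raw!r}")
        return None
    lower, upper = vals[0], vals[-1]
    mode = vals[1] if len(vals) == 3 else None
    try:
        return FactorRange(factor, lower, upper, mode)
    except ValueError as exc:
        errors.append(f"{path}: {exc}")
        return None


def study_config_from_dict(data: dict) -> StudyConfig:
    """Build and fully validate a StudyConfig from a parsed mapping."""
    errors: List[str] = []
    study = data.get("study", {})
    n_accidents = study.get("n_accidents", 0)
    if not isinstance(n_accidents, int) or n_accidents < 0:
        errors.append("study.n_accidents: must be a non-negative integer")
        n_accidents = 0

    model = data.get("model", {})
    try:
        coeffs = ModelCoefficients(
            org_weights=tuple(model.get("org_weights", (0.2, 0.6, 0.2))),
            slope=float(model.get("slope", 0.0167)),
            intercept=float(model.get("intercept", 1.5)),
        )
    except (TypeError, ValueError) as exc:
        errors.append(f"model: {exc}")
        coeffs = ModelCoefficients()

    sim = data.get("simulation", {})
    try:
        simulation = SimulationConfig(
            iterations=int(sim.get("iterations", 10_000)),
            seed=int(sim.get("seed", 0)),
            confidence=float(sim.get("confidence", 0.95)),
            truncation=str(sim.get("truncation", "none")),
            total_mode=str(sim.get("total_mode", "comonotonic")),
            coefficients=coeffs,
        )
    except (TypeError, ValueError) as exc:
        errors.append(f"simulation: {exc}")
        simulation = SimulationConfig(coefficients=coeffs)

    blocks: Dict[str, WorkingTypeBlock] = {}
    for wt_id, wt_raw in (data.get("working_types") or {}).items():
        base = f"working_types.{wt_id}"
        if wt_id not in WORKING_TYPES:
            errors.append(f"{base}: unknown working type id")
            continue
        wt_raw = wt_raw or {}
        block = WorkingTypeBlock(
            id=wt_id,
            name=str(wt_raw.get("name", WORKING_TYPES[wt_id].name)),
            is_key=bool(wt_raw.get("is_key", WORKING_TYPES[wt_id].is_key)),
        )
        factors_raw = wt_raw.get("factors")
        if factors_raw is not None:
            ranges = {}
            for f in FACTORS:
                if f not in factors_raw:
                    errors.append(f"{base}.factors.{f}: missing factor")
                    continue
                fr = _parse_factor_range(f, factors_raw[f], f"{base}.factors.{f}", errors)
                if fr is not None:
                    ranges[f] = fr
            for f in factors_raw:
                if f not in FACTORS:
                    errors.append(f"{base}.factors.{f}: unknown factor")
            if len(ranges) == len(FACTORS):
                block.profile = FactorProfile(working_type=wt_id, ranges=ranges)
        for code, b_raw in (wt_raw.get("behaviors") or {}).items():
            bpath = f"{base}.behaviors.{code}"
            if code not in BEHAVIOR_CLASSES:
                errors.append(f"{bpath}: unknown behavior code")
                continue
            b_raw = b_raw or {}
            count = b_raw.get("count", 0)
            if not isinstance(count, int) or count < 0:
                errors.append(f"{bpath}.count: must be a non-negative integer")
                count = 0
            hazard = None
            h_raw = b_raw.get("hazard")
            if h_raw is not None:
                try:
                    hazard = HazardIndexSpec(
                        wt_id, code, float(h_raw["mean"]), float(h_raw["sd"])
                    )
                except KeyError as exc:
                    errors.append(f"{bpath}.hazard: missing key {exc}")
                except (TypeError, ValueError) as exc:
                    errors.append(f"{bpath}.hazard: {exc}")
            block.behaviors[code] = BehaviorBlock(code=code, count=count, hazard=hazard)
        blocks[wt_id] = block

    for wt_id, block in blocks.items():
        if block.is_key and block.behaviors:
            if block.profile is None:
                errors.append(
                    f"working_types.{wt_id}.factors: key working type with "
                    "behavior data needs all eight factor ranges"
                )
            for code, b in block.behaviors.items():
                if b.count > 0 and b.hazard is None:
                    errors.append(
                        f"working_types.{wt_id}.behaviors.{code}.hazard: "
                        "behavior with a count needs a hazard spec before simulation"
                    )

    if errors:
        raise ConfigError(errors)
    return StudyConfig(
        n_accidents=n_accidents,
        coefficients=coeffs,
        simulation=simulation,
        working_types=blocks,
    )


def read_study_config(path) -> StudyConfig:
    """Read a YAML or JSON study configuration (JSON parses as YAML)."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(["top level: expected a mapping"])
    return study_config_from_dict(data)


def study_config_to_dict(cfg: StudyConfig) -> dict:
    def _range(fr: FactorRange):
        if fr.mode is None:
            return [fr.lower, fr.upper]
        return [fr.lower, fr.mode, fr.upper]

    out: dict = {
        "study": {"n_accidents": cfg.n_accidents},
        "model": {
            "org_weights": list(cfg.coefficients.org_weights),
            "slope": cfg.coefficients.slope,
            "intercept": cfg.coefficients.intercept,
        },
        "simulation": {
            "iterations": cfg.simulation.iterations,
            "seed": cfg.simulation.seed,
            "confidence": cfg.simulation.confidence,
            "truncation": cfg.simulation.truncation,
            "total_mode": cfg.simulation.total_mode,
        },
        "working_types": {},
    }
    for wt_id, block in cfg.working_types.items():
        wt_out: dict = {"name": block.name, "is_key": block.is_key}
        if block.profile is not None:
            wt_out["factors"] = {
                f: _range(block.profile.ranges[f]) for f in FACTORS
            }
        if block.behaviors:
            wt_out["behaviors"] = {
                code: {
                    "count": b.count,
                    **(
                        {"hazard": {"mean": b.hazard.mean, "sd": b.hazard.sd}}
                        if b.hazard
                        else {}
                    ),
                }
                for code, b in block.behaviors.items()
            }
        out["working_types"][wt_id] = wt_out
    return out


def write_study_config(cfg: StudyConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(study_config_to_dict(cfg), fh, sort_keys=False)


def write_accidents_csv(records: Sequence[AccidentRecord], path) -> None:
    """One citation per row: accident_id, working_type, behavior_code."""
    rows = [
        {"accident_id": r.accident_id, "working_type": wt, "behavior_code": bc}
        for r in records
        for wt, bc in r.citations
    ]
    pd.DataFrame(rows, columns=list(ACCIDENT_CSV_COLUMNS)).to_csv(path, index=False)


def read_accidents_csv(path) -> List[AccidentRecord]:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ACCIDENT_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"accident CSV missing column(s) {missing}")
    records: Dict[str, List[Tuple[str, str]]] = {}
    for row in df.itertuples(index=False):
        records.setdefault(row.accident_id, []).append(
            (row.working_type, row.behavior_code)
        )
    return [
        AccidentRecord(accident_id=aid, citations=tuple(cits))
        for aid, cits in records.items()
    ]


def _summary_dict(samples: np.ndarray, confidence: float) -> dict:
    if np.asarray(samples).size < 2:
        return {
            "mean": float(np.asarray(samples, dtype=float).mean()),
            "sd": None,
            "degenerate": True,
        }
    return summarize(samples, confidence).as_dict()


def run_pipeline(config: StudyConfig, seed: Optional[int] = None) -> dict:
    """Execute the full assessment and return a serializable report.

    Stages: regenerate the coded accident table from the configured counts
    and tabulate it; compute per-type correction factors and revised
    probabilities; Monte Carlo simulate per-behavior and total risks for
    every key working type; decompose the pooled total risk. ``seed``
    overrides the configured simulation seed.
    """
    from .synthetic import SyntheticStudyConfig, generate_accident_records

    sim = config.simulation
    if seed is not None:
        sim = SimulationConfig(
            iterations=sim.iterations,
            seed=seed,
            confidence=sim.confidence,
            truncation=sim.truncation,
            total_mode=sim.total_mode,
            coefficients=sim.coefficients,
        )

    stage = "tabulate"
    try:
        records = generate_accident_records(
            SyntheticStudyConfig(
                n_accidents=config.n_accidents,
                targets=config.counts(),
                mode="exact",
                seed=sim.seed,
            )
        )
        table = tabulate_occurrences(records)

        stage = "correct"
        correction: Dict[str, dict] = {}
        for block in config.key_working_types():
            F = correction_factor_mean(block.profile, config.coefficients)
            correction[block.id] = {
                "correction_factor": F,
                "share_pct": working_type_share(table, block.id),
                "behaviors": {
                    code: {
                        "count": table.count(block.id, code),
                        "p_raw": occurrence_probability(table, block.id, code),
                        "p_revised": revised_probability(
                            occurrence_probability(table, block.id, code), F
                        ),
                    }
                    for code in block.behaviors
                },
            }

        stage = "simulate"
        risk: Dict[str, dict] = {}
        p_raw_all: Dict[str, Dict[str, float]] = {}
        profiles = {}
        specs_all = {}
        for i, block in enumerate(config.key_working_types()):
            p_raw = {
                code: occurrence_probability(table, block.id, code)
                for code in block.behaviors
            }
            specs = {code: b.hazard for code, b in block.behaviors.items()}
            wt_sim = SimulationConfig(
                iterations=sim.iterations,
                seed=sim.seed + i,
                confidence=sim.confidence,
                truncation=sim.truncation,
                total_mode=sim.total_mode,
                coefficients=sim.coefficients,
            )
            samples = simulate_working_type(p_raw, block.profile, specs, wt_sim)
            totals = total_risk_samples(samples, sim.total_mode, wt_sim.seed)
            risk[block.id] = {
                "per_behavior": {
                    code: _summary_dict(x, sim.confidence)
                    for code, x in samples.items()
                },
                "total": _summary_dict(totals, sim.confidence),
            }
            p_raw_all[block.id] = p_raw
            profiles[block.id] = block.profile
            specs_all[block.id] = specs

        stage = "sensitivity"
        if sim.iterations >= 100:
            sens = pooled_sensitivity(
                p_raw_all,
                profiles,
                specs_all,
                iterations=sim.iterations,
                seed=sim.seed,
                coefficients=config.coefficients,
            )
            sens_block = {
                "output": sens.output,
                "contributions_pct": sens.contributions,
                "rank_correlations": sens.rank_correlations,
                "ranking": [name for name, _ in rank_sensitivities(sens)],
            }
        else:
            sens_block = {"skipped": "needs at least 100 iterations"}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "config": study_config_to_dict(config) | {
            "simulation_resolved": {
                "iterations": sim.iterations,
                "seed": sim.seed,
                "confidence": sim.confidence,
                "truncation": sim.truncation,
                "total_mode": sim.total_mode,
            }
        },
        "occurrence": {
            "n_accidents": table.n_accidents,
            "counts": {
                f"{wt}/{bc}": n for (wt, bc), n in sorted(table.counts.items())
            },
        },
        "correction": correction,
        "risk": risk,
        "sensitivity": sens_block,
        "provenance": {
            "package_version": __version__,
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        },
    }


def write_report(report: dict, path) -> None:
    """JSON with sorted keys and full float precision; byte-stable."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
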