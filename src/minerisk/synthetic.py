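"""Synthetic coded accident tables with a stated count structure.

The original 200-accident coding is not deposited, so testable inputs are
regenerated: given per-(working type, behavior) targets, ``exact`` mode
emits a table that tabulates back to those counts identically, while
``multinomial`` mode draws the cell counts once from a multinomial over
target probabilities. Each synthetic accident is coded to one working type
and one behavior class, matching the count algebra of the reference
tables; the record model still permits multi-citation accidents.

``reference_study`` returns the packaged reference dataset: the
200-accident exact-mode table and the full study configuration (factor
ranges, hazard-index normals, model coefficients, simulation settings).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Tuple

import numpy as np
import yaml

from .catalog import BEHAVIOR_CLASSES, WORKING_TYPES, AccidentRecord
from .io import StudyConfig, study_config_from_dict

__all__ = [
    "SyntheticStudyConfig",
    "generate_accident_records",
    "reference_study",
]


@dataclass
class SyntheticStudyConfig:
    """Target count structure of a synthetic accident table.

    ``targets`` maps (working_type, behavior) to a count (exact mode) or a
    probability (multinomial mode; must sum to 1).
    """

    n_accidents: int
    targets: Dict[Tuple[str, str], float] = field(default_factory=dict)
    mode: str = "exact"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_accidents < 0:
            raise ValueError("n_accidents must be non-negative")
        if self.mode not in ("exact", "multinomial"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for wt, bc in self.targets:
            if wt not in WORKING_TYPES:
                raise ValueError(f"unknown working type {wt!r} in targets")
            if bc not in BEHAVIOR_CLASSES:
                raise ValueError(f"unknown behavior code {bc!r} in targets")


def generate_accident_records(cfg: SyntheticStudyConfig) -> List[AccidentRecord]:
    """Generate one synthetic accident table; deterministic by seed.

    Exact mode requires integer targets summing to ``n_accidents`` and
    reproduces them under tabulation; multinomial mode draws cell counts
    from Multinomial(n_accidents, targets). Accident ids are sequential
    ``ACC-0001``-style; record order is a seeded shuffle.
    """
    if cfg.n_accidents == 0:
        return []
    cells = sorted(cfg.targets)
    rng = np.random.default_rng(cfg.seed)
    if cfg.mode == "exact":
        counts = []
        for cell in cells:
            c = cfg.targets[cell]
            if c != int(c) or c < 0:
                raise ValueError(f"exact-mode target for {cell} must be a count, got {c}")
            counts.append(int(c))
        if sum(counts) != cfg.n_accidents:
            raise ValueError(
                f"exact-mode targets sum to {sum(counts)}, not n_accidents={cfg.n_accidents}"
            )
    else:
        probs = np.array([float(cfg.targets[c]) for c in cells])
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("multinomial-mode targets must be probabilities summing to 1")
        counts = rng.multinomial(cfg.n_accidents, probs).tolist()

    citations = [cell for cell, k in zip(cells, counts) for _ in range(k)]
    rng.shuffle(citations)
    width = max(4, len(str(len(citations))))
    return [
        AccidentRecord(accident_id=f"ACC-{i + 1:0{width}d}", citations=(cell,))
        for i, cell in enumerate(citations)
    ]


def reference_study() -> Tuple[List[AccidentRecord], StudyConfig]:
    """The packaged 200-accident reference table and full study config."""
    raw = resources.files("minerisk").joinpath("data/study.yaml").read_text("utf-8")
    config = study_config_from_dict(yaml.safe_load(raw))
    records = generate_accident_records(
        SyntheticStudyConfig(
            n_accidents=config.n_accidents,
            targets=config.counts(),
            mode="exact",
            seed=config.simulation.seed,
        )
    )
    return records, config
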