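"""File interfaces: tidy placement/demographics CSVs, JSON run config, and
deterministic report output.

Placement file: one row per (participant_id, diagram, role, x_px, y_px),
UTF-8, header required.  Demographics file: one row per participant with
age, gender, romantic_status, parental_status.  All report files are
written with stable row order and a fixed float format so identical inputs
produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .composition import composition_table
from .diagram import DiagramCalibration, ParticipantRecord, Placement, Thresholds
from .errors import ValidationError
from .pipeline import score_records
from .simulate import GeneratorConfig
from .tables import (
    correlation_table,
    demographics_table,
    morphology_regressions,
    proximity_regressions,
    proximity_table,
    strength_regressions,
)

PLACEMENT_COLUMNS = ["participant_id", "diagram", "role", "x_px", "y_px"]
DEMOGRAPHIC_COLUMNS = ["participant_id", "age", "gender", "romantic_status", "parental_status"]
FLOAT_FORMAT = "%.6f"


@dataclass
class RunConfig:
    """Everything a reproducible run needs: calibrations, thresholds,
    generator settings and the master seed."""

    emotional: DiagramCalibration = field(default_factory=DiagramCalibration.emotional_default)
    physical: DiagramCalibration = field(default_factory=DiagramCalibration.physical_default)
    thresholds: Thresholds = field(default_factory=Thresholds)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    seed: int = 0

    def to_json(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))
        return json.dumps(dataclasses.asdict(self), default=default, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        def tup(d, key):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(tuple(v) if isinstance(v, list) else v for v in d[key])
        emot = raw.get("emotional", {})
        phys = raw.get("physical", {})
        for d in (emot, phys):
            tup(d, "ring_radii")
            tup(d, "ring_miles")
        gen = raw.get("generator", {})
        for key in (
            "age_group_probs", "female_probs", "romantic_probs", "child_probs",
            "hierarchy_mixture", "clear_cut_count_probs",
        ):
            tup(gen, key)
        if "role_band_probs" in gen:
            gen["role_band_probs"] = {k: tuple(v) for k, v in gen["role_band_probs"].items()}
        return cls(
            emotional=DiagramCalibration(**emot) if emot else DiagramCalibration.emotional_default(),
            physical=DiagramCalibration(**phys) if phys else DiagramCalibration.physical_default(),
            thresholds=Thresholds(**raw.get("thresholds", {})),
            generator=GeneratorConfig(**gen) if gen else GeneratorConfig(),
            seed=int(raw.get("seed", 0)),
        )

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def write_placements(records: list[ParticipantRecord], placements_path, demographics_path):
    """Write the standard placement and demographics CSVs for a record set."""
    prows, drows = [], []
    for rec in records:
        drows.append(
            {
                "participant_id": rec.participant_id,
                "age": rec.age,
                "gender": rec.gender,
                "romantic_status": rec.romantic_status,
                "parental_status": rec.parental_status,
            }
        )
        for p in rec.emotional + rec.physical:
            prows.append(
                {
                    "participant_id": rec.participant_id,
                    "diagram": p.diagram,
                    "role": p.role,
                    "x_px": p.x,
                    "y_px": p.y,
                }
            )
    pd.DataFrame(prows, columns=PLACEMENT_COLUMNS).to_csv(
        placements_path, index=False, float_format=FLOAT_FORMAT
    )
    pd.DataFrame(drows, columns=DEMOGRAPHIC_COLUMNS).to_csv(
        demographics_path, index=False, float_format=FLOAT_FORMAT
    )


def read_placements(
    placements_path, demographics_path, allow_underage: bool = False
) -> list[ParticipantRecord]:
    """Parse and validate the placement + demographics CSV pair.

    All invariant violations are collected (with file row numbers for
    duplicates and bad coordinates) and raised together as one
    :class:`ValidationError`.
    """
    problems: list[str] = []
    placements = pd.read_csv(placements_path)
    demographics = pd.read_csv(demographics_path)
    for name, frame, required in (
        ("placements", placements, PLACEMENT_COLUMNS),
        ("demographics", demographics, DEMOGRAPHIC_COLUMNS),
    ):
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValidationError(f"{name} file missing columns: {missing}")

    dup = placements.duplicated(subset=["participant_id", "diagram", "role"], keep=False)
    for idx in placements.index[dup]:
        row = placements.loc[idx]
        problems.append(
            f"row {idx + 2}: duplicate placement "
            f"({row['participant_id']}, {row['diagram']}, {row['role']})"
        )
    coords = placements[["x_px", "y_px"]].apply(pd.to_numeric, errors="coerce")
    for idx in placements.index[coords.isna().any(axis=1)]:
        problems.append(f"row {idx + 2}: non-numeric coordinates")
    if problems:
        raise ValidationError(problems)

    records = []
    demo_by_id = demographics.set_index("participant_id")
    for pid, group in placements.groupby("participant_id", sort=True):
        if pid not in demo_by_id.index:
            problems.append(f"participant {pid}: no demographics row")
            continue
        demo = demo_by_id.loc[pid]
        kwargs = {}
        for kind in ("emotional", "physical"):
            kwargs[kind] = [
                Placement(r["role"], float(r["x_px"]), float(r["y_px"]), kind)
                for _, r in group[group["diagram"] == kind].iterrows()
            ]
        try:
            records.append(
                ParticipantRecord(
                    participant_id=str(pid),
                    age=float(demo["age"]),
                    gender=str(demo["gender"]),
                    romantic_status=str(demo["romantic_status"]),
                    parental_status=str(demo["parental_status"]),
                    allow_underage=allow_underage,
                    **kwargs,
                )
            )
        except ValidationError as err:
            problems.extend(err.problems)
    if problems:
        raise ValidationError(problems)
    return records


def write_report(
    records: list[ParticipantRecord], out_dir, config: RunConfig | None = None
) -> dict:
    """Score records and write the deterministic report file set.

    Emits scores.csv (one row per participant), composition.csv,
    proximity.csv, the three regression tables, correlations.csv, and
    summary.json (counts, class frequencies, config hash).  Running twice
    on the same inputs produces byte-identical files.
    """
    cfg = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scored = score_records(records, cfg.emotional, cfg.physical, cfg.thresholds)
    if len(scored):
        scored = scored.sort_values("participant_id").reset_index(drop=True)
    else:
        scored = pd.DataFrame(columns=["participant_id"])

    def save(frame: pd.DataFrame, name: str):
        frame.to_csv(out / name, index=False, float_format=FLOAT_FORMAT)

    save(scored, "scores.csv")
    if len(records):
        save(composition_table(records, cfg.emotional, cfg.thresholds), "composition.csv")
        save(demographics_table(scored), "demographics.csv")
        save(proximity_table(scored), "proximity.csv")
        corr = correlation_table(scored)
        corr.to_csv(out / "correlations.csv", float_format=FLOAT_FORMAT)
        for name, builder in (
            ("regressions_strength.csv", strength_regressions),
            ("regressions_proximity.csv", proximity_regressions),
            ("regressions_morphology.csv", morphology_regressions),
        ):
            try:
                save(builder(scored), name)
            except Exception as err:  # small n can make any model degenerate
                (out / name).write_text(f"# not estimable: {err}\n")
    else:
        save(pd.DataFrame(columns=["participant_id"]), "scores.csv")

    if len(scored):
        class_freq = (
            scored["hierarchy_class"].value_counts(normalize=True).sort_index().to_dict()
        )
        count_freq = {
            str(k): int(v)
            for k, v in scored["n_clear_cut"].value_counts().sort_index().items()
        }
    else:
        class_freq, count_freq = {}, {}
    summary = {
        "n": len(scored),
        "config_hash": cfg.config_hash(),
        "hierarchy_class_frequencies": {k: round(v, 6) for k, v in class_freq.items()},
        "clear_cut_count_frequencies": count_freq,
        "mean_clear_cut": round(float(scored["n_clear_cut"].mean()), 6) if len(scored) else None,
    }
    (out / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=2) + "\n")
    return summary
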