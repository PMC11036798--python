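"""Configuration-driven parameter sweep over channel angle, width and
bulk velocity.

The sweep runs the solid-disc controls first (per bulk velocity, so that
relative biomass increases are computable), then one row per channel
configuration.  Completed rows are cached as JSON sidecars keyed by a
content hash of their configuration, so an interrupted sweep resumes
without recomputation and a rerun is idempotent.  Individual row
failures are recorded in the results table and do not abort the sweep.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .runner import CaseRunner

RESULTS_SCHEMA_VERSION = 1

COLUMNS = [
    "angle_deg",
    "width_um",
    "U_um_s",
    "channel_v_um_s",
    "Pe_channel",
    "collection_eff_pct",
    "rel_biomass_pct",
    "channel_flux_pct",
    "penetration_um",
    "penetration_full",
    "anoxic_pct",
    "total_biomass",
    "Sh",
    "error",
]


@dataclass
class SweepConfig:
    angles: list = field(default_factory=lambda: [0, 15, 30, 45, 60, 75, 90])
    widths_um: list = field(default_factory=lambda: [200, 300, 400, 500, 600])
    velocities_um_s: list = field(default_factory=lambda: [11.5, 115, 1150])
    include_solid_controls: bool = True
    scale: str = "test"
    out_dir: str | Path | None = None
    seed: int = 0

    def rows(self) -> list[dict]:
        """Planned configurations, solid controls first."""
        out = []
        if self.include_solid_controls:
            for u in self.velocities_um_s:
                out.append({"angle_deg": 0.0, "width_um": 0.0, "U_um_s": float(u)})
        for u in self.velocities_um_s:
            for w in self.widths_um:
                for a in self.angles:
                    out.append(
                        {"angle_deg": float(a), "width_um": float(w), "U_um_s": float(u)}
                    )
        return out


def _row_key(row: dict, config: SweepConfig) -> str:
    payload = json.dumps(
        {**row, "scale": config.scale, "schema": RESULTS_SCHEMA_VERSION},
        sort_keys=True,
    )
    return hashlib.sha1(payload.encode()).hexdigest()[:16]


def run_sweep(config: SweepConfig, runner: CaseRunner | None = None) -> pd.DataFrame:
    """Execute the sweep and return the results table (also written to
    ``results.csv`` under ``config.out_dir`` when given)."""
    runner = runner or CaseRunner(scale=config.scale)
    cache = None
    if config.out_dir is not None:
        cache = Path(config.out_dir) / "rows"
        cache.mkdir(parents=True, exist_ok=True)

    records = []
    for row in config.rows():
        key = _row_key(row, config)
        side = cache / f"{key}.json" if cache is not None else None
        if side is not None and side.exists():
            records.append(json.loads(side.read_text()))
            continue
        rec = dict(row)
        try:
            rec.update(
                runner.metrics_row(
                    row["width_um"], row["angle_deg"], row["U_um_s"], sherwood=True
                )
            )
            rec["error"] = ""
        except Exception as exc:  # row failures are data, not crashes
            rec["error"] = f"{type(exc).__name__}: {exc}"
        if side is not None:
            side.write_text(json.dumps(rec))
        records.append(rec)

    df = pd.DataFrame.from_records(records)
    for col in COLUMNS:
        if col not in df.columns:
            df[col] = float("nan")
    df = df[COLUMNS]
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "results.csv", index=False)
        (out / "schema.json").write_text(
            json.dumps({"version": RESULTS_SCHEMA_VERSION, "columns": COLUMNS})
        )
    return df
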