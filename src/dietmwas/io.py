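"""Delimited-text I/O for every table the pipeline consumes or emits.

All tables are tab-separated with a header row; missing values are empty
fields.  Metabolite panels carry a JSON sidecar (same path plus ``.json``)
recording platform, processing state and warnings.  Floats are written with
15 significant digits so a write/read round trip is lossless at that
precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .panels import MetabolitePanel

FLOAT_FMT = "%.15g"

__all__ = [
    "write_table",
    "read_table",
    "write_panel",
    "read_panel",
    "write_records",
]


def write_table(df: pd.DataFrame, path: str | Path, index_label: str = "subject_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format=FLOAT_FMT)


def read_table(path: str | Path, index_col: int | str = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_panel(panel: MetabolitePanel, path: str | Path) -> None:
    """Panel TSV: subject id, run day, then one column per metabolite."""
    path = Path(path)
    out = panel.values.copy()
    if panel.run_day is not None:
        out.insert(0, "run_day", panel.run_day)
    out.to_csv(path, sep="\t", index_label="subject_id", float_format=FLOAT_FMT)
    sidecar = {
        "platform": panel.platform,
        "steps": panel.steps,
        "warnings": panel.warnings,
        "n_subjects": int(len(panel.subjects)),
        "n_metabolites": int(len(panel.metabolites)),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_panel(path: str | Path, platform: str | None = None) -> MetabolitePanel:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col="subject_id")
    run_day = None
    if "run_day" in df.columns:
        run_day = df.pop("run_day")
    steps: list[str] = []
    warnings: list[str] = []
    sidecar_path = Path(str(path) + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        platform = platform or sidecar["platform"]
        steps = sidecar.get("steps", [])
        warnings = sidecar.get("warnings", [])
    if platform is None:
        raise ValueError("platform not given and no sidecar found")
    return MetabolitePanel(values=df.astype(float), platform=platform,
                           run_day=run_day, steps=steps, warnings=warnings)


def write_records(df: pd.DataFrame, path: str | Path) -> None:
    """Association/meta/SNP record tables: no index column."""
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
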