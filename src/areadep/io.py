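"""CSV schemas, configuration loading and result writing.

All tables are plain UTF-8 CSV with required headers and "." decimals.
``area_id``, ``legacy_id`` and ``parent_id`` are opaque text — administrative
codes must never be numerically coerced (leading zeros matter).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import SchemaError
from .indicators import FacilitySet
from .synthetic import AGE_BANDS, SyntheticBundle

AREA_COLUMNS = (
    "area_id",
    "pop_total",
    "pop_working_age",
    "pop_youth",
    "school_leavers",
    *AGE_BANDS,
    "urban_rural",
    "parent_id",
    "x",
    "y",
)

_ID_COLUMNS = {"area_id", "legacy_id", "parent_id", "urban_rural", "category"}

FILENAMES = {
    "areas": "areas.csv",
    "indicators": "indicators.csv",
    "crosswalk": "crosswalk.csv",
    "facilities": "facilities.csv",
    "outcomes": "outcomes.csv",
    "reference_rates": "reference_rates.csv",
}


@dataclass
class PipelineConfig:
    """Resolved run configuration (paths, profile, weights, anchors, seed)."""

    data_dir: Path
    output_dir: Path
    profile: str = "nz2013"
    exclusions: tuple[str, ...] = ()
    seed: int = 0
    transform_anchors: dict = field(default_factory=dict)
    domain_weights: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(
            data_dir=Path(raw["data_dir"]),
            output_dir=Path(raw.get("output_dir", "results")),
            profile=raw.get("profile", "nz2013"),
            exclusions=tuple(raw.get("exclusions", ())),
            seed=int(raw.get("seed", 0)),
            transform_anchors=dict(raw.get("transform_anchors", {})),
            domain_weights=dict(raw.get("domain_weights", {})),
        )
        if not cfg.data_dir.exists():
            raise SchemaError([f"data_dir does not exist: {cfg.data_dir}"])
        return cfg

    def digest(self) -> str:
        payload = json.dumps(
            {
                "profile": self.profile,
                "exclusions": list(self.exclusions),
                "seed": self.seed,
                "transform_anchors": self.transform_anchors,
                "domain_weights": self.domain_weights,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _read_csv(path: Path) -> pd.DataFrame:
    dtype = {c: str for c in _ID_COLUMNS}
    return pd.read_csv(path, dtype=dtype)


def write_bundle(bundle: SyntheticBundle, directory: str | Path) -> None:
    """Write a synthetic bundle as the five input CSVs plus reference rates."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    bundle.areas.to_csv(d / FILENAMES["areas"], index=False)
    bundle.indicator_numerators.rename_axis("area_id").to_csv(d / FILENAMES["indicators"])
    bundle.crosswalk.to_csv(d / FILENAMES["crosswalk"], index=False)
    bundle.facilities.to_frame().to_csv(d / FILENAMES["facilities"], index=False)
    bundle.outcomes.rename_axis("area_id").to_csv(d / FILENAMES["outcomes"])
    bundle.reference_rates.rename_axis("age_band").rename("rate").to_csv(
        d / FILENAMES["reference_rates"]
    )
    bundle.latent.rename_axis("area_id").to_csv(d / "latent.csv")


def read_tables(directory: str | Path) -> dict:
    """Load and validate every input table; schema problems are aggregated.

    Returns a dict with keys ``areas``, ``indicators``, ``crosswalk``,
    ``facilities``, ``outcomes`` and ``reference_rates``. Every violation
    found (missing file, missing column, duplicate area_id, non-numeric
    cell) is reported together in one :class:`SchemaError`.
    """
    d = Path(directory)
    problems: list[str] = []
    tables: dict = {}
    for key, fname in FILENAMES.items():
        path = d / fname
        if not path.exists():
            if key in ("outcomes", "reference_rates"):
                tables[key] = None
                continue
            problems.append(f"missing file {fname}")
            continue
        try:
            tables[key] = _read_csv(path)
        except Exception as exc:  # malformed CSV
            problems.append(f"{fname}: unreadable ({exc})")

    areas = tables.get("areas")
    if isinstance(areas, pd.DataFrame):
        missing = [c for c in AREA_COLUMNS if c not in areas.columns]
        if missing:
            problems.append(f"areas.csv: missing columns {missing}")
        if "area_id" in areas.columns:
            dupes = areas.loc[areas["area_id"].duplicated(), "area_id"].tolist()
            if dupes:
                problems.append(f"areas.csv: duplicate area_id {dupes[:10]}")
        numeric = [c for c in AREA_COLUMNS if c in areas.columns and c not in _ID_COLUMNS]
        for c in numeric:
            if not pd.api.types.is_numeric_dtype(areas[c]):
                problems.append(f"areas.csv: non-numeric column {c}")

    ind = tables.get("indicators")
    if isinstance(ind, pd.DataFrame):
        if "area_id" not in ind.columns:
            problems.append("indicators.csv: missing column area_id")
        else:
            bad = [c for c in ind.columns if c != "area_id" and not pd.api.types.is_numeric_dtype(ind[c])]
            if bad:
                problems.append(f"indicators.csv: non-numeric columns {bad}")
            dupes = ind.loc[ind["area_id"].duplicated(), "area_id"].tolist()
            if dupes:
                problems.append(f"indicators.csv: duplicate area_id {dupes[:10]}")

    cw = tables.get("crosswalk")
    if isinstance(cw, pd.DataFrame):
        missing = [c for c in ("legacy_id", "area_id", "share") if c not in cw.columns]
        if missing:
            problems.append(f"crosswalk.csv: missing columns {missing}")

    fac = tables.get("facilities")
    if isinstance(fac, pd.DataFrame):
        missing = [c for c in ("category", "x", "y") if c not in fac.columns]
        if missing:
            problems.append(f"facilities.csv: missing columns {missing}")
        else:
            tables["facilities"] = FacilitySet.from_frame(fac)

    if problems:
        raise SchemaError(problems)

    for key in ("indicators", "outcomes"):
        if isinstance(tables.get(key), pd.DataFrame):
            tables[key] = tables[key].set_index("area_id")
    rr = tables.get("reference_rates")
    if isinstance(rr, pd.DataFrame):
        tables["reference_rates"] = rr.set_index("age_band")["rate"]
    return tables


def write_results(result, directory: str | Path, metadata: dict | None = None) -> Path:
    """Write results.csv (scores, ranks, quantiles per area) and metadata.json."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    out = d / "results.csv"
    result.table.rename_axis("area_id").to_csv(out, float_format="%.10g")
    meta = {
        "n": result.n,
        "k": result.k,
        "weights": {k: float(v) for k, v in result.weights.items()},
        "transform": {
            "top_score": result.transform.top_score,
            "mid_score": result.transform.mid_score,
            "upper_tail": result.transform.upper_tail,
        },
        "indicator_weights": {
            dom: (None if w is None else {k: float(v) for k, v in w.items()})
            for dom, w in result.domain_weights_used.items()
        },
    }
    if metadata:
        meta.update(metadata)
    (d / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return out
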