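"""File formats, configuration and the end-to-end pipeline.

Interchange formats (all versioned plain text):

* contour-stack JSON — header (subject, slice geometry) plus a flat contour
  list; the schema ships with the package under ``eatq/schemas/``;
* contour-stack long CSV — one vertex per row, header fields repeated per
  row, read/written with pandas;
* cohort CSV — one subject per row, primitives plus derived columns;
* analysis-plan and results JSON for the statistics layer.

Absent measurements are explicit nulls end to end, never zeros: a subject
without a scar tracing has no LGE extent rather than an extent of 0.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import indices
from .geometry import (
    FAT_DENSITY_G_PER_ML,
    MYOCARDIAL_DENSITY_G_PER_ML,
    PHASES,
    ROLES,
    STRUCTURES,
    Contour,
    ContourStack,
    ContourValidationError,
    EmptyMeasurementError,
    stack_volume,
    volume_to_mass,
)
from .stats import DEFAULT_ALPHA, DEFAULT_LIMIT_FACTOR, two_group_compare, simple_regression

__all__ = [
    "FORMAT_VERSION",
    "AnalysisConfig",
    "read_contour_stack",
    "write_contour_stack",
    "read_contour_stack_csv",
    "write_contour_stack_csv",
    "read_cohort",
    "write_cohort",
    "quantify_stack",
    "run_pipeline",
]

FORMAT_VERSION = "1.0"

#: variables summarised group-wise by the default analysis plan
REPORT_VARIABLES = (
    "lv_ef", "lv_edm", "indexed_lv_edm", "lv_esv", "lv_edv", "lv_edd",
    "lvri", "rv_ef", "rv_esv", "rv_edv",
    "eat_volume", "indexed_eat_volume", "eat_mass", "indexed_eat_mass",
    "eat_lvm_ratio",
)


@dataclass
class AnalysisConfig:
    """Constants and knobs used throughout a pipeline run.

    The defaults are the study conventions: fat density 0.92 g/ml,
    myocardial density 1.05 g/ml, agreement limits at 1.96 SD and a 0.05
    significance level.
    """

    fat_density_g_per_ml: float = FAT_DENSITY_G_PER_ML
    myocardial_density_g_per_ml: float = MYOCARDIAL_DENSITY_G_PER_ML
    limit_factor: float = DEFAULT_LIMIT_FACTOR
    alpha: float = DEFAULT_ALPHA
    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fat_density_g_per_ml <= 0 or self.myocardial_density_g_per_ml <= 0:
            raise ValueError("densities must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.limit_factor <= 0:
            raise ValueError("limit factor must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        return cls(**json.loads(Path(path).read_text()))


# --- contour-stack JSON ----------------------------------------------------

def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ContourValidationError(msg)


def _stack_from_document(doc: dict[str, Any]) -> ContourStack:
    _require(isinstance(doc, dict), "document root must be an object")
    for key in ("subject_id", "slice_thickness_mm", "inter_slice_gap_mm", "n_slices", "contours"):
        _require(key in doc, f"missing required field {key!r}")
    version = doc.get("format_version", FORMAT_VERSION)
    _require(str(version) == FORMAT_VERSION, f"unsupported format_version {version!r}")
    contours = []
    for i, c in enumerate(doc["contours"]):
        for key in ("slice_index", "phase", "structure", "points"):
            _require(key in c, f"contour #{i}: missing field {key!r}")
        _require(c["phase"] in PHASES, f"contour #{i}: unknown phase {c['phase']!r}")
        _require(
            c["structure"] in STRUCTURES, f"contour #{i}: unknown structure {c['structure']!r}"
        )
        role = c.get("role", "outer")
        _require(role in ROLES, f"contour #{i}: unknown role {role!r}")
        contours.append(
            Contour(
                points=np.asarray(c["points"], dtype=float),
                slice_index=int(c["slice_index"]),
                phase=c["phase"],
                structure=c["structure"],
                role=role,
            )
        )
    return ContourStack(
        contours=contours,
        slice_thickness_mm=float(doc["slice_thickness_mm"]),
        inter_slice_gap_mm=float(doc["inter_slice_gap_mm"]),
        n_slices=int(doc["n_slices"]),
        subject_id=str(doc["subject_id"]),
    )


def _stack_to_document(stack: ContourStack) -> dict[str, Any]:
    return {
        "format_version": FORMAT_VERSION,
        "subject_id": stack.subject_id,
        "slice_thickness_mm": stack.slice_thickness_mm,
        "inter_slice_gap_mm": stack.inter_slice_gap_mm,
        "n_slices": stack.n_slices,
        "contours": [
            {
                "slice_index": c.slice_index,
                "phase": c.phase,
                "structure": c.structure,
                "role": c.role,
                "points": [[float(x), float(y)] for x, y in c.points],
            }
            for c in stack.contours
        ],
    }


def read_contour_stack(path: str | Path) -> ContourStack:
    """Load and fully validate a contour-stack JSON file."""
    return _stack_from_document(json.loads(Path(path).read_text()))


def write_contour_stack(stack: ContourStack, path: str | Path) -> None:
    """Write a contour stack as versioned JSON (stable key order)."""
    Path(path).write_text(json.dumps(_stack_to_document(stack), sort_keys=True))


_CSV_COLUMNS = [
    "subject_id", "slice_thickness_mm", "inter_slice_gap_mm", "n_slices",
    "contour_id", "slice_index", "phase", "structure", "role",
    "vertex_index", "x_mm", "y_mm",
]


def write_contour_stack_csv(stack: ContourStack, path: str | Path) -> None:
    """Write the long-format CSV encoding: one vertex per row."""
    rows = []
    for cid, c in enumerate(stack.contours):
        for vi, (x, y) in enumerate(c.points):
            rows.append(
                (
                    stack.subject_id, stack.slice_thickness_mm, stack.inter_slice_gap_mm,
                    stack.n_slices, cid, c.slice_index, c.phase, c.structure, c.role,
                    vi, float(x), float(y),
                )
            )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_contour_stack_csv(path: str | Path) -> ContourStack:
    """Read the long-format CSV encoding back into a validated stack."""
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    _require(not missing, f"CSV missing columns {sorted(missing)}")
    header = df.iloc[0]
    contours = []
    for _, grp in df.sort_values(["contour_id", "vertex_index"]).groupby("contour_id"):
        first = grp.iloc[0]
        contours.append(
            Contour(
                points=grp[["x_mm", "y_mm"]].to_numpy(dtype=float),
                slice_index=int(first["slice_index"]),
                phase=str(first["phase"]),
                structure=str(first["structure"]),
                role=str(first["role"]),
            )
        )
    return ContourStack(
        contours=contours,
        slice_thickness_mm=float(header["slice_thickness_mm"]),
        inter_slice_gap_mm=float(header["inter_slice_gap_mm"]),
        n_slices=int(header["n_slices"]),
        subject_id=str(header["subject_id"]),
    )


# --- cohort CSV ------------------------------------------------------------

def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# --- measurement + analysis pipeline --------------------------------------

def quantify_stack(
    stack: ContourStack, config: AnalysisConfig | None = None
) -> tuple[dict[str, Any], list[dict[str, Any]]]:
    """Measure every structure present in one stack.

    Returns a per-subject record (volumes, masses, EF where both phases of
    the cavity are traced) and an audit log listing each operation with the
    constants it used.  Structures without contours are reported as absent
    (``None``), never zero.
    """
    config = config or AnalysisConfig()
    record: dict[str, Any] = {"subject_id": stack.subject_id}
    log: list[dict[str, Any]] = []

    def measure(structure: str, phase: str) -> float | None:
        try:
            res = stack_volume(stack, structure, phase)
        except EmptyMeasurementError:
            return None
        log.append(
            {
                "op": "stack_volume",
                "structure": structure,
                "phase": phase,
                "slice_spacing_mm": stack.slice_spacing_mm,
                "value_ml": res.volume_ml,
            }
        )
        return res.volume_ml

    lv_edv = measure("lv_endo", "end_diastole")
    lv_esv = measure("lv_endo", "end_systole")
    epi_ed = measure("lv_epi", "end_diastole")
    eat_vol = measure("eat", "end_diastole")
    lge_vol = measure("lge", "end_diastole")

    record["lv_edv_ml"] = lv_edv
    record["lv_esv_ml"] = lv_esv
    record["eat_volume_ml"] = eat_vol
    if eat_vol is not None:
        record["eat_mass_g"] = volume_to_mass(eat_vol, config.fat_density_g_per_ml)
        log.append(
            {
                "op": "volume_to_mass",
                "structure": "eat",
                "density_g_per_ml": config.fat_density_g_per_ml,
                "value_g": record["eat_mass_g"],
            }
        )
    else:
        record["eat_mass_g"] = None
    if epi_ed is not None and lv_edv is not None:
        wall_ml = epi_ed - lv_edv
        record["lv_edm_g"] = volume_to_mass(wall_ml, config.myocardial_density_g_per_ml)
        log.append(
            {
                "op": "volume_to_mass",
                "structure": "lv_wall",
                "density_g_per_ml": config.myocardial_density_g_per_ml,
                "value_g": record["lv_edm_g"],
            }
        )
    else:
        record["lv_edm_g"] = None
    if lv_edv is not None and lv_esv is not None:
        record["lv_ef_pct"] = indices.ejection_fraction(lv_edv, lv_esv)
        record["lv_sv_ml"] = indices.stroke_volume(lv_edv, lv_esv)
        log.append({"op": "ejection_fraction", "value_pct": record["lv_ef_pct"]})
    else:
        record["lv_ef_pct"] = None
        record["lv_sv_ml"] = None
    if record["lv_edm_g"] is not None and lv_edv is not None:
        record["lvri_g_per_ml"] = indices.lvri(record["lv_edm_g"], lv_edv)
    else:
        record["lvri_g_per_ml"] = None
    if lge_vol is not None and record["lv_edm_g"] is not None:
        lge_mass = volume_to_mass(lge_vol, config.myocardial_density_g_per_ml)
        record["lge_mass_g"] = lge_mass
        record["lge_extent_pct"] = indices.lge_extent(lge_mass, record["lv_edm_g"])
    else:
        record["lge_mass_g"] = None
        record["lge_extent_pct"] = None
    return record, log


def _default_plan(cohort: pd.DataFrame) -> dict[str, Any]:
    groups = sorted(cohort["group"].unique())
    chf_groups = [g for g in groups if g != "control"]
    comparisons = []
    if "control" in groups and chf_groups:
        comparisons = [
            {"variable": v, "groups": ["control", "chf"], "test": "students_t"}
            for v in REPORT_VARIABLES
            if v in cohort.columns
        ]
    return {"comparisons": comparisons, "regressions": []}


def run_pipeline(
    config: AnalysisConfig,
    stacks: list[ContourStack] | None = None,
    cohort: pd.DataFrame | None = None,
    plan: dict[str, Any] | None = None,
) -> dict[str, Any]:
    """Run measurement and/or cohort analysis and return the report bundle.

    Per-subject measurement failures are isolated: the offending subject is
    listed under ``errors`` and the run continues.  The bundle embeds the
    configuration and an audit log tracing every reported number to the
    operation and constants that produced it.
    """
    bundle: dict[str, Any] = {
        "format_version": FORMAT_VERSION,
        "config": dataclasses.asdict(config),
        "log": [],
        "errors": [],
    }
    if stacks:
        records = []
        for stack in stacks:
            try:
                record, log = quantify_stack(stack, config)
                records.append(record)
                bundle["log"].extend(
                    [{"subject_id": stack.subject_id, **entry} for entry in log]
                )
            except ContourValidationError as exc:
                bundle["errors"].append({"subject_id": stack.subject_id, "error": str(exc)})
        bundle["subjects"] = pd.DataFrame(records)
    if cohort is not None:
        plan = plan or _default_plan(cohort)
        is_chf = cohort["group"] != "control"
        comparisons = []
        for spec in plan.get("comparisons", []):
            var = spec["variable"]
            ga, gb = spec["groups"]
            sel_a = ~is_chf if ga == "control" else cohort["group"] == ga
            sel_b = is_chf if gb == "chf" else cohort["group"] == gb
            a = cohort.loc[sel_a, var].dropna()
            b = cohort.loc[sel_b, var].dropna()
            res = two_group_compare(a, b, spec.get("test", "students_t"))
            comparisons.append(
                {
                    "variable": var,
                    "groups": [ga, gb],
                    "test": res.test_name,
                    "mean_a": res.group_summaries["a"]["mean"],
                    "sd_a": res.group_summaries["a"]["sd"],
                    "n_a": res.group_summaries["a"]["n"],
                    "mean_b": res.group_summaries["b"]["mean"],
                    "sd_b": res.group_summaries["b"]["sd"],
                    "n_b": res.group_summaries["b"]["n"],
                    "p_value": res.p_value,
                    "significant": bool(res.p_value < config.alpha),
                }
            )
            bundle["log"].append({"op": "two_group_compare", "variable": var, "p": res.p_value})
        regressions = []
        for spec in plan.get("regressions", []):
            grp = spec.get("group", "all")
            if grp == "all":
                sub = cohort
            elif grp == "chf":
                sub = cohort[is_chf]
            else:
                sub = cohort[cohort["group"] == grp]
            data = sub[[spec["x"], spec["y"]]].dropna()
            res = simple_regression(data[spec["x"]], data[spec["y"]])
            regressions.append(
                {
                    "x": spec["x"],
                    "y": spec["y"],
                    "group": spec.get("group", "all"),
                    "slope": res.slope,
                    "intercept": res.intercept,
                    "r": res.r,
                    "p_value": res.p_value,
                    "n": res.n,
                }
            )
            bundle["log"].append(
                {"op": "simple_regression", "x": spec["x"], "y": spec["y"], "r": res.r}
            )
        bundle["comparisons"] = comparisons
        bundle["regressions"] = regressions
    return bundle


def format_report(bundle: dict[str, Any]) -> str:
    """Render the comparison section of a bundle as an aligned text table."""
    lines = []
    comparisons = bundle.get("comparisons", [])
    if comparisons:
        ga, gb = comparisons[0]["groups"]
        lines.append(f"{'variable':<22}{ga + ' (mean±SD)':>20}{gb + ' (mean±SD)':>20}{'p':>10}")
        for c in comparisons:
            p = "<0.0001" if c["p_value"] < 1e-4 else f"{c['p_value']:.4g}"
            lines.append(
                f"{c['variable']:<22}"
                f"{c['mean_a']:>12.2f} ± {c['sd_a']:<6.2f}"
                f"{c['mean_b']:>11.2f} ± {c['sd_b']:<6.2f}"
                f"{p:>10}"
            )
    for r in bundle.get("regressions", []):
        lines.append(
            f"regression {r['y']} ~ {r['x']} [{r['group']}]: "
            f"r = {r['r']:.2f}, p = {r['p_value']:.4g}, n = {r['n']}"
        )
    return "\n".join(lines)
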