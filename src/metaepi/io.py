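"""Reading, validation and serialization of pipeline datasets.

The study-level table is delimited text with one row per experimental
arm. Effect sizes are resolved in a fixed precedence order: an explicit
``var`` column wins over a confidence interval (``ci_low``/``ci_high``),
which wins over arm-level summaries (``mean_t, sd_t, n_t, mean_c, sd_c,
n_c``). Validation collects every violation into a structured report
rather than failing on the first; rating values are case-normalized.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .effect_sizes import ArmSummary, compute_smd, smd_from_ci
from .exceptions import MetaEpiError, ValidationError
from .pipeline import CHARACTERISTICS, RunConfig

__all__ = ["Dataset", "validate_dataset", "write_results", "load_config"]

_RATING_ALIASES = {
    "low": "low",
    "high": "high",
    "unclear": "unclear",
    "not_assessed": "not_assessed",
    "na": "not_assessed",
    "nan": "not_assessed",
    "": "not_assessed",
    "none": "not_assessed",
}

_ARM_COLS = ["mean_t", "sd_t", "n_t", "mean_c", "sd_c", "n_c"]


@dataclass
class Dataset:
    """A validated pair of tables plus provenance and the validation
    report (violations with row/column/rule, warnings, normalizations)."""

    studies: pd.DataFrame
    mas: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    report: list[dict] = field(default_factory=list)

    @property
    def violations(self) -> list[dict]:
        return [r for r in self.report if r.get("severity") == "error"]

    @property
    def valid(self) -> bool:
        return not self.violations


def _resolve_effect(row: pd.Series, idx, report: list[dict]) -> tuple[float, float]:
    """Resolve (smd, var) for one row by the precedence rule."""
    has_var = pd.notna(row.get("var"))
    has_ci = pd.notna(row.get("ci_low")) and pd.notna(row.get("ci_high"))
    has_arms = all(pd.notna(row.get(c)) for c in _ARM_COLS)
    has_smd = pd.notna(row.get("smd"))

    if has_var:
        if has_ci:
            report.append(
                {"severity": "warning", "row": idx, "column": "ci_low",
                 "rule": "var_and_ci_both_present_ci_ignored"}
            )
        if not has_smd:
            raise ValidationError("var given without smd")
        return float(row["smd"]), float(row["var"])
    if has_ci:
        if not has_smd:
            raise ValidationError("ci given without smd")
        eff = smd_from_ci(
            float(row["smd"]), float(row["ci_low"]), float(row["ci_high"])
        )
        return eff.smd, eff.variance
    if has_arms:
        eff = compute_smd(
            ArmSummary(
                mean_treated=float(row["mean_t"]),
                sd_treated=float(row["sd_t"]),
                n_treated=int(row["n_t"]),
                mean_control=float(row["mean_c"]),
                sd_control=float(row["sd_c"]),
                n_control=int(row["n_c"]),
            )
        )
        return eff.smd, eff.variance
    raise ValidationError(
        "row carries none of {var}, {ci_low, ci_high}, {arm summaries}"
    )


def validate_dataset(studies_path, mas_path, sep: str = ",") -> Dataset:
    """Read and validate the study- and meta-analysis-level tables.

    Violations (orphan ``ma_id``, duplicate keys, unresolvable effect
    sizes, non-positive variances, unknown rating values) are collected
    into ``Dataset.report``; the input files are never modified. An
    empty valid file yields an empty Dataset.
    """
    studies_path, mas_path = Path(studies_path), Path(mas_path)
    report: list[dict] = []
    studies = pd.read_csv(studies_path, sep=sep)
    mas = pd.read_csv(mas_path, sep=sep)

    for col in ("ma_id", "study_id", "arm_id"):
        if col not in studies.columns and len(studies):
            report.append(
                {"severity": "error", "row": None, "column": col,
                 "rule": "missing_required_column"}
            )
    if "ma_id" not in mas.columns and len(mas):
        report.append(
            {"severity": "error", "row": None, "column": "ma_id",
             "rule": "missing_required_column"}
        )
    if [r for r in report if r["severity"] == "error"]:
        return Dataset(studies, mas, report=report,
                       provenance={"studies": str(studies_path),
                                   "mas": str(mas_path)})

    # effect-size resolution
    smds, variances = [], []
    for idx, row in studies.iterrows():
        try:
            smd, var = _resolve_effect(row, idx, report)
        except MetaEpiError as err:
            report.append(
                {"severity": "error", "row": int(idx), "column": "smd",
                 "rule": f"effect_resolution_failed: {err}"}
            )
            smd, var = np.nan, np.nan
        if not np.isnan(var) and var <= 0:
            report.append(
                {"severity": "error", "row": int(idx), "column": "var",
                 "rule": "non_positive_variance"}
            )
        smds.append(smd)
        variances.append(var)
    if len(studies):
        studies = studies.copy()
        studies["smd"] = smds
        studies["var"] = variances

    # rating normalization
    for c in CHARACTERISTICS:
        col = f"rob_{c}"
        if col not in studies.columns:
            continue
        orig = studies[col].astype("string")
        raw = orig.str.strip().str.lower()
        normalized = raw.fillna("not_assessed").map(
            lambda x: _RATING_ALIASES.get(x)
        )
        bad = normalized.isna()
        for idx in studies.index[bad]:
            report.append(
                {"severity": "error", "row": int(idx), "column": col,
                 "rule": f"unknown_rating_value: {studies.at[idx, col]!r}"}
            )
        changed = (orig.fillna("not_assessed") != normalized) & ~bad
        for idx in studies.index[changed]:
            report.append(
                {"severity": "warning", "row": int(idx), "column": col,
                 "rule": "rating_value_normalized"}
            )
        studies[col] = normalized.fillna("not_assessed")

    # referential integrity and key uniqueness
    if len(studies) and len(mas):
        known = set(mas["ma_id"])
        for idx in studies.index[~studies["ma_id"].isin(known)]:
            report.append(
                {"severity": "error", "row": int(idx), "column": "ma_id",
                 "rule": "orphan_ma_id"}
            )
    if len(studies):
        dup = studies.duplicated(subset=["ma_id", "study_id", "arm_id"],
                                 keep="first")
        for idx in studies.index[dup]:
            report.append(
                {"severity": "error", "row": int(idx), "column": "arm_id",
                 "rule": "duplicate_key"}
            )

    return Dataset(
        studies=studies,
        mas=mas,
        provenance={
            "studies": str(studies_path),
            "mas": str(mas_path),
            "schema_version": 1,
        },
        report=report,
    )


def write_results(results, out_dir, config: RunConfig | None = None) -> dict:
    """Write a fitted :class:`~metaepi.model.MetaEpiResults` to disk.

    Produces ``metaepi_results.csv`` (one row per characteristic,
    skipped ones included with their reason), ``dmsd_per_ma.csv`` and
    ``run_log.json`` (config echo, exclusion log, package version).
    Output is byte-identical across runs with identical inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = results.to_frame()
    frame.to_csv(out_dir / "metaepi_results.csv", index=False)
    results.per_ma_frame().to_csv(out_dir / "dmsd_per_ma.csv", index=False)
    config = config or getattr(results.model, "config", RunConfig())
    log = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "robust": results.robust,
        "exclusions": [
            {"characteristic": r.characteristic, **e}
            for r in results.results
            for e in r.exclusions
        ],
        "skipped": {
            r.characteristic: r.skip_reason
            for r in results.results if r.skipped
        },
    }
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return {
        "results": str(out_dir / "metaepi_results.csv"),
        "per_ma": str(out_dir / "dmsd_per_ma.csv"),
        "log": str(out_dir / "run_log.json"),
    }


def load_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from a TOML file; unknown keys are
    rejected."""
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
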