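"""Reading, writing and pipeline plumbing for germination study tables.

The on-disk format is a long-format CSV with header
``replicate_id,temperature_C,psi_MPa,time_d,cum_germinated,n_seeds`` (one
row per dish x observation, decimal point '.').  Seedling measures travel in
a second CSV ``replicate_id,temperature_C,psi_MPa,radicle_cm,plumule_cm,
dryweight_g``.  Water potentials are stored as signed MPa (<= 0); a file
using unsigned tension values is accepted only under ``assume_tension=True``
(the sign is flipped with a warning), otherwise rejected.
"""
from __future__ import annotations

import io as _io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .metrics import index_report
from .models import fit_hydrotime_probit, fit_htt, fit_thermal, table1_grid
from .timecourse import FitFailureError, GerminationTimeCourse, SeedlingMeasures

log = logging.getLogger("httime")

STUDY_COLUMNS = [
    "replicate_id", "temperature_C", "psi_MPa", "time_d", "cum_germinated", "n_seeds",
]
SEEDLING_COLUMNS = [
    "replicate_id", "temperature_C", "psi_MPa", "radicle_cm", "plumule_cm", "dryweight_g",
]


@dataclass
class StudyTable:
    """Collection of time courses keyed by (temperature, psi, replicate_id)."""

    courses: dict[tuple[float, float, str], GerminationTimeCourse] = field(
        default_factory=dict
    )
    seedlings: dict[tuple[float, float, str], SeedlingMeasures] = field(
        default_factory=dict
    )

    def add(self, tc: GerminationTimeCourse) -> None:
        key = (tc.temperature, tc.water_potential, tc.replicate_id)
        if key in self.courses:
            raise ValueError(f"duplicate course for {key}")
        self.courses[key] = tc

    def all_courses(self) -> list[GerminationTimeCourse]:
        return list(self.courses.values())

    def __len__(self) -> int:
        return len(self.courses)

    @classmethod
    def from_courses(cls, courses: Sequence[GerminationTimeCourse]) -> "StudyTable":
        table = cls()
        for tc in courses:
            table.add(tc)
        return table


def _fmt(x: float) -> str:
    """Canonical number formatting: shortest exact decimal via repr."""
    if x == int(x):
        return str(int(x))
    return repr(float(x))


def study_to_csv_text(study: StudyTable) -> str:
    """Serialise to the canonical CSV byte layout (stable row order/format)."""
    buf = _io.StringIO()
    buf.write(",".join(STUDY_COLUMNS) + "\n")
    for (T, psi, rep) in sorted(study.courses, key=lambda k: (k[0], -k[1], k[2])):
        tc = study.courses[(T, psi, rep)]
        for t, c in zip(tc.times, tc.cumulative_counts):
            buf.write(
                f"{rep},{_fmt(T)},{_fmt(psi)},{_fmt(t)},{c},{tc.n_seeds}\n"
            )
    return buf.getvalue()


def write_study(study: StudyTable, path: str | Path) -> None:
    Path(path).write_text(study_to_csv_text(study))


def read_study(
    path: str | Path, units: str = "days", assume_tension: bool = False
) -> StudyTable:
    """Load and validate a study CSV.

    ``units`` declares the time column's unit ("days" or "hours"; hours are
    converted to days on load).  Malformed rows are reported with their
    1-based line numbers.
    """
    if units not in ("days", "hours"):
        raise ValueError("units must be 'days' or 'hours'")
    df = pd.read_csv(path)
    missing = [c for c in STUDY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    df = df.copy()
    df["_line"] = df.index + 2  # header is line 1

    pos = df["psi_MPa"] > 0
    if pos.any():
        if assume_tension:
            warnings.warn(
                f"{int(pos.sum())} positive psi_MPa values interpreted as tension "
                "and sign-flipped",
                stacklevel=2,
            )
            df.loc[pos, "psi_MPa"] *= -1
        else:
            bad = df.loc[pos, "_line"].tolist()
            raise ValueError(
                f"positive psi_MPa on lines {bad}; pass assume_tension=True to flip"
            )

    if units == "hours":
        df["time_d"] = df["time_d"] / 24.0

    problems = []
    study = StudyTable()
    for (rep, T, psi), grp in df.groupby(
        ["replicate_id", "temperature_C", "psi_MPa"], sort=False
    ):
        grp = grp.sort_values("time_d")
        over = grp[grp["cum_germinated"] > grp["n_seeds"]]
        for _, r in over.iterrows():
            problems.append(
                f"line {int(r['_line'])}: cum_germinated {int(r['cum_germinated'])} "
                f"> n_seeds {int(r['n_seeds'])}"
            )
        counts = grp["cum_germinated"].to_numpy()
        if (counts[1:] < counts[:-1]).any():
            problems.append(
                f"non-monotone cumulative counts for replicate {rep} at "
                f"T={T}, psi={psi} (lines {grp['_line'].tolist()})"
            )
        if problems:
            continue
        study.add(
            GerminationTimeCourse(
                temperature=float(T),
                water_potential=float(psi),
                times=tuple(grp["time_d"]),
                cumulative_counts=tuple(int(c) for c in counts),
                n_seeds=int(grp["n_seeds"].iloc[0]),
                replicate_id=str(rep),
            )
        )
    if problems:
        raise ValueError("invalid study file:\n" + "\n".join(problems))
    return study


def read_seedlings(path: str | Path) -> dict[tuple[float, float, str], SeedlingMeasures]:
    df = pd.read_csv(path)
    missing = [c for c in SEEDLING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    out = {}
    for _, r in df.iterrows():
        out[(float(r["temperature_C"]), float(r["psi_MPa"]), str(r["replicate_id"]))] = (
            SeedlingMeasures(
                radicle_length=float(r["radicle_cm"]),
                plumule_length=float(r["plumule_cm"]),
                dry_weight=float(r["dryweight_g"]),
            )
        )
    return out


def read_config(path: str | Path) -> dict:
    """Flat key-value configuration file (YAML mapping of scalars/lists)."""
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError("config must be a flat key-value mapping")
    return data


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def metrics_table(study: StudyTable, gri_variant: str = "standard") -> pd.DataFrame:
    """IndexReport rows, one per dish, plus treatment means."""
    rows = []
    for key, tc in sorted(study.courses.items(), key=lambda kv: (kv[0][0], -kv[0][1], kv[0][2])):
        rep = index_report(tc, study.seedlings.get(key), gri_variant=gri_variant)
        rows.append({
            "temperature_C": rep.temperature,
            "psi_MPa": rep.water_potential,
            "replicate_id": rep.replicate_id,
            "germination_percent": rep.germination_percent,
            "MGT_d": rep.MGT, "MGR_per_d": rep.MGR, "GE": rep.GE,
            "GRI": rep.GRI, "GI": rep.GI, "timson": rep.timson_index,
            "CVG_pct_per_d": rep.CVG, "T50_d": rep.T50,
            "SVI_length": rep.SVI_length, "SVI_weight": rep.SVI_weight,
            "undefined": ";".join(
                f"{k}:{v}" for k, v in sorted(rep.undefined_reasons.items())
            ),
        })
    per_dish = pd.DataFrame(rows)
    means = (
        per_dish.drop(columns=["replicate_id", "undefined"])
        .groupby(["temperature_C", "psi_MPa"], sort=False)
        .mean()
        .reset_index()
        .assign(replicate_id="mean", undefined="")
    )
    return pd.concat([per_dish, means], ignore_index=True)


def run_pipeline(
    study: StudyTable,
    config: dict | None = None,
) -> dict:
    """Run metrics + all model fits, isolating stage failures.

    Returns a bundle with keys ``metrics`` (DataFrame), ``thermal``,
    ``hydrotime`` (per temperature), ``htt``, ``table1`` (DataFrame) and
    ``errors`` (stage -> message).  Deterministic given inputs and config.
    """
    config = dict(config or {})
    g = float(config.get("percentile", 0.5))
    bundle: dict = {"errors": {}, "config": config}
    courses = study.all_courses()
    if not courses:
        bundle["errors"]["study"] = "empty study"
        return bundle

    try:
        bundle["metrics"] = metrics_table(
            study, gri_variant=config.get("gri_variant", "standard")
        )
    except Exception as err:  # pragma: no cover - defensive isolation
        bundle["errors"]["metrics"] = str(err)

    if config.get("metrics_only", False):
        return bundle

    psi_max = max(tc.water_potential for tc in courses)
    at_psi0 = [tc for tc in courses if tc.water_potential == psi_max]
    try:
        bundle["thermal"] = fit_thermal(at_psi0, g=g)
    except (FitFailureError, ValueError) as err:
        bundle["errors"]["thermal"] = str(err)

    bundle["hydrotime"] = {}
    for T in sorted({tc.temperature for tc in courses}):
        sub = [tc for tc in courses if tc.temperature == T]
        try:
            bundle["hydrotime"][T] = fit_hydrotime_probit(sub)
        except (FitFailureError, ValueError) as err:
            bundle["errors"][f"hydrotime@{T}"] = str(err)

    try:
        bundle["htt"] = fit_htt(courses)
    except (FitFailureError, ValueError) as err:
        bundle["errors"]["htt"] = str(err)

    try:
        if "htt" in bundle:
            p = bundle["htt"][0]
            Tc = config.get("Tc", max(tc.temperature for tc in courses))
            bundle["table1"] = table1_grid(
                courses, Tb=p.Tb, Tc=float(Tc), psib=p.psib50, g=g
            )
    except (FitFailureError, ValueError) as err:
        bundle["errors"]["table1"] = str(err)
    return bundle


def fit_summary_text(params, diag) -> str:
    """Flat key = value rendering of a fit result."""
    lines = []
    for name, val in vars(params).items():
        if val is not None and not isinstance(val, dict):
            lines.append(f"{name} = {val:.6g}")
    lines.append(f"r_squared = {diag.r_squared:.6g}")
    lines.append(f"n_obs = {diag.n_obs}")
    if diag.F_statistic is not None:
        lines.append(f"F_statistic = {diag.F_statistic:.6g}")
    if diag.standard_error is not None:
        lines.append(f"standard_error = {diag.standard_error:.6g}")
    if diag.p_value is not None:
        lines.append(f"p_value = {diag.p_value:.6g}")
    return "\n".join(lines) + "\n"
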