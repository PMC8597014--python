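"""CSV readers/writers for time courses, pH logs and acetyl-peak integrals.

File conventions: comma-separated, UTF-8, ``.`` decimal point, ``#`` comment
lines.  Metadata is carried in leading ``# key: value`` comments.  Times are
hours throughout; a ``time_unit`` metadata key of ``d`` converts day-stamped
files to hours on load.  Species columns follow the fixed orderings
``c_1a ... c_1g`` (trisaccharide) and ``c_A ... c_D`` (GGM); missing
observations are empty cells.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .fitting import TimecourseDataset
from .kinetics import (
    GGM_SPECIES,
    PhProfile,
    Trajectory,
    normalize_model_kind,
    species_for,
)

__all__ = [
    "FormatError",
    "PeakIntegralTable",
    "read_timecourse_csv",
    "write_timecourse_csv",
    "read_ph_log",
    "write_ph_log",
    "read_peak_integrals",
    "integrals_to_fractions",
]


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


def _format_value(value: float) -> str:
    if isinstance(value, float) and math.isnan(value):
        return ""
    return f"{value:.10g}"


def _read_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as handle:
        for line in handle:
            stripped = line.strip()
            if not stripped.startswith("#"):
                break
            body = stripped.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta


def _time_scale(meta: Mapping[str, str]) -> float:
    unit = meta.get("time_unit", "h")
    if unit == "h":
        return 1.0
    if unit == "d":
        return 24.0
    raise FormatError(f"unknown time_unit {unit!r}; expected 'h' or 'd'")


# ---------------------------------------------------------------------------
# Time-course files
# ---------------------------------------------------------------------------

def read_timecourse_csv(path, ph_profile: PhProfile | None = None) -> TimecourseDataset:
    """Load a species-fraction time course.

    Expects a ``time_h`` column plus species columns drawn from the fixed
    orderings; species columns absent from the file are recorded as
    unobserved.  Metadata comments may carry ``model_kind``, ``label``,
    ``time_unit`` and ``initial_state`` (comma-separated full state vector);
    without an explicit initial state the first observed row is used, with
    unobserved species set to zero.  ``ph_profile`` defaults to constant pH 8.
    """
    path = Path(path)
    meta = _read_metadata(path)
    table = pd.read_csv(path, comment="#")
    if "time_h" not in table.columns:
        raise FormatError(f"{path}: missing required column 'time_h'")

    kind = normalize_model_kind(meta.get("model_kind", "trisaccharide"))
    species = species_for(kind)
    valid_columns = {f"c_{s}": s for s in species}
    observed: list[str] = []
    for column in table.columns:
        if column == "time_h":
            continue
        if column not in valid_columns:
            raise FormatError(
                f"{path}: unknown species column {column!r} for model {kind!r}"
            )
        observed.append(valid_columns[column])
    # keep fixed species ordering regardless of file column order
    observed = [s for s in species if s in observed]

    times = table["time_h"].to_numpy(dtype=float) * _time_scale(meta)
    if np.any(np.diff(times) < 0):
        raise FormatError(f"{path}: time_h values must be non-decreasing")
    observations = np.column_stack(
        [table[f"c_{s}"].to_numpy(dtype=float) for s in observed]
    ) if observed else np.empty((times.size, 0))

    row_sums = np.nansum(observations, axis=1) if observed else np.zeros(times.size)
    bad = np.nonzero(row_sums > 1 + 0.05)[0]
    if bad.size:
        raise FormatError(
            f"{path}: species fractions in rows {bad.tolist()} sum to more than 1"
        )

    if "initial_state" in meta:
        initial_state = np.array(
            [float(v) for v in meta["initial_state"].split(",")], dtype=float
        )
        if initial_state.size != len(species):
            raise FormatError(
                f"{path}: initial_state must list {len(species)} values for {kind!r}"
            )
    else:
        initial_state = np.zeros(len(species))
        if times.size:
            for j, s in enumerate(observed):
                value = observations[0, j]
                initial_state[species.index(s)] = 0.0 if math.isnan(value) else value

    return TimecourseDataset(
        model_kind=kind,
        sample_times=times,
        observations=observations,
        observed_species=tuple(observed),
        ph_profile=ph_profile or PhProfile.constant(8.0),
        initial_state=initial_state,
        label=meta.get("label", path.stem),
    )


def write_timecourse_csv(data: TimecourseDataset | Trajectory, path) -> Path:
    """Write a time course with deterministic column order and 10 significant digits."""
    path = Path(path)
    if isinstance(data, Trajectory):
        kind = data.model_kind
        observed = data.species
        times = data.times
        values = data.states
        meta = {"model_kind": kind, "time_unit": "h"}
    else:
        kind = data.model_kind
        observed = data.observed_species
        times = data.sample_times
        values = data.observations
        meta = {
            "model_kind": kind,
            "time_unit": "h",
            "label": data.label,
            "initial_state": ",".join(_format_value(v) for v in data.initial_state),
        }

    buffer = io.StringIO()
    for key, value in meta.items():
        if value != "":
            buffer.write(f"# {key}: {value}\n")
    header = ["time_h"] + [f"c_{s}" for s in observed]
    buffer.write(",".join(header) + "\n")
    for i in range(len(times)):
        row = [_format_value(float(times[i]))]
        row += [_format_value(float(v)) for v in values[i]]
        buffer.write(",".join(row) + "\n")
    path.write_text(buffer.getvalue(), encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# pH logs
# ---------------------------------------------------------------------------

def read_ph_log(path, reference_ph: float = 8.0) -> PhProfile:
    """Load a pH log with columns ``time_h, ph`` into a validated profile."""
    path = Path(path)
    meta = _read_metadata(path)
    table = pd.read_csv(path, comment="#")
    for column in ("time_h", "ph"):
        if column not in table.columns:
            raise FormatError(f"{path}: missing required column {column!r}")
    times = table["time_h"].to_numpy(dtype=float) * _time_scale(meta)
    ph = table["ph"].to_numpy(dtype=float)
    try:
        return PhProfile(times=times, ph=ph, reference_ph=reference_ph)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_ph_log(profile: PhProfile, path) -> Path:
    path = Path(path)
    lines = ["# time_unit: h", "time_h,ph"]
    for t, ph in zip(profile.times, profile.ph):
        lines.append(f"{_format_value(float(t))},{_format_value(float(ph))}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Peak integrals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakIntegralTable:
    """Acetyl-peak integrals over time plus the site-to-species assignment.

    ``rows`` holds (time_h, site_id, integral) records; ``site_map`` sends
    each NMR site id to its (species, acetyl position).  Each acetyl methyl
    singlet is a 3H reporter of the molar concentration of its species, so
    integrals of a species' sites are averaged, not summed, to form the
    molar proxy.
    """

    rows: pd.DataFrame
    site_map: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        required = {"time_h", "site_id", "integral"}
        missing = required - set(self.rows.columns)
        if missing:
            raise FormatError(f"peak table missing columns {sorted(missing)}")
        if (self.rows["integral"] < 0).any():
            raise FormatError("peak integrals must be >= 0")
        unresolved = set(self.rows["site_id"]) - set(self.site_map)
        if unresolved:
            raise FormatError(f"site ids without mapping: {sorted(unresolved)}")


def read_peak_integrals(peaks_path, site_map_path) -> PeakIntegralTable:
    """Load a peak-integral CSV (time_h, site_id, integral) and a site map
    CSV (site_id, species, position)."""
    rows = pd.read_csv(Path(peaks_path), comment="#")
    mapping = pd.read_csv(Path(site_map_path), comment="#")
    for column in ("site_id", "species", "position"):
        if column not in mapping.columns:
            raise FormatError(f"{site_map_path}: missing column {column!r}")
    site_map = {
        str(row.site_id): (str(row.species), str(row.position))
        for row in mapping.itertuples()
    }
    return PeakIntegralTable(rows=rows, site_map=site_map)


def integrals_to_fractions(
    table: PeakIntegralTable,
    model_kind: str = "trisaccharide",
    convention: str = "per_time",
    ph_profile: PhProfile | None = None,
) -> TimecourseDataset:
    """Convert acetyl-peak integrals to species mole fractions.

    Per time point each species' molar proxy is the mean of its available
    site integrals.  With ``convention="per_time"`` the acetyl-bearing
    species are normalised to sum 1 at every time point (the deacetylated
    species is not reported).  With ``convention="t0_total"`` all proxies are
    scaled by the total proxy at the first time point and the deacetylated
    species (1g or D) is assigned ``1 - sum(acetyl-bearing)``.

    Species with no resolvable site at a time point become missing values
    (NaN), never zero.
    """
    kind = normalize_model_kind(model_kind)
    species = species_for(kind)
    deacetylated = "D" if species == GGM_SPECIES else "1g"
    acetyl_bearing = [s for s in species if s != deacetylated]
    if convention not in ("per_time", "t0_total"):
        raise ValueError(f"unknown convention {convention!r}")

    known = {s for s, _pos in table.site_map.values()}
    unknown = known - set(acetyl_bearing)
    if unknown:
        raise FormatError(
            f"site map references species {sorted(unknown)} not in model {kind!r}"
        )
    # only species with at least one mapped site are observable
    acetyl_bearing = [s for s in acetyl_bearing if s in known]

    times = np.array(sorted(table.rows["time_h"].unique()), dtype=float)
    proxies = np.full((times.size, len(acetyl_bearing)), np.nan)
    for i, t in enumerate(times):
        at_t = table.rows[table.rows["time_h"] == t]
        if at_t.empty:
            continue
        for j, sp in enumerate(acetyl_bearing):
            site_ids = [sid for sid, (s, _p) in table.site_map.items() if s == sp]
            values = at_t[at_t["site_id"].isin(site_ids)]["integral"].to_numpy(dtype=float)
            if values.size:
                proxies[i, j] = values.mean()
        if np.all(np.isnan(proxies[i])):
            raise FormatError(f"no resolvable site at time {t}")

    fractions = np.full_like(proxies, np.nan)
    if convention == "per_time":
        for i in range(times.size):
            total = np.nansum(proxies[i])
            if total > 0:
                fractions[i] = proxies[i] / total
        observed = tuple(acetyl_bearing)
        observations = fractions
    else:
        t0_total = np.nansum(proxies[0])
        if t0_total <= 0:
            raise FormatError("total integral at the first time point is zero")
        scaled = proxies / t0_total
        deacet = 1.0 - np.nansum(scaled, axis=1)
        observed = tuple(acetyl_bearing) + (deacetylated,)
        observations = np.column_stack([scaled, np.clip(deacet, 0.0, 1.0)])

    initial_state = np.zeros(len(species))
    for j, sp in enumerate(observed):
        value = observations[0, j]
        initial_state[species.index(sp)] = 0.0 if math.isnan(value) else value

    return TimecourseDataset(
        model_kind=kind,
        sample_times=times,
        observations=np.clip(observations, 0.0, 1.0),
        observed_species=observed,
        ph_profile=ph_profile or PhProfile.constant(8.0),
        initial_state=initial_state,
        label=f"from peak integrals ({convention})",
    )
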