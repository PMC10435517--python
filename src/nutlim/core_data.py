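"""Domain types, unit handling and CSV I/O for bioassay meta-analysis.

The experiment tables mirror the structure of published nutrient-addition
bioassay compilations: one experiment = one site/date with an unamended
control and a set of nutrient-amended treatments, each with replicate final
chlorophyll-a measurements.  Station tables carry surface dissolved nutrient
concentrations (one row per station).

Canonical internal concentration unit is mol/L.  Default file units follow
oceanographic reporting convention: µmol/L for the macronutrients N, P, Si;
nmol/L for the trace metals Fe, Mn, Zn, Co; pmol/L for vitamin B12.
"""
from __future__ import annotations

import enum
import logging
import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

__all__ = [
    "Nutrient",
    "Concentration",
    "Treatment",
    "Experiment",
    "Station",
    "Level",
    "LimitationResult",
    "DEFAULT_STOICHIOMETRY",
    "DEFAULT_FILE_UNITS",
    "UNIT_FACTORS",
    "parse_added",
    "format_added",
    "parse_limitation",
    "format_limitation",
    "read_experiments",
    "read_station_table",
    "write_results",
    "write_experiments",
    "read_growth_responses",
    "load_config",
    "ReadResult",
]


class Nutrient(str, enum.Enum):
    """Closed enumeration of nutrients tested across the dataset."""

    N = "N"
    P = "P"
    Fe = "Fe"
    Mn = "Mn"
    Co = "Co"
    Zn = "Zn"
    Si = "Si"
    B12 = "B12"

    def __str__(self) -> str:  # serialize as the bare symbol
        return self.value

    @classmethod
    def parse(cls, symbol: str) -> "Nutrient":
        s = symbol.strip()
        for n in cls:
            if n.value.lower() == s.lower():
                return n
        raise ValueError(f"unknown nutrient symbol: {symbol!r}")


#: mol/L per declared unit
UNIT_FACTORS = {
    "umol/L": 1e-6,
    "nmol/L": 1e-9,
    "pmol/L": 1e-12,
}
# units per µmol/L; dividing first keeps the 1e3/1e6 equivalences exact
_PER_UMOL = {
    "umol/L": 1.0,
    "nmol/L": 1e3,
    "pmol/L": 1e6,
}
# accept the micro sign and compact column-name spellings
_UNIT_ALIASES = {
    "µmol/L": "umol/L",
    "umolL": "umol/L",
    "nmolL": "nmol/L",
    "pmolL": "pmol/L",
    "umol": "umol/L",
    "nmol": "nmol/L",
    "pmol": "pmol/L",
}

DEFAULT_FILE_UNITS = {
    Nutrient.N: "umol/L",
    Nutrient.P: "umol/L",
    Nutrient.Si: "umol/L",
    Nutrient.Fe: "nmol/L",
    Nutrient.Mn: "nmol/L",
    Nutrient.Zn: "nmol/L",
    Nutrient.Co: "nmol/L",
    Nutrient.B12: "pmol/L",
}

#: Assumed-average phytoplankton requirement relative to P = 1.
#: Si and B12 carry no default requirement and are excluded from deficiency.
DEFAULT_STOICHIOMETRY = {
    Nutrient.N: 16.0,
    Nutrient.P: 1.0,
    Nutrient.Fe: 7.5e-3,
    Nutrient.Mn: 2.8e-3,
    Nutrient.Zn: 8.0e-4,
    Nutrient.Co: 1.9e-4,
}


def canonical_unit(unit: str) -> str:
    u = _UNIT_ALIASES.get(unit, unit)
    if u not in UNIT_FACTORS:
        raise ValueError(f"unknown concentration unit: {unit!r}")
    return u


@dataclass(frozen=True)
class Concentration:
    """A dissolved nutrient concentration with its reporting unit.

    ``below_detection`` marks values stored as the detection limit; downstream
    deficiency calculations use the limit value itself.
    """

    value: float
    unit: str = "umol/L"
    below_detection: bool = False

    def __post_init__(self):
        object.__setattr__(self, "unit", canonical_unit(self.unit))
        if not math.isfinite(self.value) or self.value < 0:
            raise ValueError(f"concentration must be finite and >= 0, got {self.value}")

    @property
    def molar(self) -> float:
        """Concentration in mol/L (1 µmol/L ≡ 1e3 nmol/L ≡ 1e6 pmol/L
        exactly)."""
        return (self.value / _PER_UMOL[self.unit]) * 1e-6


@dataclass(frozen=True)
class Treatment:
    """One bottle treatment: the set of added nutrients (empty = control)
    and replicate final chlorophyll-a concentrations in µg/L."""

    added: frozenset
    chl_final: tuple
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "added", frozenset(self.added))
        object.__setattr__(self, "chl_final", tuple(float(v) for v in self.chl_final))
        if len(self.chl_final) < 1:
            raise ValueError("treatment needs at least one replicate")
        if any(v < 0 for v in self.chl_final):
            raise ValueError("negative chlorophyll replicate")

    @property
    def is_control(self) -> bool:
        return len(self.added) == 0

    @property
    def n_replicates(self) -> int:
        return len(self.chl_final)

    @property
    def mean_chl(self) -> float:
        return float(np.mean(self.chl_final))


@dataclass(frozen=True)
class Level:
    """One level of a limitation hierarchy: a set of nutrients with a tag.

    tag "co" means the nutrients are jointly (co-)limiting at that level;
    tag "single" with more than one nutrient means independent responses
    (each nutrient alone was stimulatory)."""

    nutrients: frozenset
    tag: str = "single"  # "single" | "co"

    def __post_init__(self):
        object.__setattr__(self, "nutrients", frozenset(self.nutrients))
        if self.tag not in ("single", "co"):
            raise ValueError(f"bad level tag {self.tag!r}")
        if self.tag == "co" and len(self.nutrients) < 2:
            raise ValueError("co-tagged level requires >= 2 nutrients")
        if len(self.nutrients) == 0:
            raise ValueError("empty level")

    def sorted_symbols(self):
        return sorted(n.value for n in self.nutrients)


@dataclass
class LimitationResult:
    """Primary / serial / co-limitation structure of one experiment.

    ``levels[0]`` is the primary level, ``levels[1]`` secondary, ``levels[2]``
    tertiary.  ``category`` is "limited" (levels non-empty), "replete" (no
    addition stimulated growth) or "indeterminate" (untestable)."""

    category: str  # "limited" | "replete" | "indeterminate"
    levels: list = field(default_factory=list)
    comparisons: list = field(default_factory=list)
    flags: list = field(default_factory=list)
    reason: str = ""

    def __post_init__(self):
        if self.category not in ("limited", "replete", "indeterminate"):
            raise ValueError(f"bad category {self.category!r}")
        if self.category == "limited" and not self.levels:
            raise ValueError("limited result requires at least one level")
        if self.category != "limited" and self.levels:
            raise ValueError("levels only allowed for category 'limited'")
        seen = set()
        for lv in self.levels:
            if lv.nutrients & seen:
                raise ValueError("nutrient repeated across levels")
            seen |= lv.nutrients

    @property
    def primary(self):
        return self.levels[0] if self.levels else None

    def signature(self):
        """Hashable (category, levels) summary used for regime comparison."""
        return (
            self.category,
            tuple((tuple(lv.sorted_symbols()), lv.tag) for lv in self.levels),
        )

    @property
    def is_co_or_serial(self) -> bool:
        return self.category == "limited" and (
            len(self.levels) > 1 or any(lv.tag == "co" for lv in self.levels)
        )


# --- compact string codec for limitation structures -----------------------
# "N" primary single; "N+Fe" primary co; "N&Fe" multiple independent
# primaries; levels separated by ">", e.g. "N>Fe>Co"; "replete";
# "indeterminate".


def format_limitation(res: LimitationResult) -> str:
    if res.category != "limited":
        return res.category
    parts = []
    for lv in res.levels:
        sep = "+" if lv.tag == "co" else "&"
        parts.append(sep.join(lv.sorted_symbols()))
    return ">".join(parts)


def parse_limitation(text: str) -> LimitationResult:
    s = str(text).strip()
    if s in ("replete", "indeterminate"):
        return LimitationResult(category=s)
    if not s:
        raise ValueError("empty limitation string")
    levels = []
    for part in s.split(">"):
        if "+" in part:
            tag, sep = "co", "+"
        else:
            tag, sep = "single", "&"
        nuts = frozenset(Nutrient.parse(x) for x in part.split(sep))
        levels.append(Level(nutrients=nuts, tag=tag))
    return LimitationResult(category="limited", levels=levels)


def parse_added(text: str) -> frozenset:
    """Parse a '+'-separated nutrient set; empty string = control."""
    s = str(text).strip()
    if s == "" or s.lower() in ("control", "ctrl", "nan", "none"):
        return frozenset()
    return frozenset(Nutrient.parse(p) for p in s.split("+"))


def format_added(added) -> str:
    return "+".join(sorted(n.value for n in added))


@dataclass
class Experiment:
    """One bioassay experiment: metadata, ambient nutrients, treatments."""

    id: str
    latitude: float
    longitude: float
    duration: float  # days
    chl_initial: float  # µg/L
    temperature: float | None = None  # °C
    nutrients: dict = field(default_factory=dict)  # Nutrient -> Concentration
    treatments: list = field(default_factory=list)
    design: str = "bottle"  # "bottle" | "mesoscale_in_situ"
    recorded_limitation: LimitationResult | None = None
    source: str = ""

    def __post_init__(self):
        if not (-90 <= self.latitude <= 90):
            raise ValueError(f"latitude out of range: {self.latitude}")
        # normalize longitude to (-180, 180]
        lon = ((self.longitude + 180.0) % 360.0) - 180.0
        self.longitude = 180.0 if lon == -180.0 else lon
        if not self.duration > 0:
            raise ValueError("duration must be > 0 days")
        if self.chl_initial < 0:
            raise ValueError("negative initial chlorophyll")
        if self.design not in ("bottle", "mesoscale_in_situ"):
            raise ValueError(f"unknown design {self.design!r}")
        seen = set()
        for t in self.treatments:
            if t.added in seen:
                raise ValueError(
                    f"duplicate treatment added-set {format_added(t.added) or 'control'}"
                    f" in experiment {self.id}"
                )
            seen.add(t.added)

    @property
    def control(self) -> Treatment | None:
        for t in self.treatments:
            if t.is_control:
                return t
        return None

    @property
    def min_replicates(self) -> int:
        return min((t.n_replicates for t in self.treatments), default=0)

    def classifiable(self) -> bool:
        """Bottle design with a control and triplicate replication throughout."""
        return (
            self.design == "bottle"
            and self.control is not None
            and self.min_replicates >= 3
        )

    def ambient_molar(self) -> dict:
        return {n: c.molar for n, c in self.nutrients.items()}


@dataclass
class Station:
    """A surface-seawater station with measured nutrient concentrations."""

    id: str
    latitude: float
    longitude: float
    nutrients: dict = field(default_factory=dict)  # Nutrient -> Concentration
    depth_m: float | None = None


@dataclass
class ReadResult:
    """Validated records plus a rejection report (never silently dropped)."""

    experiments: list = field(default_factory=list)
    rejections: list = field(default_factory=list)  # dicts: id/row, reason

    def __iter__(self):
        return iter(self.experiments)

    def __len__(self):
        return len(self.experiments)

    def rejection_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rejections, columns=["experiment_id", "reason"])


_NUTRIENT_COL = re.compile(r"^nutrient_([A-Za-z0-9]+)_(.+)$")

_MANDATORY_LONG = [
    "experiment_id",
    "lat",
    "lon",
    "duration_d",
    "chl_initial_ugL",
    "added_nutrients",
    "chl_final_ugL",
]


def _ambient_from_row(row, nutrient_cols) -> dict:
    out = {}
    for col, (nut, unit) in nutrient_cols.items():
        v = row.get(col)
        if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
            continue
        out[nut] = Concentration(float(v), unit)
    return out


def _scan_nutrient_columns(columns, unit_overrides=None):
    found = {}
    for col in columns:
        m = _NUTRIENT_COL.match(col)
        if not m:
            continue
        nut = Nutrient.parse(m.group(1))
        unit = canonical_unit(m.group(2))
        if unit_overrides and nut in unit_overrides:
            unit = canonical_unit(unit_overrides[nut])
        found[col] = (nut, unit)
    return found


def read_experiments(path, schema_config=None) -> ReadResult:
    """Read an experiments CSV into validated :class:`Experiment` objects.

    Two dialects are supported, declared via ``schema_config["dialect"]``:

    - ``"long"`` (default): one row per treatment-replicate with columns
      ``experiment_id, source, lat, lon, temperature_C, duration_d,
      chl_initial_ugL, treatment_label, added_nutrients, replicate_index,
      chl_final_ugL, design, recorded_limitation`` plus optional
      ``nutrient_<X>_<unit>`` ambient-concentration columns.
    - ``"wide"``: one row per treatment with replicate columns
      ``chl_final_1 .. chl_final_k``.

    Rows or experiments violating invariants are collected into the
    rejection report of the returned :class:`ReadResult`.
    """
    cfg = dict(schema_config or {})
    dialect = cfg.get("dialect", "long")
    result = ReadResult()
    try:
        df = pd.read_csv(path, dtype={"experiment_id": str})
    except pd.errors.EmptyDataError:
        log.warning("empty experiments file: %s", path)
        return result
    if df.empty:
        log.warning("empty experiments file: %s", path)
        return result

    if dialect == "long":
        missing = [c for c in _MANDATORY_LONG if c not in df.columns]
    elif dialect == "wide":
        missing = [
            c
            for c in _MANDATORY_LONG
            if c != "chl_final_ugL" and c not in df.columns
        ]
        if not any(c.startswith("chl_final_") for c in df.columns):
            missing.append("chl_final_1")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")

    nutrient_cols = _scan_nutrient_columns(df.columns, cfg.get("units"))

    for exp_id, g in df.groupby("experiment_id", sort=False):
        try:
            result.experiments.append(
                _build_experiment(str(exp_id), g, dialect, nutrient_cols)
            )
        except (ValueError, KeyError) as exc:
            result.rejections.append(
                {"experiment_id": str(exp_id), "reason": str(exc)}
            )
    return result


def _opt(row, key, default=None):
    v = row.get(key, default)
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return default
    return v


def _build_experiment(exp_id, g, dialect, nutrient_cols) -> Experiment:
    first = g.iloc[0].to_dict()
    treatments = []
    if dialect == "long":
        for label, tg in g.groupby(g["added_nutrients"].fillna("").astype(str), sort=False):
            added = parse_added(label)
            reps = tuple(float(v) for v in tg["chl_final_ugL"])
            tl = str(_opt(tg.iloc[0].to_dict(), "treatment_label", label) or label)
            treatments.append(Treatment(added=added, chl_final=reps, label=tl))
    else:
        rep_cols = sorted(
            (c for c in g.columns if re.fullmatch(r"chl_final_\d+", c)),
            key=lambda c: int(c.rsplit("_", 1)[1]),
        )
        for _, row in g.iterrows():
            added = parse_added(str(row["added_nutrients"]) if not pd.isna(row["added_nutrients"]) else "")
            reps = tuple(
                float(row[c]) for c in rep_cols if not pd.isna(row[c])
            )
            treatments.append(
                Treatment(added=added, chl_final=reps,
                          label=str(_opt(row.to_dict(), "treatment_label", "") or ""))
            )

    recorded = _opt(first, "recorded_limitation")
    rec = parse_limitation(recorded) if recorded not in (None, "") else None
    temp = _opt(first, "temperature_C")
    return Experiment(
        id=exp_id,
        latitude=float(first["lat"]),
        longitude=float(first["lon"]),
        temperature=None if temp is None else float(temp),
        duration=float(first["duration_d"]),
        chl_initial=float(first["chl_initial_ugL"]),
        nutrients=_ambient_from_row(first, nutrient_cols),
        treatments=treatments,
        design=str(_opt(first, "design", "bottle") or "bottle"),
        recorded_limitation=rec,
        source=str(_opt(first, "source", "") or ""),
    )


def read_station_table(path, schema_config=None) -> list:
    """Read a station nutrient CSV (columns: station_id, lat, lon, optional
    depth_m, nutrient_<X>_<unit>).  Stations deeper than 10 m are excluded
    (surface criterion); stations without any measured nutrient are dropped."""
    cfg = dict(schema_config or {})
    try:
        df = pd.read_csv(path, dtype={"station_id": str})
    except pd.errors.EmptyDataError:
        log.warning("empty station file: %s", path)
        return []
    if df.empty:
        log.warning("empty station file: %s", path)
        return []
    nutrient_cols = _scan_nutrient_columns(df.columns, cfg.get("units"))
    if not nutrient_cols:
        raise ValueError("no recognized nutrient_<X>_<unit> column in station table")
    stations = []
    max_depth = cfg.get("max_depth_m", 10.0)
    for _, row in df.iterrows():
        d = row.to_dict()
        depth = _opt(d, "depth_m")
        if depth is not None and float(depth) >= max_depth:
            continue
        concs = _ambient_from_row(d, nutrient_cols)
        if not concs:
            continue
        stations.append(
            Station(
                id=str(d["station_id"]),
                latitude=float(d["lat"]),
                longitude=float(d["lon"]),
                nutrients=concs,
                depth_m=None if depth is None else float(depth),
            )
        )
    return stations


def write_results(objects, path) -> None:
    """Serialize a homogeneous collection of result objects to CSV.

    Deterministic column order; round-trips losslessly through the matching
    reader.  An empty collection writes a header-only file when the element
    type can be inferred, otherwise an empty file."""
    rows = [_to_row(o) for o in objects]
    if rows:
        df = pd.DataFrame(rows, columns=list(rows[0].keys()))
    else:
        df = pd.DataFrame()
    df.to_csv(path, index=False)


def _to_row(obj) -> dict:
    # local import: growth/deficiency dataclasses live downstream
    from . import growth_rates as gr

    if isinstance(obj, gr.GrowthResponse):
        return {
            "experiment_id": obj.experiment_id,
            "added_nutrients": format_added(obj.added),
            "n_added": obj.n_added,
            "mu_net_d": obj.mu_net,
            "mu_max_d": "" if obj.mu_max is None else obj.mu_max,
            "mu_rel": "" if obj.mu_rel is None else obj.mu_rel,
            "chl_T_ugL": obj.chl_T,
            "chl_I_ugL": obj.chl_I,
            "t_d": obj.t,
            "temperature_C": "" if obj.T is None else obj.T,
        }
    if isinstance(obj, LimitationResult):
        return {"limitation": format_limitation(obj), "flags": ";".join(obj.flags)}
    if isinstance(obj, tuple) and len(obj) == 2 and isinstance(obj[1], LimitationResult):
        return {
            "experiment_id": obj[0],
            "limitation": format_limitation(obj[1]),
            "flags": ";".join(obj[1].flags),
        }
    if isinstance(obj, dict):
        return obj
    if hasattr(obj, "to_row"):
        return obj.to_row()
    raise TypeError(f"cannot serialize {type(obj).__name__}")


def read_growth_responses(path) -> list:
    from . import growth_rates as gr

    df = pd.read_csv(path, dtype={"experiment_id": str})
    out = []
    for _, row in df.iterrows():
        d = row.to_dict()
        mu_max = _opt(d, "mu_max_d")
        mu_rel = _opt(d, "mu_rel")
        temp = _opt(d, "temperature_C")
        out.append(
            gr.GrowthResponse(
                experiment_id=str(d["experiment_id"]),
                added=parse_added(str(_opt(d, "added_nutrients", "") or "")),
                mu_net=float(d["mu_net_d"]),
                mu_max=None if mu_max is None else float(mu_max),
                mu_rel=None if mu_rel is None else float(mu_rel),
                chl_T=float(d["chl_T_ugL"]),
                chl_I=float(d["chl_I_ugL"]),
                t=float(d["t_d"]),
                T=None if temp is None else float(temp),
            )
        )
    return out


def write_experiments(experiments, path) -> None:
    """Write experiments in the long dialect (inverse of
    :func:`read_experiments`); ambient concentrations are emitted in their
    stored units as ``nutrient_<X>_<unit>`` columns."""
    nutrient_cols = {}
    for exp in experiments:
        for nut, conc in exp.nutrients.items():
            unit_token = conc.unit.replace("/", "")
            nutrient_cols[nut] = f"nutrient_{nut.value}_{unit_token}"
    rows = []
    for exp in experiments:
        base = {
            "experiment_id": exp.id,
            "source": exp.source,
            "lat": exp.latitude,
            "lon": exp.longitude,
            "temperature_C": "" if exp.temperature is None else exp.temperature,
            "duration_d": exp.duration,
            "chl_initial_ugL": exp.chl_initial,
            "design": exp.design,
            "recorded_limitation": (
                "" if exp.recorded_limitation is None
                else format_limitation(exp.recorded_limitation)
            ),
        }
        for nut, col in nutrient_cols.items():
            conc = exp.nutrients.get(nut)
            base[col] = "" if conc is None else conc.value
        for tr in exp.treatments:
            for ri, v in enumerate(tr.chl_final, start=1):
                rows.append(
                    {
                        **base,
                        "treatment_label": tr.label,
                        "added_nutrients": format_added(tr.added),
                        "replicate_index": ri,
                        "chl_final_ugL": v,
                    }
                )
    cols = [
        "experiment_id", "source", "lat", "lon", "temperature_C",
        "duration_d", "chl_initial_ugL", "treatment_label",
        "added_nutrients", "replicate_index", "chl_final_ugL", "design",
        "recorded_limitation",
    ] + sorted(nutrient_cols.values())
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a YAML configuration file (dialects, units, alpha, stoichiometry
    overrides).  Returns an empty dict for an empty file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "stoichiometry" in cfg:
        cfg["stoichiometry"] = {
            Nutrient.parse(k): float(v) for k, v in cfg["stoichiometry"].items()
        }
    return cfg
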