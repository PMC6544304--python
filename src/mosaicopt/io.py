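"""File formats and run configuration.

Landscape rasters travel as headerless CSV of single-character codes
(``G`` grassland, ``F`` forest, ``A`` agriculture, ``U`` urban, ``W``
water; ``U``/``W`` map to the inert excluded state) or as ESRI ASCII grids
with integer codes mapped through the configuration. Owner rasters are
same-shape integer CSV (``-1`` = unowned/state land). Quadrat tables are
CSV with a species-id first column and one column per quadrat.

Run configuration is YAML or JSON, schema-checked before any run; unknown
keys are rejected rather than ignored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path as FsPath
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import CodeError, ConfigError, ParseError
from .grid import Landscape, LandState
from .objective import ObjectiveConfig
from .sar import QuadratTable, SarParams, build_state_params, default_params
from .search import ALL_PAIRS, ExchangeRules, SearchLimits, Path, SearchResult

__all__ = [
    "DEFAULT_CODE_MAP",
    "read_landscape",
    "write_landscape",
    "read_owners",
    "read_quadrat_csv",
    "RunConfig",
    "load_config",
    "result_report",
    "trajectory_frame",
]

SCHEMA_VERSION = 1

#: CSV symbol -> land state (exported codes use the same convention).
DEFAULT_CODE_MAP = {
    "G": LandState.G,
    "F": LandState.F,
    "A": LandState.AG,
    "U": LandState.X,
    "W": LandState.X,
}
_EXPORT_CODE = {LandState.G: "G", LandState.F: "F", LandState.AG: "A", LandState.X: "U"}

#: default integer code -> state for ESRI ASCII grids
DEFAULT_ASC_CODES = {1: LandState.G, 2: LandState.F, 3: LandState.AG, 4: LandState.X}


def _read_landscape_csv(path, code_map) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for r, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            row = []
            for c, tok in enumerate(line.split(",")):
                tok = tok.strip()
                if tok not in code_map:
                    raise CodeError(f"unmapped land-state symbol {tok!r} at cell ({r}, {c})")
                row.append(int(code_map[tok]))
            rows.append(row)
    if not rows:
        raise ParseError(f"{path}: no grid rows found")
    width = len(rows[0])
    for r, row in enumerate(rows):
        if len(row) != width:
            raise ParseError(f"{path}: row {r} has {len(row)} cells, expected {width}")
    return np.array(rows, dtype=np.int8)


def _read_landscape_asc(path, int_codes) -> np.ndarray:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines) and lines[i].split() and not _is_number(lines[i].split()[0]):
        key, *val = lines[i].split()
        if not val:
            raise ParseError(f"{path}: malformed header line {i}: {lines[i]!r}")
        header[key.lower()] = float(val[0])
        i += 1
    for req in ("ncols", "nrows"):
        if req not in header:
            raise ParseError(f"{path}: missing required header field {req!r}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    nodata = header.get("nodata_value")
    vals = []
    for line in lines[i:]:
        vals.extend(line.split())
    if len(vals) != nrows * ncols:
        raise ParseError(f"{path}: expected {nrows * ncols} cells, found {len(vals)}")
    grid = np.empty((nrows, ncols), dtype=np.int8)
    for idx, tok in enumerate(vals):
        r, c = divmod(idx, ncols)
        v = float(tok)
        if nodata is not None and v == nodata:
            grid[r, c] = int(LandState.X)
            continue
        iv = int(v)
        if iv not in int_codes:
            raise CodeError(f"unmapped integer code {iv} at cell ({r}, {c})")
        grid[r, c] = int(int_codes[iv])
    return grid


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_landscape(
    path,
    fmt: Optional[str] = None,
    code_map: Optional[dict] = None,
    parcel_area: float = 1.0,
    owners_path=None,
) -> Landscape:
    """Read a landscape raster (CSV of codes or ESRI ASCII grid)."""
    fmt = fmt or ("asc" if str(path).endswith(".asc") else "csv")
    if fmt == "csv":
        states = _read_landscape_csv(path, code_map or DEFAULT_CODE_MAP)
    elif fmt == "asc":
        states = _read_landscape_asc(path, code_map or DEFAULT_ASC_CODES)
    else:
        raise ConfigError(f"unknown landscape format {fmt!r}")
    owners = read_owners(owners_path, states.shape) if owners_path else None
    return Landscape(states=states, parcel_area=parcel_area, owners=owners)


def write_landscape(landscape: Landscape, path) -> None:
    """Write the landscape as code CSV; round-trips through read_landscape."""
    with open(path, "w") as fh:
        for row in landscape.states:
            fh.write(",".join(_EXPORT_CODE[LandState(v)] for v in row) + "\n")


def read_owners(path, shape) -> np.ndarray:
    owners = np.loadtxt(path, delimiter=",", dtype=np.int64, ndmin=2)
    if owners.shape != tuple(shape):
        raise ParseError(f"{path}: owners grid shape {owners.shape} != states {tuple(shape)}")
    return owners


def read_quadrat_csv(path, quadrat_area: float = 1.0, group_file=None):
    """Read species × quadrat cover CSV.

    First column: species id; remaining columns: cover per quadrat, with a
    header row of quadrat labels. With ``group_file`` (CSV: quadrat label,
    group), returns ``{group: QuadratTable}`` instead of one table.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need a species column plus at least one quadrat")
    species = tuple(df.iloc[:, 0].astype(str))
    covers = df.iloc[:, 1:].to_numpy(dtype=float)
    labels = list(df.columns[1:])
    if group_file is None:
        return QuadratTable(species_ids=species, covers=covers, quadrat_area=quadrat_area)
    groups = pd.read_csv(group_file, header=None, names=["quadrat", "group"])
    mapping = dict(zip(groups["quadrat"].astype(str), groups["group"].astype(str)))
    out = {}
    for g in sorted(set(mapping.values())):
        cols = [i for i, lab in enumerate(labels) if mapping.get(str(lab)) == g]
        if not cols:
            continue
        out[g] = QuadratTable(species_ids=species, covers=covers[:, cols], quadrat_area=quadrat_area)
    return out


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_TOP_KEYS = {"sar", "objective", "costs", "rules", "limits", "seed", "io"}
_SAR_KEYS = {"c_G", "z_G", "f_ratio", "ag_ratio", "c", "z"}
_OBJ_KEYS = {"w", "architecture_mode", "degenerate_cap"}
_RULE_KEYS = {"allowed_pairs", "mode", "owner_pair", "max_exchanges", "once_per_parcel", "tie_tol"}
_LIMIT_KEYS = {"node_budget", "on_budget"}
_COST_KEYS = {"GF", "GA", "FG", "FA", "AF", "AG"}
# cost ledger names follow the "new-state, old-state" convention:
# GF = forest parcels changed to grassland, i.e. an F -> G transition
_COST_PAIRS = {
    "GF": (LandState.F, LandState.G),
    "GA": (LandState.AG, LandState.G),
    "FG": (LandState.G, LandState.F),
    "FA": (LandState.AG, LandState.F),
    "AF": (LandState.F, LandState.AG),
    "AG": (LandState.G, LandState.AG),
}
_PAIR_NAMES = {
    "G-Ag": frozenset({LandState.G, LandState.AG}),
    "F-Ag": frozenset({LandState.F, LandState.AG}),
    "G-F": frozenset({LandState.G, LandState.F}),
}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration: objective + rules + limits + seed."""

    objective: ObjectiveConfig
    rules: ExchangeRules
    limits: SearchLimits
    seed: int = 0


def _check_keys(section: str, given: dict, allowed: set) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {section!r}: {sorted(unknown)}")


def config_from_dict(raw: dict) -> RunConfig:
    _check_keys("config", raw, _TOP_KEYS)
    sar_raw = dict(raw.get("sar", {}))
    _check_keys("sar", sar_raw, _SAR_KEYS)
    if "c" in sar_raw or "z" in sar_raw:
        try:
            c = {LandState.from_code(k): float(v) for k, v in sar_raw["c"].items()}
            z = {LandState.from_code(k): float(v) for k, v in sar_raw["z"].items()}
        except KeyError as e:
            raise ConfigError(f"bad per-state SAR spec: {e}") from None
        sar = SarParams(c=c, z=z)
    elif sar_raw:
        sar = build_state_params(
            c_G=float(sar_raw.get("c_G", 19.95)),
            z_G=float(sar_raw.get("z_G", 0.51)),
            f_ratio=float(sar_raw.get("f_ratio", 0.5)),
            ag_ratio=float(sar_raw.get("ag_ratio", 0.05)),
        )
    else:
        sar = default_params()
    obj_raw = dict(raw.get("objective", {}))
    _check_keys("objective", obj_raw, _OBJ_KEYS)
    cost_raw = raw.get("costs")
    cost_table = None
    if cost_raw is not None:
        _check_keys("costs", dict(cost_raw), _COST_KEYS)
        cost_table = {_COST_PAIRS[k]: float(v) for k, v in cost_raw.items()}
    caps = {}
    if "degenerate_cap" in obj_raw:
        cap = float(obj_raw["degenerate_cap"])
        caps = {"distance_cap": cap, "adjacency_cap": cap, "cost_cap": cap}
    objective = ObjectiveConfig(
        sar=sar,
        w=float(obj_raw.get("w", 1.0)),
        architecture_mode=obj_raw.get("architecture_mode", "none"),
        cost_table=cost_table,
        **caps,
    )
    rules_raw = dict(raw.get("rules", {}))
    _check_keys("rules", rules_raw, _RULE_KEYS)
    if "allowed_pairs" in rules_raw:
        try:
            pairs = frozenset(_PAIR_NAMES[p] for p in rules_raw["allowed_pairs"])
        except KeyError as e:
            raise ConfigError(f"unknown exchange pair {e}") from None
    else:
        pairs = ALL_PAIRS
    rules = ExchangeRules(
        allowed_pairs=pairs,
        mode=rules_raw.get("mode", "unrestricted"),
        owner_pair=tuple(rules_raw["owner_pair"]) if "owner_pair" in rules_raw else None,
        max_exchanges=rules_raw.get("max_exchanges"),
        once_per_parcel=rules_raw.get("once_per_parcel", "prune_in_search"),
        tie_tol=float(rules_raw.get("tie_tol", 1e-9)),
    )
    limits_raw = dict(raw.get("limits", {}))
    _check_keys("limits", limits_raw, _LIMIT_KEYS)
    limits = SearchLimits(
        node_budget=int(limits_raw.get("node_budget", 1_000_000)),
        on_budget=limits_raw.get("on_budget", "error"),
    )
    return RunConfig(objective=objective, rules=rules, limits=limits, seed=int(raw.get("seed", 0)))


def load_config(path) -> RunConfig:
    """Load and validate YAML or JSON run configuration."""
    text = FsPath(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top-level config must be a mapping")
    return config_from_dict(raw)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def _landscape_codes(landscape: Landscape) -> list[str]:
    return [
        "".join(_EXPORT_CODE[LandState(v)] for v in row) for row in landscape.states
    ]


def _path_record(path: Path, path_id: int, cls: Optional[str], reason: Optional[str], is_global: Optional[bool]):
    return {
        "path_id": path_id,
        "length": path.length,
        "class": cls,
        "deviation_reason": reason,
        "trajectory": list(path.trajectory),
        "terminal": _landscape_codes(path.terminal),
        "terminal_hash": path.terminal.grid_key().hex(),
        "global_optimum": is_global,
        "moves": [
            {
                "step": t + 1,
                "a": list(mv.parcel_a),
                "b": list(mv.parcel_b),
                "states": [mv.state_a.code, mv.state_b.code],
                "delta_B": path.trajectory[t + 1] - path.trajectory[t],
            }
            for t, mv in enumerate(path.moves)
        ],
    }


def result_report(result: SearchResult, classification=None) -> dict:
    """JSON-serializable report of a search (+ optional classification)."""
    from .taxonomy import is_global_optimum

    records = []
    cls_of: dict[int, str] = {}
    reason_of: dict[int, str] = {}
    if classification is not None:
        for p in classification.minimal:
            cls_of[id(p)] = "minimal"
        for p in classification.dominant_minimal:
            cls_of[id(p)] = "dominant_minimal"
        for p in classification.deviants:
            cls_of.setdefault(id(p), "deviant")
            reason_of[id(p)] = classification.deviation_reason.get(id(p), "")
    for i, p in enumerate(result.paths):
        records.append(
            _path_record(
                p, i, cls_of.get(id(p)), reason_of.get(id(p)), is_global_optimum(p.terminal)
            )
        )
    return {
        "schema_version": SCHEMA_VERSION,
        "stats": result.stats,
        "n_paths": result.n_paths,
        "n_distinct_ends": len(result.distinct_ends),
        "paths": records,
    }


def trajectory_frame(paths: list[Path], moves: bool = True) -> pd.DataFrame:
    """Long-form trajectory table (path_id, step, B, move coordinates)."""
    rows = []
    for i, p in enumerate(paths):
        for t, b in enumerate(p.trajectory):
            rec = {"path_id": i, "step": t, "B": b}
            if moves:
                if t > 0:
                    mv = p.moves[t - 1]
                    rec.update(
                        move_a_row=mv.parcel_a[0],
                        move_a_col=mv.parcel_a[1],
                        move_b_row=mv.parcel_b[0],
                        move_b_col=mv.parcel_b[1],
                    )
                else:
                    rec.update(move_a_row=-1, move_a_col=-1, move_b_row=-1, move_b_col=-1)
            rows.append(rec)
    return pd.DataFrame(rows)
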