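"""Readers and writers for microstate systems and titration profiles.

A system file is JSON with optional ``"name"`` and ``"sites"`` keys plus
exactly one of three payloads:

* ``"energies"``: ``{"<bitstring>": g, ...}`` -- per-microstate relative
  free energies in log10 units;
* ``"edges"``: a list of one-proton microconstants,
  ``{"from_state", "to_state", "site_index", "pka"}``;
* ``"model"``: ``{"intrinsic_pka": [...], "coupling": [[...]]}`` --
  pairwise generator parameters.

Edge lists may also come as CSV with columns
``from_state,to_state,site_index,pka`` (states as bitstrings, site 0
leftmost).  All numeric output is serialized with 12 significant digits,
'.' decimal separator and LF line endings, so repeated runs are
byte-identical.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np

from .errors import SchemaError, SizeError
from .generators import PairwiseModel, from_pairwise
from .microstates import (
    DEFAULT_TOLERANCE,
    MicroEquilibrium,
    MicrostateSystem,
    Site,
    as_occupancy,
    bitstring,
    edges_to_energies,
    validate_system,
)
from .site_metrics import TitrationProfile, default_grid

_FMT = "%.12g"  # 12 significant digits


def _fmt(x: float) -> str:
    return _FMT % float(x)


@dataclass
class RunConfig:
    """Numeric defaults shared by the CLI subcommands."""

    pH_min: float = 0.0
    pH_max: float = 14.0
    pH_step: float = 0.1
    tolerance: float = DEFAULT_TOLERANCE
    strict: bool = False
    report_pH: list[float] = field(default_factory=lambda: [7.4])
    output_format: str = "csv"

    def __post_init__(self) -> None:
        if not self.pH_min < self.pH_max:
            raise SchemaError("pH_min must be < pH_max")
        if not self.pH_step > 0:
            raise SchemaError("pH_step must be positive")
        if self.output_format not in ("csv", "json"):
            raise SchemaError("output format must be 'csv' or 'json'")

    @property
    def grid(self) -> np.ndarray:
        return default_grid(self.pH_min, self.pH_max, self.pH_step)

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if not isinstance(raw, dict):
            raise SchemaError("config file must hold a JSON object")
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise SchemaError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


# -- system files ------------------------------------------------------------


def _parse_sites(raw: list | None, n_sites: int) -> Sequence[Site] | int:
    if raw is None:
        return n_sites
    if len(raw) != n_sites:
        raise SchemaError(
            f"'sites' lists {len(raw)} entries but the payload implies {n_sites} sites"
        )
    sites = []
    for i, entry in enumerate(raw):
        if not isinstance(entry, dict):
            raise SchemaError("each site must be a JSON object")
        sites.append(
            Site(
                index=i,
                label=str(entry.get("label", f"G{i + 1}")),
                kind=str(entry.get("kind", "acid")),
                charge_protonated=entry.get("charge_protonated"),
            )
        )
    return sites


def _edges_from_records(records: Iterable[dict]) -> list[MicroEquilibrium]:
    edges = []
    for rec in records:
        try:
            f = as_occupancy(str(rec["from_state"]))
            t = as_occupancy(str(rec["to_state"]))
            pka = float(rec["pka"])
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"bad edge record {rec!r}") from exc
        site = rec.get("site_index")
        if site is None:
            diff = [i for i, (a, b) in enumerate(zip(f, t)) if a != b]
            if len(diff) != 1:
                raise SchemaError(f"edge {rec!r} is not a single bit flip")
            site = diff[0]
        edges.append(MicroEquilibrium(f, t, int(site), pka))
    return edges


def read_edges_csv(path: str) -> list[MicroEquilibrium]:
    """Read an edge list from CSV (columns from_state,to_state,site_index,pka)."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {
            "from_state",
            "to_state",
            "pka",
        } <= set(reader.fieldnames):
            raise SchemaError(
                "edge CSV needs columns from_state,to_state,pka (site_index optional)"
            )
        return _edges_from_records(reader)


def read_system(
    path: str,
    tolerance: float = DEFAULT_TOLERANCE,
    strict: bool = False,
) -> MicrostateSystem:
    """Load a system from a JSON file (or a CSV edge list).

    Dispatches on whichever of ``energies`` / ``edges`` / ``model`` is
    present -- exactly one must be.  The system is validated on the way
    in; in lenient mode (default) the :class:`ConsistencyReport` is
    attached as ``system.consistency_report``, in strict mode a failed
    check raises.
    """
    if os.path.splitext(path)[1].lower() == ".csv":
        edges = read_edges_csv(path)
        system, _ = edges_to_energies(
            edges, tolerance=tolerance, strict=strict,
            name=os.path.splitext(os.path.basename(path))[0],
        )
        return system

    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: top level must be a JSON object")

    payloads = [k for k in ("energies", "edges", "model") if k in raw]
    if len(payloads) != 1:
        raise SchemaError(
            f"{path}: exactly one of 'energies', 'edges', 'model' required, "
            f"found {payloads or 'none'}"
        )
    name = str(raw.get("name", os.path.splitext(os.path.basename(path))[0]))

    if payloads[0] == "energies":
        energies = raw["energies"]
        if not isinstance(energies, dict) or not energies:
            raise SchemaError(f"{path}: 'energies' must be a nonempty object")
        n = len(as_occupancy(next(iter(energies))))
        system = MicrostateSystem(
            _parse_sites(raw.get("sites"), n), energies, name=name, check=False
        )
        validate_system(system, tolerance=tolerance, strict=strict)
        return system

    if payloads[0] == "edges":
        edges = _edges_from_records(raw["edges"])
        n = len(edges[0].from_state) if edges else 0
        sites = _parse_sites(raw.get("sites"), n)
        system, _ = edges_to_energies(
            edges, tolerance=tolerance, strict=strict, name=name,
            sites=None if isinstance(sites, int) else sites,
        )
        return system

    model_raw = raw["model"]
    if not isinstance(model_raw, dict) or "intrinsic_pka" not in model_raw:
        raise SchemaError(f"{path}: 'model' needs at least 'intrinsic_pka'")
    pk = np.asarray(model_raw["intrinsic_pka"], dtype=float)
    coupling = np.asarray(
        model_raw.get("coupling", np.zeros((pk.size, pk.size))), dtype=float
    )
    sites = _parse_sites(raw.get("sites"), pk.size)
    labels = None if isinstance(sites, int) else [s.label for s in sites]
    system = from_pairwise(PairwiseModel(pk, coupling, labels=labels), name=name)
    if not isinstance(sites, int):
        system.sites = tuple(sites)
    validate_system(system, tolerance=tolerance, strict=strict)
    return system


def system_to_dict(system: MicrostateSystem) -> dict:
    """JSON-ready representation of a system in the energies form."""
    return {
        "name": system.name,
        "sites": [
            {
                "label": s.label,
                "kind": s.kind,
                "charge_protonated": s.charge_protonated,
            }
            for s in system.sites
        ],
        "energies": {
            bitstring(state): float(g) for state, g in zip(system.states, system.g)
        },
    }


def write_system(system: MicrostateSystem, path_or_file: str | TextIO) -> None:
    """Write a system as JSON (energies form), deterministically formatted."""
    payload = json.dumps(system_to_dict(system), indent=2, sort_keys=False)
    if isinstance(path_or_file, str):
        with open(path_or_file, "w", newline="\n") as fh:
            fh.write(payload + "\n")
    else:
        path_or_file.write(payload + "\n")


# -- profile tables ----------------------------------------------------------


def write_profiles(
    profiles: Sequence[TitrationProfile],
    nbar_values,
    path_or_file: str | TextIO,
    output_format: str = "csv",
) -> None:
    """Write per-site titration profiles plus the binding curve.

    CSV columns: ``pH, asp_<label>..., paspa_<label>..., nbar``; the JSON
    form holds the same columns as arrays.  All grids must be identical.
    """
    if not profiles:
        raise SizeError("no profiles to write")
    grid = profiles[0].pH_grid
    for p in profiles[1:]:
        if p.pH_grid.shape != grid.shape or not np.array_equal(p.pH_grid, grid):
            raise SizeError("all profiles must share one pH grid")
    nbar_values = np.asarray(nbar_values, dtype=float)
    if nbar_values.shape != grid.shape:
        raise SizeError("nbar length must match the pH grid")

    header = (
        ["pH"]
        + [f"asp_{p.site.label}" for p in profiles]
        + [f"paspa_{p.site.label}" for p in profiles]
        + ["nbar"]
    )
    columns = [grid] + [p.asp for p in profiles] + [p.paspa for p in profiles] + [
        nbar_values
    ]

    if output_format == "json":
        payload = json.dumps(
            {h: [float(_fmt(v)) for v in col] for h, col in zip(header, columns)},
            indent=2,
        )
        if isinstance(path_or_file, str):
            with open(path_or_file, "w", newline="\n") as fh:
                fh.write(payload + "\n")
        else:
            path_or_file.write(payload + "\n")
        return
    if output_format != "csv":
        raise SchemaError("output format must be 'csv' or 'json'")

    lines = [",".join(header)]
    for k in range(grid.size):
        lines.append(",".join(_fmt(col[k]) for col in columns))
    payload = "\n".join(lines) + "\n"
    if isinstance(path_or_file, str):
        with open(path_or_file, "w", newline="\n") as fh:
            fh.write(payload)
    else:
        path_or_file.write(payload)


def read_profiles(path: str) -> dict[str, np.ndarray]:
    """Read a profiles CSV back as a column-name -> array mapping."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        rows = [[float(x) for x in row] for row in reader if row]
    data = np.asarray(rows, dtype=float)
    return {h: data[:, j] for j, h in enumerate(header)}
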