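"""Readers and writers for landmark files (TPS, wide/long CSV) and partitions.

File conventions
----------------
* All on-disk landmark indices are 1-based; the library is 0-based internally.
* TPS: 3D blocks introduced by ``LM3=<count>``, one ``x y z`` line per
  landmark, followed by optional ``ID=`` and ``SCALE=`` records. ``SCALE``
  multiplies coordinates on read. Other ``KEY=`` records are ignored.
* csv_long: columns ``specimen,landmark,x,y,z``; rows may appear in any
  order — landmarks are re-ordered by landmark id (numerically when all ids
  are numeric) consistently across specimens, specimens keep their order of
  first appearance.
* csv_wide: a ``specimen`` column followed by ``x1,y1,z1,x2,...``.
* Partition files: JSON mapping ``name -> [indices or "a-b" ranges]`` (1-based)
  or a two-column CSV ``landmark_id,partition_name``.

Missing landmarks are not supported: NA or the 9999 sentinel raise a hard
error, because every downstream statistic assumes complete configurations.

Floats are written with 17 significant digits so read(write(s)) round-trips
bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import Configuration, MorphovarError, Partition, Sample, StructuralError
from .types import remainder_partition

__all__ = ["read_landmarks", "write_landmarks", "read_partitions", "write_partitions"]

logger = logging.getLogger(__name__)

_FORMATS = ("tps", "csv_wide", "csv_long")
_SENTINEL = 9999.0


class ParseError(MorphovarError):
    """Malformed file content; carries the offending line number when known."""


def _check_value(v: float, where: str) -> float:
    if not np.isfinite(v):
        raise ParseError(f"{where}: non-finite coordinate (missing-data markers are not supported)")
    if abs(v) == _SENTINEL:
        raise ParseError(f"{where}: sentinel value {v:g} — missing landmarks are not supported")
    return v


def _parse_float(token: str, where: str) -> float:
    try:
        v = float(token)
    except ValueError:
        raise ParseError(f"{where}: non-numeric coordinate {token!r}") from None
    return _check_value(v, where)


def read_landmarks(path: str | Path, format: str | None = None) -> Sample:
    """Read a landmark file into a validated :class:`Sample`.

    ``format`` is one of ``tps``, ``csv_wide``, ``csv_long``; if None it is
    inferred from the extension (``.tps`` / ``.csv`` is ambiguous between the
    two CSV dialects, so CSVs require an explicit format).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        if path.suffix.lower() == ".tps":
            format = "tps"
        else:
            raise MorphovarError(
                f"cannot infer dialect of {path.name}: pass format= one of {_FORMATS}"
            )
    if format not in _FORMATS:
        raise MorphovarError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if format == "tps":
        return _read_tps(path)
    if format == "csv_wide":
        return _read_csv_wide(path)
    return _read_csv_long(path)


def write_landmarks(sample: Sample, path: str | Path, format: str) -> Path:
    """Write ``sample`` to ``path`` in the given dialect (inverse of read)."""
    if format not in _FORMATS:
        raise MorphovarError(f"unknown format {format!r}; expected one of {_FORMATS}")
    path = Path(path)
    if format == "tps":
        _write_tps(sample, path)
    elif format == "csv_wide":
        _write_csv_wide(sample, path)
    else:
        _write_csv_long(sample, path)
    return path


# --- TPS ---------------------------------------------------------------

_TPS_KEY = re.compile(r"^([A-Za-z0-9_]+)\s*=\s*(.*)$")


def _read_tps(path: Path) -> Sample:
    configs: list[Configuration] = []
    cur_coords: list[list[float]] | None = None
    cur_n = 0
    cur_id: str | None = None
    cur_scale = 1.0
    anon = 0

    def flush(lineno: int) -> None:
        nonlocal cur_coords, cur_n, cur_id, cur_scale, anon
        if cur_coords is None:
            return
        if len(cur_coords) != cur_n:
            sid = cur_id if cur_id is not None else f"<specimen {len(configs) + 1}>"
            raise StructuralError(
                f"{path.name}: specimen {sid}: LM3={cur_n} but "
                f"{len(cur_coords)} coordinate lines (near line {lineno})"
            )
        if cur_id is None:
            anon += 1
            cur_id = f"specimen_{anon}"
        coords = np.asarray(cur_coords, dtype=float) * cur_scale
        configs.append(Configuration(cur_id, coords))
        cur_coords, cur_n, cur_id, cur_scale = None, 0, None, 1.0

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            m = _TPS_KEY.match(line)
            if m:
                key, value = m.group(1).upper(), m.group(2).strip()
                if key == "LM3":
                    flush(lineno)
                    try:
                        cur_n = int(value)
                    except ValueError:
                        raise ParseError(f"{path.name}:{lineno}: bad LM3 count {value!r}") from None
                    cur_coords = []
                elif key == "LM":
                    raise StructuralError(
                        f"{path.name}:{lineno}: 2D TPS (LM=) not supported; expected LM3="
                    )
                elif key == "ID":
                    if cur_coords is None:
                        raise ParseError(f"{path.name}:{lineno}: ID= before any LM3= block")
                    cur_id = value
                elif key == "SCALE":
                    if cur_coords is None:
                        raise ParseError(f"{path.name}:{lineno}: SCALE= before any LM3= block")
                    cur_scale = _parse_float(value, f"{path.name}:{lineno}")
                # other keys (IMAGE=, COMMENT=...) are ignored
                continue
            if cur_coords is None:
                raise ParseError(f"{path.name}:{lineno}: coordinates before any LM3= record")
            tokens = line.split()
            if len(tokens) != 3:
                raise ParseError(
                    f"{path.name}:{lineno}: expected 3 coordinates, got {len(tokens)}"
                )
            cur_coords.append([_parse_float(t, f"{path.name}:{lineno}") for t in tokens])
    flush(lineno if "lineno" in locals() else 0)
    if not configs:
        raise StructuralError(f"{path.name}: no LM3 blocks found")
    return Sample(configs)


def _write_tps(sample: Sample, path: Path) -> None:
    with open(path, "w") as fh:
        for c in sample.configurations:
            fh.write(f"LM3={c.n_landmarks}\n")
            for x, y, z in c.coords:
                fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
            fh.write(f"ID={c.specimen_id}\n")


# --- CSV dialects ------------------------------------------------------


def _read_csv_wide(path: Path) -> Sample:
    df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    if df.shape[1] < 13 or (df.shape[1] - 1) % 3 != 0:
        raise StructuralError(
            f"{path.name}: wide CSV needs a specimen column plus 3 columns per "
            f"landmark (≥ 4 landmarks); got {df.shape[1]} columns"
        )
    spec_col = df.columns[0]
    coord_cols = df.columns[1:]
    L = len(coord_cols) // 3
    expected = [f"{a}{i}" for i in range(1, L + 1) for a in ("x", "y", "z")]
    if list(coord_cols) != expected:
        raise StructuralError(
            f"{path.name}: wide CSV columns must be x1,y1,z1,...,x{L},y{L},z{L}"
        )
    vals = df[coord_cols].to_numpy()
    try:
        vals = vals.astype(float)
    except ValueError as e:
        raise ParseError(f"{path.name}: non-numeric coordinate ({e})") from None
    configs = []
    for i, sid in enumerate(df[spec_col]):
        row = vals[i]
        for v in row:
            _check_value(v, f"{path.name}: specimen {sid!r}")
        configs.append(Configuration(str(sid), row.reshape(L, 3)))
    return Sample(configs)


def _write_csv_wide(sample: Sample, path: Path) -> None:
    L = sample.n_landmarks
    cols = [f"{a}{i}" for i in range(1, L + 1) for a in ("x", "y", "z")]
    with open(path, "w") as fh:
        fh.write("specimen," + ",".join(cols) + "\n")
        for c in sample.configurations:
            flat = c.coords.reshape(-1)
            fh.write(str(c.specimen_id) + "," + ",".join(f"{v:.17g}" for v in flat) + "\n")


def _landmark_sort_key(ids: Sequence[str]):
    if all(re.fullmatch(r"-?\d+", i) for i in ids):
        return lambda i: int(i)
    return lambda i: i


def _read_csv_long(path: Path) -> Sample:
    df = pd.read_csv(
        path, dtype={"specimen": str, "landmark": str}, float_precision="round_trip"
    )
    required = ["specimen", "landmark", "x", "y", "z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise StructuralError(f"{path.name}: long CSV missing columns {missing}")
    for axis in "xyz":
        if not np.issubdtype(df[axis].dtype, np.number):
            bad = df.loc[pd.to_numeric(df[axis], errors="coerce").isna(), axis]
            raise ParseError(
                f"{path.name}: non-numeric {axis} value {bad.iloc[0]!r} "
                f"(row {bad.index[0] + 2})"
            )
    for v in df[["x", "y", "z"]].to_numpy().ravel():
        _check_value(float(v), f"{path.name}")
    specimens = list(dict.fromkeys(df["specimen"]))  # order of first appearance
    landmark_ids = sorted(set(df["landmark"]), key=_landmark_sort_key(set(df["landmark"])))
    pivot = df.set_index(["specimen", "landmark"])
    if pivot.index.has_duplicates:
        dup = pivot.index[pivot.index.duplicated()][0]
        raise StructuralError(f"{path.name}: duplicate row for {dup}")
    configs = []
    for sid in specimens:
        sub = df[df["specimen"] == sid].set_index("landmark")
        missing_lm = [l for l in landmark_ids if l not in sub.index]
        if missing_lm:
            raise StructuralError(
                f"{path.name}: specimen {sid!r} is missing landmarks {missing_lm[:5]}"
            )
        coords = sub.loc[landmark_ids, ["x", "y", "z"]].to_numpy(dtype=float)
        configs.append(Configuration(sid, coords, landmark_ids))
    return Sample(configs)


def _write_csv_long(sample: Sample, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("specimen,landmark,x,y,z\n")
        for c in sample.configurations:
            for lid, (x, y, z) in zip(c.landmark_ids, c.coords):
                fh.write(f"{c.specimen_id},{lid},{x:.17g},{y:.17g},{z:.17g}\n")


# --- Partitions --------------------------------------------------------

_RANGE = re.compile(r"^(\d+)\s*-\s*(\d+)$")


def _expand_indices(entries, name: str) -> np.ndarray:
    """1-based ints or 'a-b' range strings -> 0-based index array."""
    out: list[int] = []
    for e in entries:
        if isinstance(e, str):
            m = _RANGE.match(e.strip())
            if not m:
                raise ParseError(f"partition {name!r}: bad index entry {e!r}")
            a, b = int(m.group(1)), int(m.group(2))
            if b < a:
                raise ParseError(f"partition {name!r}: inverted range {e!r}")
            out.extend(range(a - 1, b))
        else:
            if not float(e).is_integer():
                raise ParseError(f"partition {name!r}: non-integer index {e!r}")
            i = int(e)
            if i < 1:
                raise ParseError(f"partition {name!r}: index {i} < 1 (file indices are 1-based)")
            out.append(i - 1)
    return np.asarray(out, dtype=int)


def read_partitions(
    path: str | Path,
    n_landmarks: int | None = None,
    auto_remainder: bool = False,
    remainder_name: str = "remainder",
) -> list[Partition]:
    """Read a partition battery from JSON or two-column CSV.

    Indices in the file are 1-based. Overlap between partitions is permitted
    but logged. With ``auto_remainder`` (requires ``n_landmarks``) a partition
    covering the unassigned landmarks is appended, unless nothing remains.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            spec = json.load(fh)
        if not isinstance(spec, dict):
            raise ParseError(f"{path.name}: expected a JSON object name -> indices")
        parts = [Partition(str(k), _expand_indices(v, str(k))) for k, v in spec.items()]
    else:
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        if "landmark_id" not in cols or "partition_name" not in cols:
            raise StructuralError(
                f"{path.name}: partition CSV needs columns landmark_id,partition_name"
            )
        parts = []
        for name, grp in df.groupby(cols["partition_name"], sort=False):
            parts.append(Partition(str(name), _expand_indices(grp[cols["landmark_id"]], str(name))))
    if not parts:
        raise StructuralError(f"{path.name}: no partitions defined")
    if n_landmarks is not None:
        for p in parts:
            p.validate_against(n_landmarks)
    seen: dict[int, str] = {}
    for p in parts:
        overlap = [i for i in p.indices if i in seen]
        if overlap:
            logger.warning(
                "partition %r overlaps %r on %d landmark(s)",
                p.name, seen[overlap[0]], len(overlap),
            )
        for i in p.indices:
            seen.setdefault(int(i), p.name)
    if auto_remainder:
        if n_landmarks is None:
            raise MorphovarError("auto_remainder requires n_landmarks")
        rem = remainder_partition(parts, n_landmarks, remainder_name)
        if rem is not None:
            parts.append(rem)
    return parts


def write_partitions(partitions: Sequence[Partition], path: str | Path) -> Path:
    """Write partitions as JSON (1-based indices)."""
    path = Path(path)
    payload = {p.name: [int(i) + 1 for i in p.indices] for p in partitions}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
    return path
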