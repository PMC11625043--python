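"""File formats and validated containers for atlases, time series and cohorts.

All on-disk formats are tab-delimited UTF-8 text with a single header line.
Time-series matrices additionally support a flat little-endian float64 binary
dialect; both dialects carry a JSON sidecar naming the subject and the matrix
shape. Vertex indexing is 0-based everywhere and the row order of a time-series
matrix is the row order of the atlas file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, ShapeError

HEMISPHERES = ("L", "R")
#: The seven task-relevant resting-state networks; NONE marks vertices outside them.
NETWORKS = ("SMN", "AUD", "LAN", "DAN", "CON", "FPN", "DMN")
NETWORK_TOKENS = NETWORKS + ("NONE",)
GROUPS = ("YNM", "OM", "ONM")
GENDERS = ("F", "M")

_ATLAS_COLUMNS = ["vertex_id", "hemisphere", "pair_id", "network"]

#: Float format used by every text writer; round-trips IEEE doubles exactly.
FLOAT_FMT = "%.17g"

COHORT_NUMERIC_FIELDS = [
    "age",
    "education",
    "hearing",
    "moca",
    "digit_span",
    "stroop",
    "mfd",
    "mean_global_fc",
    "sin_threshold",
    "sis_threshold",
    "training_onset",
    "training_years",
]
#: Fields that may legitimately be absent (NA) for some subjects.
COHORT_OPTIONAL_FIELDS = {"moca", "training_onset", "training_years"}
COHORT_COLUMNS = ["subject_id", "group", "gender"] + COHORT_NUMERIC_FIELDS


@dataclass(frozen=True)
class HomotopicAtlas:
    """Vertex registry with hemisphere labels, homotopic bijection and network labels.

    Parameters
    ----------
    vertex_id, hemisphere, pair_id, network
        Per-vertex arrays in file (= time-series row) order. ``pair_id`` links
        each vertex to its mirror-symmetric partner in the other hemisphere;
        the pairing must be a bijection. ``network`` is one of the seven
        network tokens or ``NONE``.
    """

    vertex_id: np.ndarray
    hemisphere: np.ndarray
    pair_id: np.ndarray
    network: np.ndarray
    #: index (row position) of each vertex's homotopic partner
    partner_index: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        vid = np.asarray(self.vertex_id, dtype=np.int64)
        hemi = np.asarray(self.hemisphere, dtype=object)
        pid = np.asarray(self.pair_id, dtype=np.int64)
        net = np.asarray(self.network, dtype=object)
        for name, arr in (("vertex_id", vid), ("hemisphere", hemi), ("pair_id", pid), ("network", net)):
            if arr.shape != vid.shape:
                raise ShapeError(f"atlas column {name!r} has mismatched length")
        bad_h = set(hemi) - set(HEMISPHERES)
        if bad_h:
            raise ValueError(f"unknown hemisphere token(s): {sorted(bad_h)}")
        bad_n = set(net) - set(NETWORK_TOKENS)
        if bad_n:
            raise ValueError(f"unknown network token(s): {sorted(bad_n)}")
        if len(np.unique(vid)) != len(vid):
            raise IntegrityError("vertex_id values are not unique")
        # bijection: every pair_id exactly twice, once per hemisphere
        partner = np.full(len(vid), -1, dtype=np.int64)
        by_pair: dict[int, list[int]] = {}
        for i, p in enumerate(pid):
            by_pair.setdefault(int(p), []).append(i)
        for p, members in by_pair.items():
            if len(members) != 2:
                raise IntegrityError(f"pair_id {p} occurs {len(members)} time(s), expected 2")
            a, b = members
            if {hemi[a], hemi[b]} != {"L", "R"}:
                raise IntegrityError(f"pair_id {p} does not span both hemispheres")
            partner[a], partner[b] = b, a
        object.__setattr__(self, "vertex_id", vid)
        object.__setattr__(self, "hemisphere", hemi)
        object.__setattr__(self, "pair_id", pid)
        object.__setattr__(self, "network", net)
        object.__setattr__(self, "partner_index", partner)

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_id)

    @property
    def n_pairs(self) -> int:
        return self.n_vertices // 2

    @property
    def left_mask(self) -> np.ndarray:
        return self.hemisphere == "L"

    @property
    def right_mask(self) -> np.ndarray:
        return self.hemisphere == "R"

    def pairs(self) -> pd.DataFrame:
        """One row per homotopic pair, sorted by pair_id.

        Columns: pair_id, left_index, right_index (row positions), network_left,
        network_right, and ``network_valid`` — true iff both members carry the
        same network label and that label is not NONE.
        """
        left = np.flatnonzero(self.left_mask)
        order = np.argsort(self.pair_id[left], kind="stable")
        li = left[order]
        ri = self.partner_index[li]
        net_l = self.network[li]
        net_r = self.network[ri]
        return pd.DataFrame(
            {
                "pair_id": self.pair_id[li],
                "left_index": li,
                "right_index": ri,
                "network_left": net_l,
                "network_right": net_r,
                "network_valid": (net_l == net_r) & (net_l != "NONE"),
            }
        )

    def swap_hemispheres(self) -> "HomotopicAtlas":
        """Return the atlas with every L relabelled R and vice versa."""
        flipped = np.where(self.hemisphere == "L", "R", "L").astype(object)
        return HomotopicAtlas(self.vertex_id.copy(), flipped, self.pair_id.copy(), self.network.copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "vertex_id": self.vertex_id,
                "hemisphere": self.hemisphere,
                "pair_id": self.pair_id,
                "network": self.network,
            }
        )


@dataclass(frozen=True)
class TimeSeries:
    """Per-subject vertex x time matrix of preprocessed BOLD-like signal."""

    subject_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ShapeError("time series must be a 2-D matrix (vertices x timepoints)")
        if v.shape[1] < 3:
            raise ShapeError("time series needs at least 3 timepoints")
        if not np.isfinite(v).all():
            raise ValueError(f"time series for {self.subject_id!r} contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


class CohortTable:
    """Subject table: group membership, covariates and behavioral scores."""

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in COHORT_COLUMNS if c not in table.columns]
        if missing:
            raise FormatError(f"cohort table missing column(s): {missing}")
        t = table.loc[:, COHORT_COLUMNS].copy().reset_index(drop=True)
        if t["subject_id"].duplicated().any():
            dup = t.loc[t["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise IntegrityError(f"duplicate subject_id {dup!r}")
        bad_g = set(t["group"]) - set(GROUPS)
        if bad_g:
            raise ValueError(f"unknown group token(s): {sorted(bad_g)}")
        bad_s = set(t["gender"]) - set(GENDERS)
        if bad_s:
            raise ValueError(f"unknown gender token(s): {sorted(bad_s)}")
        for col in COHORT_NUMERIC_FIELDS:
            try:
                t[col] = _exact_floats(t[col])
            except (ValueError, TypeError) as exc:
                raise ValueError(f"cohort column {col!r} is not numeric: {exc}") from exc
            if col not in COHORT_OPTIONAL_FIELDS and t[col].isna().any():
                raise ValueError(f"cohort column {col!r} has missing values")
            if np.isinf(t[col].to_numpy(dtype=float)).any():
                raise ValueError(f"cohort column {col!r} has non-finite values")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    def groups(self) -> dict[str, pd.DataFrame]:
        return {g: sub for g, sub in self.table.groupby("group", sort=False)}

    def subjects(self, group: str | None = None) -> list[str]:
        t = self.table if group is None else self.table[self.table["group"] == group]
        return list(t["subject_id"])


# ---------------------------------------------------------------------------
# readers / writers


def _exact_floats(column: pd.Series) -> np.ndarray:
    """Parse decimal strings with Python's exact strtod (pandas' parser can be off by 1 ulp)."""
    return np.array(
        [np.nan if v is None or (isinstance(v, float) and np.isnan(v)) else float(v) for v in column],
        dtype=float,
    )


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas detail
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return df


def load_atlas(path: str | Path) -> HomotopicAtlas:
    """Read and validate a tab-delimited atlas file."""
    df = _read_tsv(path, _ATLAS_COLUMNS)
    try:
        vid = pd.to_numeric(df["vertex_id"], errors="raise").astype(np.int64)
        pid = pd.to_numeric(df["pair_id"], errors="raise").astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-integer id column: {exc}") from exc
    return HomotopicAtlas(
        vid.to_numpy(), df["hemisphere"].to_numpy(dtype=object), pid.to_numpy(), df["network"].to_numpy(dtype=object)
    )


def write_atlas(atlas: HomotopicAtlas, path: str | Path) -> None:
    atlas.to_frame().to_csv(path, sep="\t", index=False)


def load_cohort(path: str | Path) -> CohortTable:
    df = _read_tsv(path, COHORT_COLUMNS)
    df = df.replace({"NA": None})
    return CohortTable(df)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    out = cohort.table.copy()
    for col in COHORT_NUMERIC_FIELDS:
        out[col] = [("NA" if pd.isna(v) else FLOAT_FMT % v) for v in out[col]]
    out.to_csv(path, sep="\t", index=False)


def _sidecar_path(path: Path) -> Path:
    # S001.ts.tsv -> S001.ts.json ; S001.ts.bin -> S001.ts.json
    return path.with_suffix(".json")


def write_timeseries(ts: TimeSeries, path: str | Path, dialect: str = "text") -> None:
    """Write a time-series matrix plus its JSON sidecar.

    ``dialect='text'`` writes a headerless tab-delimited matrix (%.17g, exact
    round trip); ``dialect='binary'`` writes flat little-endian float64,
    row-major.
    """
    path = Path(path)
    if dialect == "text":
        np.savetxt(path, ts.values, fmt=FLOAT_FMT, delimiter="\t")
    elif dialect == "binary":
        ts.values.astype("<f8").tofile(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    sidecar = {
        "subject_id": ts.subject_id,
        "n_vertices": ts.n_vertices,
        "n_timepoints": ts.n_timepoints,
        "dialect": dialect,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=0) + "\n")


def load_timeseries(path: str | Path, atlas: HomotopicAtlas) -> TimeSeries:
    """Load a time-series matrix, checking its shape against the atlas."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    side_path = _sidecar_path(path)
    if not side_path.exists():
        raise FormatError(f"missing sidecar {side_path}")
    side = json.loads(side_path.read_text())
    for key in ("subject_id", "n_vertices", "n_timepoints"):
        if key not in side:
            raise FormatError(f"{side_path}: sidecar missing {key!r}")
    n_v, n_t = int(side["n_vertices"]), int(side["n_timepoints"])
    if side.get("dialect", "text") == "binary" or path.suffix == ".bin":
        values = np.fromfile(path, dtype="<f8")
        if values.size != n_v * n_t:
            raise ShapeError(f"{path}: {values.size} values, sidecar promises {n_v}x{n_t}")
        values = values.reshape(n_v, n_t)
    else:
        values = np.loadtxt(path, delimiter="\t", ndmin=2)
        if values.shape != (n_v, n_t):
            raise ShapeError(f"{path}: matrix is {values.shape}, sidecar promises {(n_v, n_t)}")
    if values.shape[0] != atlas.n_vertices:
        raise ShapeError(
            f"{path}: {values.shape[0]} rows but atlas has {atlas.n_vertices} vertices"
        )
    if not np.isfinite(values).all():
        raise ValueError(f"{path}: non-finite entries")
    return TimeSeries(str(side["subject_id"]), values)


def load_fd(path: str | Path) -> np.ndarray:
    """Read a framewise-displacement trace (one 'fd_mm' column, mm per frame)."""
    df = _read_tsv(path, ["fd_mm"])
    fd = _exact_floats(df["fd_mm"])
    if (fd < 0).any() or not np.isfinite(fd).all():
        raise ValueError(f"{path}: FD values must be finite and non-negative")
    return fd


def write_fd(fd: np.ndarray, path: str | Path) -> None:
    lines = ["fd_mm"] + [FLOAT_FMT % v for v in np.asarray(fd, dtype=float)]
    Path(path).write_text("\n".join(lines) + "\n")
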