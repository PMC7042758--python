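"""Input tables: marking-group assignment, wintering-area assignment, and CSV I/O.

The normal entry point for users with already-tabulated data is the trio of
``read_*``/``write_*`` functions plus the validated container types
(:class:`ReencounterData`, :class:`IsotopeData`, :class:`ParasiteData`).
Users holding raw per-bird records instead go through :func:`assign_group`,
:func:`assign_wintering_area`, :func:`filter_wintering_reencounters` and
:func:`build_reencounter_matrices`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import AreaBoundaries, GroupingRules

__all__ = [
    "AgeClass",
    "GroupLabel",
    "WinteringArea",
    "RingingRecord",
    "ReencounterData",
    "IsotopeData",
    "ParasiteData",
    "SchemaError",
    "UnassignableRecordError",
    "assign_group",
    "assign_wintering_area",
    "filter_wintering_reencounters",
    "build_reencounter_matrices",
    "read_reencounters",
    "write_reencounters",
    "read_isotopes",
    "write_isotopes",
    "read_parasites",
    "write_parasites",
    "GROUPS",
    "AREAS",
    "POPULATIONS",
    "POPULATION_INDICES",
    "DEFAULT_LINEAGES",
]


class SchemaError(ValueError):
    """A table violates its documented column schema or an invariant."""


class UnassignableRecordError(ValueError):
    """No marking group is defined for this record."""


class AgeClass(str, Enum):
    chick = "chick"
    full_grown = "full_grown"


class GroupLabel(str, Enum):
    """The eight marking groups (region x season); index order is fixed."""

    SWE = "SWE"
    FIN = "FIN"
    Central_spring = "Central_spring"
    Central_breeding = "Central_breeding"
    Central_autumn = "Central_autumn"
    Southern_spring = "Southern_spring"
    Southern_breeding = "Southern_breeding"
    Southern_autumn = "Southern_autumn"

    @property
    def index(self) -> int:
        return GROUPS.index(self)

    @property
    def is_population(self) -> bool:
        """True for groups of known breeding origin."""
        return self in POPULATIONS


class WinteringArea(str, Enum):
    Western = "Western"
    Central = "Central"
    Eastern = "Eastern"
    Southern = "Southern"

    @property
    def index(self) -> int:
        return AREAS.index(self)


GROUPS: tuple[GroupLabel, ...] = tuple(GroupLabel)
AREAS: tuple[WinteringArea, ...] = tuple(WinteringArea)
#: Groups of known breeding origin sharing rows with the isotope and parasite
#: models (Northern, Central-breeding, Southern-breeding).
POPULATIONS: tuple[GroupLabel, ...] = (
    GroupLabel.SWE,
    GroupLabel.Central_breeding,
    GroupLabel.Southern_breeding,
)
POPULATION_INDICES: tuple[int, ...] = tuple(g.index for g in POPULATIONS)
DEFAULT_LINEAGES: tuple[str, ...] = ("SYBOR21", "GRW02", "GRW09", "LINOLI1", "PSEGRI1")

_REGIONS = ("Sweden", "Finland", "NorthernGermany", "SouthernGermanySwitzerland")


@dataclass(frozen=True)
class RingingRecord:
    """One marked bird, optionally with its first wintering-area reencounter."""

    ring_id: str
    scheme: str
    ringing_date: date
    ringing_lat: float
    ringing_lon: float
    age_at_ringing: AgeClass
    reencounter_date: date | None = None
    reencounter_lat: float | None = None
    reencounter_lon: float | None = None

    def __post_init__(self):
        for lat in (self.ringing_lat, self.reencounter_lat):
            if lat is not None and not -90.0 <= lat <= 90.0:
                raise ValueError(f"latitude out of range: {lat}")
        for lon in (self.ringing_lon, self.reencounter_lon):
            if lon is not None and not -180.0 <= lon <= 180.0:
                raise ValueError(f"longitude out of range: {lon}")
        if self.reencounter_date is not None and self.reencounter_date < self.ringing_date:
            raise ValueError(
                f"ring {self.ring_id}: reencounter date {self.reencounter_date} "
                f"precedes ringing date {self.ringing_date}"
            )


def assign_group(
    record: RingingRecord,
    region: str,
    rules: GroupingRules | None = None,
) -> GroupLabel:
    """Map a record to one of the eight marking groups.

    Swedish and Finnish records are not split seasonally. German/Swiss records
    are split into spring (full-grown, Mar-May), breeding (chicks plus
    full-grown Jun-Jul) and autumn (chicks and full-grown Aug-Oct) groups, with
    the Central/Southern prefix decided by the 52N latitude split
    (north-inclusive).

    Raises :class:`UnassignableRecordError` for full-grown German/Swiss birds
    ringed November-February, for which no group is defined.
    """
    rules = rules or GroupingRules()
    if region not in _REGIONS:
        raise ValueError(f"unknown marking region {region!r}; expected one of {_REGIONS}")
    if region == "Sweden":
        return GroupLabel.SWE
    if region == "Finland":
        return GroupLabel.FIN

    prefix = "Central" if record.ringing_lat >= rules.lat_split else "Southern"
    month = record.ringing_date.month
    if record.age_at_ringing is AgeClass.chick:
        if rules.chicks_follow_autumn and month in rules.autumn_months:
            season = "autumn"
        else:
            season = "breeding"
    elif month in rules.spring_months:
        season = "spring"
    elif month in rules.breeding_months:
        season = "breeding"
    elif month in rules.autumn_months:
        season = "autumn"
    else:
        raise UnassignableRecordError(
            f"ring {record.ring_id}: full-grown bird ringed in month {month} "
            "has no defined marking group"
        )
    return GroupLabel(f"{prefix}_{season}")


def assign_wintering_area(
    lat: float,
    lon: float,
    boundaries: AreaBoundaries | None = None,
) -> WinteringArea | None:
    """Map a coordinate to a wintering area, or ``None`` if outside the domain.

    Rectangles with half-open boundaries, southern/western side inclusive.
    """
    b = boundaries or AreaBoundaries()
    if not -90.0 <= lat <= 90.0 or not -180.0 <= lon <= 180.0:
        raise ValueError(f"invalid coordinate ({lat}, {lon})")
    if lat > b.sahara_lat:
        return None
    if lat <= b.southern_lat:
        return WinteringArea.Southern
    if lon <= b.west_central_lon:
        return WinteringArea.Western
    if lon <= b.rift_lon:
        return WinteringArea.Central
    return WinteringArea.Eastern


def filter_wintering_reencounters(
    records: Iterable[RingingRecord],
    boundaries: AreaBoundaries | None = None,
    rules: GroupingRules | None = None,
) -> list[RingingRecord]:
    """Keep records reencountered Nov-Feb inside one of the four areas."""
    rules = rules or GroupingRules()
    kept = []
    for rec in records:
        if rec.reencounter_date is None or rec.reencounter_lat is None:
            continue
        if rec.reencounter_date.month not in rules.winter_months:
            continue
        area = assign_wintering_area(rec.reencounter_lat, rec.reencounter_lon, boundaries)
        if area is not None:
            kept.append(rec)
    return kept


def _as_count_matrix(x, shape, name) -> np.ndarray:
    arr = np.asarray(x)
    if arr.shape != shape:
        raise SchemaError(f"{name} must have shape {shape}, got {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise SchemaError(f"{name} contains non-integer counts")
        arr = np.round(arr).astype(np.int64)
    else:
        arr = arr.astype(np.int64)
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise SchemaError(f"{name}[{i},{j}] is negative ({arr[i, j]})")
    return arr


@dataclass
class ReencounterData:
    """Ring-reencounter count matrices for the eight marking groups.

    ``R_ad_known``/``R_juv_known`` are 8x5 (four areas plus the
    never-reencountered column) with row sums equal to the numbers ringed
    ``N_ad``/``N_juv``. ``R_ad_unknown``/``R_juv_unknown`` are 8x4 counts for
    marking periods without known ringing totals; all-zero rows contribute no
    likelihood and are exposed via :attr:`zero_unknown_rows`.
    """

    R_ad_known: np.ndarray
    R_juv_known: np.ndarray
    N_ad: np.ndarray
    N_juv: np.ndarray
    R_ad_unknown: np.ndarray
    R_juv_unknown: np.ndarray

    def __post_init__(self):
        n = len(GROUPS)
        self.R_ad_known = _as_count_matrix(self.R_ad_known, (n, 5), "R_ad_known")
        self.R_juv_known = _as_count_matrix(self.R_juv_known, (n, 5), "R_juv_known")
        self.R_ad_unknown = _as_count_matrix(self.R_ad_unknown, (n, 4), "R_ad_unknown")
        self.R_juv_unknown = _as_count_matrix(self.R_juv_unknown, (n, 4), "R_juv_unknown")
        self.N_ad = _as_count_matrix(self.N_ad, (n,), "N_ad")
        self.N_juv = _as_count_matrix(self.N_juv, (n,), "N_juv")
        for R, N, name in (
            (self.R_ad_known, self.N_ad, "ad"),
            (self.R_juv_known, self.N_juv, "juv"),
        ):
            sums = R.sum(axis=1)
            bad = np.nonzero(sums != N)[0]
            if bad.size:
                i = bad[0]
                raise SchemaError(
                    f"known-total {name} row {GROUPS[i].value}: counts sum to "
                    f"{sums[i]} but N={N[i]}"
                )

    @property
    def zero_unknown_rows(self) -> dict[str, np.ndarray]:
        """Boolean masks of unknown-total rows carrying no information."""
        return {
            "ad": self.R_ad_unknown.sum(axis=1) == 0,
            "juv": self.R_juv_unknown.sum(axis=1) == 0,
        }

    @property
    def total_reencounters(self) -> int:
        return int(
            self.R_ad_known[:, :4].sum()
            + self.R_juv_known[:, :4].sum()
            + self.R_ad_unknown.sum()
            + self.R_juv_unknown.sum()
        )


@dataclass
class IsotopeData:
    """Per-individual feather (d13C, d15N) pairs with population labels.

    ``values`` holds raw per-mil measurements; ``standardized`` the z-scored
    copy used by the likelihood. ``pop`` indexes into
    :data:`POPULATIONS` (0 = Northern, 1 = Central, 2 = Southern).
    """

    values: np.ndarray
    pop: np.ndarray
    standardized: np.ndarray = field(default=None)  # type: ignore[assignment]
    standardization_constants: tuple[np.ndarray, np.ndarray] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 2:
            raise SchemaError(f"isotope values must be n x 2, got {self.values.shape}")
        if self.values.shape[0] == 0:
            raise SchemaError("isotope table has no rows")
        if not np.isfinite(self.values).all():
            raise SchemaError("isotope values contain non-finite entries")
        self.pop = np.asarray(self.pop, dtype=np.int64)
        if self.pop.shape != (self.values.shape[0],):
            raise SchemaError("pop indicator length mismatch")
        if self.pop.min() < 0 or self.pop.max() >= len(POPULATIONS):
            raise SchemaError("pop indicator out of range 0..2")
        if self.standardized is None:
            mean = self.values.mean(axis=0)
            sd = self.values.std(axis=0, ddof=1)
            if (sd == 0).any():
                raise SchemaError("cannot standardize a zero-variance isotope column")
            self.standardized = (self.values - mean) / sd
            self.standardization_constants = (mean, sd)
        else:
            self.standardized = np.asarray(self.standardized, dtype=float)
            if self.standardization_constants is None:
                self.standardization_constants = (np.zeros(2), np.ones(2))

    @classmethod
    def from_standardized(cls, standardized: np.ndarray, pop: np.ndarray) -> "IsotopeData":
        """Wrap already-standardized values (constants become identity)."""
        standardized = np.asarray(standardized, dtype=float)
        return cls(
            values=standardized,
            pop=pop,
            standardized=standardized,
            standardization_constants=(np.zeros(2), np.ones(2)),
        )

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class ParasiteData:
    """Infection count tables: wintering areas x lineages and populations x lineages."""

    G_nb: np.ndarray
    H_nb: np.ndarray
    G_b: np.ndarray
    H_b: np.ndarray
    lineage_names: tuple[str, ...] = DEFAULT_LINEAGES

    def __post_init__(self):
        L = len(self.lineage_names)
        if L != 5:
            raise SchemaError(f"expected 5 parasite lineages, got {L}")
        self.G_nb = _as_count_matrix(self.G_nb, (4, L), "G_nb")
        self.H_nb = _as_count_matrix(self.H_nb, (4, L), "H_nb")
        self.G_b = _as_count_matrix(self.G_b, (3, L), "G_b")
        self.H_b = _as_count_matrix(self.H_b, (3, L), "H_b")
        self.lineage_names = tuple(self.lineage_names)
        for G, H, name in ((self.G_nb, self.H_nb, "nb"), (self.G_b, self.H_b, "b")):
            bad = np.argwhere(G > H)
            if bad.size:
                i, j = bad[0]
                raise SchemaError(
                    f"{name} cell ({i},{self.lineage_names[j]}): infected "
                    f"{G[i, j]} exceeds sampled {H[i, j]}"
                )


def build_reencounter_matrices(
    records: Sequence[RingingRecord],
    groups: Sequence[GroupLabel],
    known_totals: dict[tuple[GroupLabel, AgeClass], int],
    boundaries: AreaBoundaries | None = None,
) -> ReencounterData:
    """Tabulate assigned records into the four count matrices.

    ``known_totals`` maps (group, age class) to the number ringed N for
    marking periods where it is recorded; records from other periods are
    tabulated into the unknown-total matrices. Each ring id is counted at
    most once (first record wins).
    """
    if len(records) != len(groups):
        raise ValueError("records and groups must align")
    n = len(GROUPS)
    R_ad_known = np.zeros((n, 5), dtype=np.int64)
    R_juv_known = np.zeros((n, 5), dtype=np.int64)
    R_ad_unknown = np.zeros((n, 4), dtype=np.int64)
    R_juv_unknown = np.zeros((n, 4), dtype=np.int64)
    N_ad = np.zeros(n, dtype=np.int64)
    N_juv = np.zeros(n, dtype=np.int64)
    for (group, age), total in known_totals.items():
        if age is AgeClass.full_grown:
            N_ad[group.index] = total
        else:
            N_juv[group.index] = total

    seen: set[str] = set()
    for rec, group in zip(records, groups):
        if rec.ring_id in seen:
            continue
        seen.add(rec.ring_id)
        area = assign_wintering_area(rec.reencounter_lat, rec.reencounter_lon, boundaries)
        if area is None:
            raise ValueError(f"ring {rec.ring_id}: reencounter outside the wintering domain")
        i, k = group.index, area.index
        known = (group, rec.age_at_ringing) in known_totals
        if rec.age_at_ringing is AgeClass.full_grown:
            (R_ad_known if known else R_ad_unknown)[i, k] += 1
        else:
            (R_juv_known if known else R_juv_unknown)[i, k] += 1

    for R, N, name in ((R_ad_known, N_ad, "ad"), (R_juv_known, N_juv, "juv")):
        recovered = R[:, :4].sum(axis=1)
        if (recovered > N).any():
            i = int(np.nonzero(recovered > N)[0][0])
            raise SchemaError(
                f"group {GROUPS[i].value} ({name}): {recovered[i]} reencounters "
                f"exceed {N[i]} ringed"
            )
        R[:, 4] = N - recovered
    return ReencounterData(R_ad_known, R_juv_known, N_ad, N_juv, R_ad_unknown, R_juv_unknown)


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

_AREA_COLS = [f"area_{a.value}" for a in AREAS]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def write_reencounters(data: ReencounterData, known_path, unknown_path) -> None:
    rows_known, rows_unknown = [], []
    for age, Rk, N, Ru in (
        ("full_grown", data.R_ad_known, data.N_ad, data.R_ad_unknown),
        ("chick", data.R_juv_known, data.N_juv, data.R_juv_unknown),
    ):
        for i, g in enumerate(GROUPS):
            rows_known.append(
                dict(group=g.value, **dict(zip(_AREA_COLS, Rk[i, :4])), n_ringed=N[i], age_class=age)
            )
            rows_unknown.append(
                dict(group=g.value, **dict(zip(_AREA_COLS, Ru[i])), age_class=age)
            )
    pd.DataFrame(rows_known).to_csv(known_path, index=False)
    pd.DataFrame(rows_unknown).to_csv(unknown_path, index=False)


def read_reencounters(known_path, unknown_path) -> ReencounterData:
    dfk = pd.read_csv(known_path)
    dfu = pd.read_csv(unknown_path)
    _require_columns(dfk, ["group", *_AREA_COLS, "n_ringed", "age_class"], known_path)
    _require_columns(dfu, ["group", *_AREA_COLS, "age_class"], unknown_path)
    n = len(GROUPS)
    Rk = {a: np.zeros((n, 5), dtype=np.int64) for a in ("full_grown", "chick")}
    N = {a: np.zeros(n, dtype=np.int64) for a in ("full_grown", "chick")}
    Ru = {a: np.zeros((n, 4), dtype=np.int64) for a in ("full_grown", "chick")}
    for _, row in dfk.iterrows():
        i = GroupLabel(row["group"]).index
        age = str(row["age_class"])
        counts = np.array([row[c] for c in _AREA_COLS], dtype=np.int64)
        Rk[age][i, :4] = counts
        N[age][i] = int(row["n_ringed"])
        Rk[age][i, 4] = N[age][i] - counts.sum()
    for _, row in dfu.iterrows():
        i = GroupLabel(row["group"]).index
        Ru[str(row["age_class"])][i] = [row[c] for c in _AREA_COLS]
    return ReencounterData(
        Rk["full_grown"], Rk["chick"], N["full_grown"], N["chick"], Ru["full_grown"], Ru["chick"]
    )


def write_isotopes(data: IsotopeData, path) -> None:
    pd.DataFrame(
        {
            "individual_id": np.arange(data.n),
            "population": [POPULATIONS[p].value for p in data.pop],
            "d13C": data.values[:, 0],
            "d15N": data.values[:, 1],
        }
    ).to_csv(path, index=False)


def read_isotopes(path, standardize: bool = True) -> IsotopeData:
    df = pd.read_csv(path)
    _require_columns(df, ["individual_id", "population", "d13C", "d15N"], path)
    if len(df) == 0:
        raise SchemaError(f"{path}: no rows")
    pop_index = {g.value: i for i, g in enumerate(POPULATIONS)}
    try:
        pop = np.array([pop_index[p] for p in df["population"]], dtype=np.int64)
    except KeyError as exc:
        raise SchemaError(f"{path}: unknown population label {exc.args[0]!r}") from exc
    values = df[["d13C", "d15N"]].to_numpy(dtype=float)
    if standardize:
        return IsotopeData(values=values, pop=pop)
    return IsotopeData.from_standardized(values, pop)


def write_parasites(data: ParasiteData, nb_path, b_path) -> None:
    def rows(G, H, labels):
        out = []
        for i, lab in enumerate(labels):
            for j, lin in enumerate(data.lineage_names):
                out.append(
                    dict(area_or_population=lab, lineage=lin, n_infected=G[i, j], n_sampled=H[i, j])
                )
        return pd.DataFrame(out)

    rows(data.G_nb, data.H_nb, [a.value for a in AREAS]).to_csv(nb_path, index=False)
    rows(data.G_b, data.H_b, [g.value for g in POPULATIONS]).to_csv(b_path, index=False)


def read_parasites(nb_path, b_path) -> ParasiteData:
    def load(path, labels, shape):
        df = pd.read_csv(path)
        _require_columns(df, ["area_or_population", "lineage", "n_infected", "n_sampled"], path)
        lineages = list(dict.fromkeys(df["lineage"]))
        G = np.zeros(shape, dtype=np.int64)
        H = np.zeros(shape, dtype=np.int64)
        idx = {lab: i for i, lab in enumerate(labels)}
        lidx = {lin: j for j, lin in enumerate(lineages)}
        for _, row in df.iterrows():
            lab = row["area_or_population"]
            if lab not in idx:
                raise SchemaError(f"{path}: unknown area/population {lab!r}")
            G[idx[lab], lidx[row["lineage"]]] = row["n_infected"]
            H[idx[lab], lidx[row["lineage"]]] = row["n_sampled"]
        return G, H, tuple(lineages)

    G_nb, H_nb, lin_nb = load(nb_path, [a.value for a in AREAS], (4, 5))
    G_b, H_b, lin_b = load(b_path, [g.value for g in POPULATIONS], (3, 5))
    if lin_nb != lin_b:
        raise SchemaError("lineage sets differ between wintering and breeding tables")
    return ParasiteData(G_nb, H_nb, G_b, H_b, lineage_names=lin_nb)


def study_parasite_data() -> ParasiteData:
    """The in-study parasite infection table (breeding + wintering counts)."""
    lineages = DEFAULT_LINEAGES
    G_b = np.array([[0, 0, 1, 1, 1], [12, 16, 18, 0, 0], [1, 5, 8, 0, 0]])
    H_b = np.array([[50] * 5, [435] * 5, [90] * 5])
    G_nb = np.array(
        [[1, 6, 1, 0, 0], [0, 1, 74, 2, 22], [0, 0, 26, 1, 0], [0, 2, 0, 34, 0]]
    )
    H_nb = np.array([[803] * 5, [2767] * 5, [506] * 5, [660] * 5])
    return ParasiteData(G_nb, H_nb, G_b, H_b, lineage_names=lineages)
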