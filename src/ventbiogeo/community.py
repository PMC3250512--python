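"""Site-by-species occurrence matrices and site coordinate records.

The community matrix (sites as rows, species as columns) is the response
data for every clustering stage; site records carry the coordinates used
as constraining variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CommunityMatrix",
    "SiteRecord",
    "read_presence_absence",
    "write_community_matrix",
    "read_site_records",
    "write_site_records",
    "combine_datasets",
    "esr_fixture",
]


class CommunityDataError(ValueError):
    """Raised for malformed community matrices or coordinate tables."""


@dataclass(frozen=True)
class SiteRecord:
    """A site label with decimal-degree coordinates."""

    site_id: str
    latitude_deg: float
    longitude_deg: float
    region_label: str | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude_deg <= 90.0:
            raise CommunityDataError(
                f"site {self.site_id!r}: latitude {self.latitude_deg} outside [-90, 90]"
            )
        if not -180.0 <= self.longitude_deg < 180.0:
            raise CommunityDataError(
                f"site {self.site_id!r}: longitude {self.longitude_deg} outside [-180, 180)"
            )


@dataclass
class CommunityMatrix:
    """Sites x species occurrence table.

    Parameters
    ----------
    site_ids, species_ids
        Ordered, unique row and column labels.
    occurrences
        Nonnegative matrix, shape ``(len(site_ids), len(species_ids))``.
        All entries in {0, 1} puts the matrix in presence/absence mode.
    """

    site_ids: list[str]
    species_ids: list[str]
    occurrences: np.ndarray
    binary: bool = field(init=False)

    def __post_init__(self) -> None:
        self.site_ids = [str(s) for s in self.site_ids]
        self.species_ids = [str(s) for s in self.species_ids]
        occ = np.asarray(self.occurrences, dtype=float)
        if occ.ndim != 2:
            raise CommunityDataError("occurrences must be a 2-D array")
        if occ.shape != (len(self.site_ids), len(self.species_ids)):
            raise CommunityDataError(
                f"shape {occ.shape} does not match {len(self.site_ids)} sites x "
                f"{len(self.species_ids)} species"
            )
        _check_unique(self.site_ids, "site")
        _check_unique(self.species_ids, "species")
        if not np.isfinite(occ).all():
            raise CommunityDataError("occurrences contain non-finite values")
        if (occ < 0).any():
            i, j = np.argwhere(occ < 0)[0]
            raise CommunityDataError(
                f"negative occurrence at site {self.site_ids[i]!r}, "
                f"species {self.species_ids[j]!r}"
            )
        self.occurrences = occ
        self.binary = bool(np.isin(occ, (0.0, 1.0)).all())
        empty = [self.site_ids[i] for i in np.flatnonzero(occ.sum(axis=1) == 0)]
        if empty:
            warnings.warn(
                f"all-zero site rows: {', '.join(empty)}", UserWarning, stacklevel=2
            )

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def row_totals(self) -> np.ndarray:
        return self.occurrences.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.occurrences, index=self.site_ids, columns=self.species_ids
        )


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise CommunityDataError(f"duplicate {what} label {lab!r}")
        seen.add(lab)


def read_presence_absence(path, sep: str | None = None) -> CommunityMatrix:
    """Read a delimited site x species table.

    First row is the species header, first column the site labels.  The
    delimiter is sniffed (comma vs tab) unless given.  Binary mode is
    auto-detected from the parsed values.
    """
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if sep is None:
        sep = "\t" if first.count("\t") >= first.count(",") else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise CommunityDataError(f"{path}: malformed table ({exc})") from exc
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise CommunityDataError(
                f"{path}: non-numeric cell at site {row!r}, species {col!r}: "
                f"{df[col][bad].iloc[0]!r}"
            )
    if df.isna().any().any():
        raise CommunityDataError(f"{path}: missing values in table")
    return CommunityMatrix(
        site_ids=[str(i) for i in df.index],
        species_ids=[str(c) for c in df.columns],
        occurrences=df.to_numpy(dtype=float),
    )


def write_community_matrix(matrix: CommunityMatrix, path, sep: str = "\t") -> None:
    """Write the matrix in the format read by :func:`read_presence_absence`."""
    df = matrix.to_frame()
    if matrix.binary:
        df = df.astype(int)
    df.to_csv(path, sep=sep, index_label="site_id")


def read_site_records(path, sep: str | None = None) -> list[SiteRecord]:
    """Read a coordinate table with columns site_id, latitude_deg, longitude_deg."""
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if sep is None:
        sep = "\t" if first.count("\t") >= first.count(",") else ","
    df = pd.read_csv(path, sep=sep)
    required = {"site_id", "latitude_deg", "longitude_deg"}
    if not required.issubset(df.columns):
        raise CommunityDataError(
            f"{path}: coordinate table needs columns {sorted(required)}"
        )
    records = []
    for _, row in df.iterrows():
        region = row.get("region_label")
        records.append(
            SiteRecord(
                site_id=str(row["site_id"]),
                latitude_deg=float(row["latitude_deg"]),
                longitude_deg=float(row["longitude_deg"]),
                region_label=None if pd.isna(region) else str(region),
            )
        )
    _check_unique([r.site_id for r in records], "site")
    return records


def write_site_records(records: Sequence[SiteRecord], path, sep: str = "\t") -> None:
    df = pd.DataFrame(
        {
            "site_id": [r.site_id for r in records],
            "latitude_deg": [r.latitude_deg for r in records],
            "longitude_deg": [r.longitude_deg for r in records],
            "region_label": [r.region_label or "" for r in records],
        }
    )
    df.to_csv(path, sep=sep, index=False)


def combine_datasets(
    base: CommunityMatrix, addition: CommunityMatrix
) -> CommunityMatrix:
    """Stack two matrices with disjoint site sets over the union of species.

    Species columns keep base order, then addition-only species in addition
    order.  Cells absent from a source matrix are filled with 0, so row sums
    are preserved exactly.
    """
    overlap = set(base.site_ids) & set(addition.site_ids)
    if overlap:
        raise CommunityDataError(
            f"overlapping site labels: {', '.join(sorted(overlap))}"
        )
    species = list(base.species_ids) + [
        s for s in addition.species_ids if s not in set(base.species_ids)
    ]
    col = {s: j for j, s in enumerate(species)}
    out = np.zeros((base.n_sites + addition.n_sites, len(species)))
    for j, s in enumerate(base.species_ids):
        out[: base.n_sites, col[s]] = base.occurrences[:, j]
    for j, s in enumerate(addition.species_ids):
        out[base.n_sites :, col[s]] = addition.occurrences[:, j]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # transient empty rows allowed
        return CommunityMatrix(
            site_ids=base.site_ids + addition.site_ids,
            species_ids=species,
            occurrences=out,
        )


# Dominant fauna at the two East Scotia Ridge vent fields, one column per
# lowest-level taxon.  Vent-periphery taxa are kept as presences.
_ESR_TAXA: list[tuple[str, int, int]] = [
    # (taxon, at E2, at E9)
    ("Cladorhiza n. sp. 1", 1, 1),
    ("Abyssocladia n. sp. 1", 0, 1),
    ("Chondrophellia sp. or Hormathia spinosa", 0, 1),
    ("Actinostolidae n. sp. 1", 0, 1),
    ("Actinostolidae n. sp. 2", 1, 1),
    ("Actinostolidae n. sp. 3", 1, 1),
    ("Actinostolidae n. sp. 4", 1, 0),
    ("Polynoidae sp. 1", 1, 0),
    ("Polynoidae sp. 2", 0, 1),
    ("Polynoidae sp. 3", 0, 1),
    ("Polynoidae sp. 4", 0, 1),
    ("Peltospiroidea n. sp.", 1, 1),
    ("cf. Protolira sp.", 1, 1),
    ("Lepetodrilus n. sp. 1", 1, 1),
    ("Provannid sp. 1", 1, 1),
    ("Provannid sp. 2", 0, 1),
    ("Octopodidae", 0, 1),
    ("Vulcanolepas n. sp.", 1, 1),
    ("Kiwa n. sp.", 1, 1),
    ("Sericosura sp. 1", 1, 1),
    ("Sericosura sp. 2", 1, 1),
    ("Sericosura sp. 3", 0, 1),
    ("Colossendeis cf. concedis", 1, 1),
    ("Colossendeis cf. elephantis", 1, 1),
    ("Stichasteridae n. sp.", 1, 1),
    ("Freyella cf. fragilissima", 1, 1),
    ("Zoarcid fish", 0, 1),
]

# Midpoints of the published position ranges for the two vent fields.
_E2_LAT = -(56.0 + 5.3 / 60.0)
_E2_LON = -(30.0 + 19.175 / 60.0)
_E9_LAT = -(60.0 + 2.75 / 60.0)
_E9_LON = -(29.0 + 58.8 / 60.0)


def esr_fixture() -> tuple[CommunityMatrix, list[SiteRecord]]:
    """Two-site presence/absence fixture for the E2 and E9 vent fields."""
    occ = np.array([[e2 for _, e2, _ in _ESR_TAXA], [e9 for _, _, e9 in _ESR_TAXA]],
                   dtype=float)
    matrix = CommunityMatrix(
        site_ids=["E2", "E9"],
        species_ids=[name for name, _, _ in _ESR_TAXA],
        occurrences=occ,
    )
    sites = [
        SiteRecord("E2", _E2_LAT, _E2_LON, region_label="East Scotia Ridge"),
        SiteRecord("E9", _E9_LAT, _E9_LON, region_label="East Scotia Ridge"),
    ]
    return matrix, sites
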