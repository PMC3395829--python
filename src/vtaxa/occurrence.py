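"""Metadata validation, supercontinent mapping, incidence matrices, filters.

Occurrence analyses cross virtual taxa with categorical strata: host
taxonomic order, host functional group (grass/forb/woody), ecosystem,
continent, biogeographical realm, Koeppen-Geiger climate type, supercontinent
(Laurasia/Gondwana) and sampling location.  This module validates metadata
against the controlled vocabularies, builds VT x category count matrices, and
applies the sampling-sufficiency filters used before ordination: locations
need >= 12 sequences or >= 6 VTs, plants (host orders) need >= 3 VTs, and the
under-sampled Indo-Malay realm and shrubland ecosystem are always excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .synthetic_data import METADATA_COLUMNS, VOCABULARIES
from .vt_delimit import VTAssignment

logger = logging.getLogger("vtaxa")

SUPERCONTINENTS = ("Gondwana", "Laurasia")

#: category schemes usable as incidence-matrix columns
SCHEMES = (
    "host_order", "functional_group", "ecosystem", "continent", "realm",
    "climate", "supercontinent", "location",
)

# sequence-count / VT-count thresholds of the location sufficiency filter
MIN_LOCATION_SEQS = 12
MIN_LOCATION_VTS = 6
MIN_PLANT_VTS = 3
ALWAYS_DROPPED = ("Indo-Malay", "shrubland")

FilterMode = Literal["location", "plant", "none"]


@dataclass
class SampleMetadata:
    """Validated per-sequence metadata row."""

    seq_id: str
    host_order: str
    functional_group: str
    ecosystem: str
    continent: str
    realm: str
    climate: str
    location_id: str
    origin: str


@dataclass
class IncidenceMatrix:
    """VT x category (or location) count table with a presence view."""

    counts: pd.DataFrame  # rows: vt ids; columns: categories; int counts

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("incidence counts must be nonnegative")
        self.counts = self.counts.astype(int)

    @property
    def presence(self) -> pd.DataFrame:
        return self.counts > 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="vt_id")

    def to_triplets(self, path) -> None:
        """Sparse triplet TSV: vt_id, category, count (nonzero cells only)."""
        with open(path, "w") as fh:
            fh.write("vt_id\tcategory\tcount\n")
            for vt, row in self.counts.iterrows():
                for cat, v in row.items():
                    if v > 0:
                        fh.write(f"{vt}\t{cat}\t{v}\n")


# ---------------------------------------------------------------------------
# Metadata IO
# ---------------------------------------------------------------------------

def read_metadata(path) -> list[SampleMetadata]:
    """Read and validate the metadata TSV; vocabulary violations are collected
    and reported together."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if df.empty:
        logger.warning("metadata file %s has a header but no rows", path)
        return []
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> list[SampleMetadata]:
    errors: list[str] = []
    seen: set[str] = set()
    records: list[SampleMetadata] = []
    vocab_cols = (
        "host_order", "functional_group", "ecosystem", "continent", "realm",
        "climate", "origin",
    )
    for i, row in df.iterrows():
        sid = row["seq_id"]
        if sid in seen:
            errors.append(f"row {i}: duplicate seq_id {sid!r}")
        seen.add(sid)
        if not row["location_id"]:
            errors.append(f"row {i}: empty location_id")
        for col in vocab_cols:
            if row[col] not in VOCABULARIES[col]:
                errors.append(f"row {i}: {col} value {row[col]!r} not in vocabulary")
        records.append(SampleMetadata(**{c: row[c] for c in METADATA_COLUMNS}))
    if errors:
        raise ValueError("invalid metadata:\n" + "\n".join(errors))
    logger.info("read %d metadata rows", len(records))
    return records


def metadata_frame(meta: Sequence[SampleMetadata]) -> pd.DataFrame:
    df = pd.DataFrame([vars(m) for m in meta])
    return df.set_index("seq_id", drop=False)


# ---------------------------------------------------------------------------
# Supercontinents
# ---------------------------------------------------------------------------

def map_supercontinent(continent: str, realm: str = "") -> str:
    """Laurasia = North America + Eurasia; Gondwana = Africa, South America,
    Oceania and India (Indo-Malay realm), per the Pangaea break-up."""
    if realm == "Indo-Malay":
        return "Gondwana"
    if continent in ("North America", "Europe", "Asia"):
        return "Laurasia"
    if continent in ("Africa", "South America", "Oceania"):
        return "Gondwana"
    raise ValueError(f"unknown continent {continent!r}")


# ---------------------------------------------------------------------------
# Incidence matrices
# ---------------------------------------------------------------------------

def incidence_matrix(
    assignment: VTAssignment,
    meta: Sequence[SampleMetadata],
    scheme: str,
    origin: str | None = None,
) -> IncidenceMatrix:
    """Count, per VT and category of ``scheme``, the sequences carrying it.

    ``scheme`` is a metadata field, "supercontinent" (derived) or "location".
    ``origin`` restricts to sequences of that sample origin (host-linked
    analyses use root-origin sequences only).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; one of {SCHEMES}")
    by_id = {m.seq_id: m for m in meta}
    vt_of = assignment.vt_of()
    missing = sorted(s for s in vt_of if s not in by_id)
    if missing:
        raise ValueError(f"sequences without metadata: {missing}")

    def category(m: SampleMetadata) -> str:
        if scheme == "location":
            return m.location_id
        if scheme == "supercontinent":
            return map_supercontinent(m.continent, m.realm)
        return getattr(m, scheme)

    cells: dict[tuple[str, str], int] = {}
    for sid, vt in vt_of.items():
        m = by_id[sid]
        if origin is not None and m.origin != origin:
            continue
        key = (vt, category(m))
        cells[key] = cells.get(key, 0) + 1

    vts = sorted(assignment.members)
    cats = sorted({c for (_, c) in cells})
    data = pd.DataFrame(0, index=vts, columns=cats, dtype=int)
    for (vt, c), v in cells.items():
        data.loc[vt, c] = v
    # VTs with no retained sequence (e.g. origin filter) keep an all-zero row
    return IncidenceMatrix(counts=data)


def apply_filters(
    matrix: IncidenceMatrix,
    meta: Sequence[SampleMetadata] | None = None,
    mode: FilterMode = "none",
) -> IncidenceMatrix:
    """Sampling-sufficiency column filters (idempotent).

    location mode: drop location columns with fewer than 12 sequences AND
    fewer than 6 VTs (either condition retains).  plant mode: drop host
    columns with fewer than 3 VTs.  Indo-Malay and shrubland columns are
    always dropped.  Raises if nothing survives.
    """
    if mode not in ("location", "plant", "none"):
        raise ValueError(f"unknown filter mode {mode!r}")
    counts = matrix.counts
    keep: list[str] = []
    dropped: list[str] = []
    for col in counts.columns:
        if col in ALWAYS_DROPPED:
            dropped.append(col)
            continue
        n_seqs = int(counts[col].sum())
        n_vts = int((counts[col] > 0).sum())
        if mode == "location" and not (n_seqs >= MIN_LOCATION_SEQS or n_vts >= MIN_LOCATION_VTS):
            dropped.append(col)
            continue
        if mode == "plant" and n_vts < MIN_PLANT_VTS:
            dropped.append(col)
            continue
        keep.append(col)
    if dropped:
        logger.info("apply_filters(%s): dropped columns %s", mode, dropped)
    if not keep:
        raise ValueError("all columns removed by filtering")
    return IncidenceMatrix(counts=counts[keep].copy())
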