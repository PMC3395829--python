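"""Pairwise alignment, identity, OTU clustering and representative picking.

All similarity thresholds downstream (97 % OTU clustering, the 90 % virtual-taxon
fallback) are fractions of identical columns in a global pairwise alignment, so
this module fixes the alignment and identity conventions once:

* global (Needleman–Wunsch) alignment with linear gap costs and deterministic
  tie-breaking (diagonal, then up, then left);
* identity excludes terminal-gap columns; internal gap columns count as one
  difference each (``each-gap`` policy) or one per run (``one-gap-per-run``).

Distances used for clustering are ``1 - identity`` and are stored in a
:class:`skbio.DistanceMatrix`.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import SeqIO
from skbio import DistanceMatrix

logger = logging.getLogger("vtaxa")

VALID_BASES = frozenset("ACGTN")

#: default Needleman-Wunsch scoring (match, mismatch, gap)
DEFAULT_MATCH = 1.0
DEFAULT_MISMATCH = -1.0
DEFAULT_GAP = -2.0

GapPolicy = Literal["each-gap", "one-gap-per-run"]
Linkage = Literal["furthest", "average", "nearest"]


@dataclass(frozen=True)
class SequenceRecord:
    """One ITS sequence: an id unique within its dataset and its residues."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        for pos, ch in enumerate(self.seq):
            if ch not in VALID_BASES:
                raise ValueError(
                    f"invalid character {ch!r} in sequence {self.id!r} at position {pos}"
                )


@dataclass
class Alignment:
    """Gapped rows of equal length plus the alignment score (pairwise only)."""

    ids: list[str]
    rows: list[str]
    score: float = 0.0

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows must all have the same length")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


@dataclass
class OTU:
    """A 97 %-style sequence cluster with a medoid representative."""

    otu_id: str
    members: list[str]
    representative: str

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError("representative must be a member of the OTU")


# ---------------------------------------------------------------------------
# FASTA / matrix IO
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[SequenceRecord]:
    """Read FASTA into SequenceRecords (uppercased), enforcing unique ids."""
    records = [
        SequenceRecord(id=r.id, seq=str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")
    ]
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate sequence id {r.id!r}")
        seen.add(r.id)
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.seq}\n")


def write_msa_fasta(aln: "Alignment", path) -> None:
    """Write a (gapped) alignment as FASTA."""
    with open(path, "w") as fh:
        for rid, row in zip(aln.ids, aln.rows):
            fh.write(f">{rid}\n{row}\n")


def write_phylip_dm(dm: DistanceMatrix, path) -> None:
    """Write a square PHYLIP distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"{dm.shape[0]}\n")
        for label, row in zip(dm.ids, dm.data):
            fh.write(label + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")


def read_phylip_dm(path) -> DistanceMatrix:
    with open(path) as fh:
        n = int(fh.readline().split()[0])
        labels, rows = [], []
        for _ in range(n):
            parts = fh.readline().split()
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return DistanceMatrix(np.asarray(rows), labels)


# ---------------------------------------------------------------------------
# Global alignment
# ---------------------------------------------------------------------------

def _validate_record(rec: SequenceRecord) -> None:
    # SequenceRecord validates on construction; re-check for raw duck-typed input
    for pos, ch in enumerate(rec.seq):
        if ch not in VALID_BASES:
            raise ValueError(
                f"invalid character {ch!r} in sequence {rec.id!r} at position {pos}"
            )


def global_align(
    a: SequenceRecord,
    b: SequenceRecord,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap: float = DEFAULT_GAP,
) -> Alignment:
    """Optimal global alignment of two sequences under linear gap scoring.

    The dynamic program is filled row-wise (vectorised over columns; the
    within-row gap chain is a running maximum).  The traceback resolves ties
    by preferring diagonal, then up (gap in ``b``), then left (gap in ``a``).
    """
    _validate_record(a)
    _validate_record(b)
    sa = np.frombuffer(a.seq.encode(), dtype=np.uint8)
    sb = np.frombuffer(b.seq.encode(), dtype=np.uint8)
    n, m = len(sa), len(sb)

    H = np.empty((n + 1, m + 1), dtype=np.float64)
    H[0, :] = gap * np.arange(m + 1)
    H[:, 0] = gap * np.arange(n + 1)
    jg = gap * np.arange(m + 1)  # j*gap offsets for the left-chain running max
    nmatch = np.where(sb == ord("N"), mismatch, match)
    for i in range(1, n + 1):
        sub = np.where(sa[i - 1] == sb, nmatch, mismatch)
        if sa[i - 1] == ord("N"):
            sub = np.full(m, mismatch)
        cand = np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] + gap)
        # H[i,j] = max(cand[j], H[i,j-1]+gap) chains leftward:
        # H[i,j] = j*gap + running_max over k<=j of (cand_or_boundary[k] - k*gap)
        x = np.empty(m + 1)
        x[0] = H[i, 0]
        x[1:] = cand - jg[1:]
        H[i, :] = jg + np.maximum.accumulate(x)

    # traceback with tie preference: diagonal, up, left
    ra: list[str] = []
    rb: list[str] = []
    i, j = n, m
    eps = 1e-9
    while i > 0 or j > 0:
        h = H[i, j]
        if i > 0 and j > 0:
            sub = (
                match
                if (sa[i - 1] == sb[j - 1] and sa[i - 1] != ord("N"))
                else mismatch
            )
            if abs(H[i - 1, j - 1] + sub - h) < eps:
                ra.append(a.seq[i - 1])
                rb.append(b.seq[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and abs(H[i - 1, j] + gap - h) < eps:
            ra.append(a.seq[i - 1])
            rb.append("-")
            i -= 1
            continue
        ra.append("-")
        rb.append(b.seq[j - 1])
        j -= 1

    return Alignment(
        ids=[a.id, b.id], rows=["".join(reversed(ra)), "".join(reversed(rb))],
        score=float(H[n, m]),
    )


def pairwise_identity(aln: Alignment, mode: GapPolicy = "each-gap") -> float:
    """Fraction of identical columns in a 2-row alignment.

    Terminal-gap columns (overhangs) are excluded.  With ``each-gap`` every
    internal gap column counts as one difference; with ``one-gap-per-run`` a
    run of consecutive gap columns counts as a single difference.
    """
    if aln.n_rows != 2:
        raise ValueError("pairwise_identity requires a 2-row alignment")
    r0, r1 = aln.rows
    L = len(r0)
    # trim terminal-gap columns: positions before the later start / after the
    # earlier end of the two ungapped rows
    def span(row: str) -> tuple[int, int]:
        first = next(i for i, c in enumerate(row) if c != "-")
        last = L - 1 - next(i for i, c in enumerate(reversed(row)) if c != "-")
        return first, last

    s0, e0 = span(r0)
    s1, e1 = span(r1)
    lo, hi = max(s0, s1), min(e0, e1)
    if lo > hi:
        raise ValueError("no counted columns after excluding terminal gaps")

    matches = 0
    mismatches = 0
    gap_cols = 0
    gap_runs = 0
    in_run = False
    for c0, c1 in zip(r0[lo : hi + 1], r1[lo : hi + 1]):
        if c0 == "-" or c1 == "-":
            gap_cols += 1
            if not in_run:
                gap_runs += 1
                in_run = True
            continue
        in_run = False
        if c0 == c1 and c0 != "N":
            matches += 1
        else:
            mismatches += 1

    gap_units = gap_cols if mode == "each-gap" else gap_runs
    counted = matches + mismatches + gap_units
    if counted == 0:
        raise ValueError("no counted columns after excluding terminal gaps")
    return matches / counted


def sequence_identity(
    a: SequenceRecord,
    b: SequenceRecord,
    mode: GapPolicy = "each-gap",
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap: float = DEFAULT_GAP,
) -> float:
    """Convenience: align two records globally and return their identity."""
    return pairwise_identity(global_align(a, b, match, mismatch, gap), mode=mode)


def distance_matrix(
    records: Sequence[SequenceRecord],
    mode: GapPolicy = "each-gap",
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap: float = DEFAULT_GAP,
) -> DistanceMatrix:
    """All-pairs ``1 - identity`` distances (each pair aligned once)."""
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in input")
    n = len(records)
    d = np.zeros((n, n))
    n_aln = 0
    for i, j in itertools.combinations(range(n), 2):
        ident = sequence_identity(records[i], records[j], mode, match, mismatch, gap)
        d[i, j] = d[j, i] = 1.0 - ident
        n_aln += 1
    logger.debug("distance_matrix: %d alignments for %d records", n_aln, n)
    return DistanceMatrix(d, ids)


# ---------------------------------------------------------------------------
# Center-star multiple alignment
# ---------------------------------------------------------------------------

def center_star_msa(
    records: Sequence[SequenceRecord],
    dm: DistanceMatrix | None = None,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap: float = DEFAULT_GAP,
) -> Alignment:
    """Center-star progressive alignment.

    The center is the record minimising its distance-matrix row sum (ties to
    the lexicographically smaller id).  Every other record is aligned to the
    center pairwise, and gaps opened in the center are propagated to all rows
    already merged ("once a gap, always a gap").
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    if dm is None:
        dm = distance_matrix(records, match=match, mismatch=mismatch, gap=gap)
    by_id = {r.id: r for r in records}
    rowsums = dm.data.sum(axis=1)
    order = sorted(range(len(dm.ids)), key=lambda i: (rowsums[i], dm.ids[i]))
    center_id = dm.ids[order[0]]
    center = by_id[center_id]

    master = list(center.seq)  # current gapped center
    msa_ids = [center_id]
    msa_rows = [list(center.seq)]

    others = sorted((r for r in records if r.id != center_id), key=lambda r: r.id)
    for rec in others:
        aln = global_align(
            SequenceRecord("c", "".join(c for c in master if c != "-")), rec,
            match, mismatch, gap,
        )
        c_row, o_row = aln.rows
        # map the freshly aligned (degapped) center back onto the gapped master,
        # inserting any new gap columns into every existing row
        merged_master: list[str] = []
        merged_new: list[str] = []
        inserts: list[int] = []  # master positions where new all-gap columns go
        mi = 0  # index into master
        for cc, oc in zip(c_row, o_row):
            if cc == "-":
                # new column relative to the master
                inserts.append(mi)
                merged_master.append("-")
                merged_new.append(oc)
            else:
                while mi < len(master) and master[mi] == "-":
                    merged_master.append("-")
                    merged_new.append("-")
                    mi += 1
                merged_master.append(cc)
                merged_new.append(oc)
                mi += 1
        while mi < len(master):
            merged_master.append(master[mi])
            merged_new.append("-")
            mi += 1
        # rebuild existing rows: map each merged column back to an old master
        # column, or to a fresh all-gap column (None)
        col_map: list[int | None] = []
        mi = 0
        for cc in merged_master:
            if cc == "-":
                if mi < len(master) and master[mi] == "-":
                    col_map.append(mi)
                    mi += 1
                else:
                    col_map.append(None)
            else:
                col_map.append(mi)
                mi += 1
        msa_rows = [
            [row[c] if c is not None else "-" for c in col_map] for row in msa_rows
        ]
        master = merged_master
        msa_rows.append(merged_new)
        msa_ids.append(rec.id)

    return Alignment(ids=msa_ids, rows=["".join(r) for r in msa_rows], score=0.0)


# ---------------------------------------------------------------------------
# OTU clustering
# ---------------------------------------------------------------------------

def _linkage_distance(
    d: np.ndarray, a: list[int], b: list[int], linkage: Linkage
) -> float:
    block = d[np.ix_(a, b)]
    if linkage == "furthest":
        return float(block.max())
    if linkage == "nearest":
        return float(block.min())
    if linkage == "average":
        return float(block.mean())
    raise ValueError(f"unknown linkage {linkage!r}")


def cluster_otus(
    dm: DistanceMatrix, threshold: float = 0.03, linkage: Linkage = "average"
) -> list[OTU]:
    """Agglomerative clustering cut at ``threshold`` (distance scale).

    Clusters merge while the minimum between-cluster linkage distance is
    ``<= threshold``; equal-distance ties pick the pair whose (smallest member
    id) labels sort first.  Output OTUs partition the input and are named
    OTU0001... in order of their lexicographically smallest member.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    labels = list(dm.ids)
    d = dm.data
    clusters: list[list[int]] = [[i] for i in range(len(labels))]

    def key(c: list[int]) -> str:
        return min(labels[i] for i in c)

    while len(clusters) > 1:
        best = None
        for x, y in itertools.combinations(range(len(clusters)), 2):
            dist = _linkage_distance(d, clusters[x], clusters[y], linkage)
            pair_key = tuple(sorted((key(clusters[x]), key(clusters[y]))))
            cand = (dist, pair_key, x, y)
            if best is None or cand[:2] < best[:2]:
                best = cand
        if best is None or best[0] > threshold:
            break
        _, _, x, y = best
        merged = clusters[x] + clusters[y]
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)]
        clusters.append(merged)

    clusters.sort(key=key)
    otus = []
    for k, c in enumerate(clusters, start=1):
        members = sorted(labels[i] for i in c)
        otu = OTU(otu_id=f"OTU{k:04d}", members=members, representative=members[0])
        otu.representative = pick_representative(otu, dm)
        otus.append(otu)
    return otus


def pick_representative(otu: OTU, dm: DistanceMatrix) -> str:
    """Medoid member: minimal summed distance to the other members, ties to
    the lexicographically smaller id."""
    if not otu.members:
        raise ValueError("empty OTU")
    if len(otu.members) == 1:
        return otu.members[0]
    idx = [dm.index(m) for m in otu.members]
    sub = dm.data[np.ix_(idx, idx)]
    sums = sub.sum(axis=1)
    order = sorted(range(len(idx)), key=lambda i: (sums[i], otu.members[i]))
    return otu.members[order[0]]


def write_otu_tsv(otus: Sequence[OTU], path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\totu_id\trepresentative\n")
        for otu in otus:
            for m in otu.members:
                fh.write(f"{m}\t{otu.otu_id}\t{otu.representative}\n")
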