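"""Two-step delimitation of ITS virtual taxa (ITS-VTs).

The ITS region of glomeromycotan fungi is too variable for a single OTU cutoff
to approximate species, so virtual taxa are delimited in two steps:

1. sequences are pre-clustered into OTUs at 97 % identity (distance 0.03) and
   a medoid representative is chosen per OTU;
2. representatives are placed on a bootstrapped phylogeny, and representative
   groups are agglomerated bottom-up through the tree's supported clades: a
   clade merges the groups it contains when its bootstrap support reaches the
   support threshold AND every between-group representative identity is at
   least the 90 % similarity envelope.  Representatives that no supported
   clade absorbs fall back to plain 90 %-similarity assignment.

Each final representative group, expanded to its OTU members, is one virtual
taxon.  Provenance tags record how each sequence was placed: ``clade``
(supported-clade merge), ``similarity`` (fallback join), or ``singleton``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix

from . import phylo, seqops
from .seqops import OTU, SequenceRecord

Provenance = str  # "clade" | "similarity" | "singleton"


@dataclass
class VTConfig:
    """Thresholds of the two-step procedure.

    otu_threshold
        distance cutoff of the OTU pre-clustering step (0.03 = 97 % identity).
    support_threshold
        minimum bootstrap percentage for a clade to drive a merge.
    similarity_threshold
        identity envelope: merges and fallback assignment both require
        pairwise representative identity at or above this value (0.90).
    """

    otu_threshold: float = 0.03
    support_threshold: float = 50.0
    similarity_threshold: float = 0.90
    linkage: str = "average"
    bootstrap_reps: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.otu_threshold <= 1.0 - self.similarity_threshold <= 1.0):
            raise ValueError(
                "need 0 <= otu_threshold <= 1 - similarity_threshold <= 1"
            )
        if not 0.0 <= self.support_threshold <= 100.0:
            raise ValueError("support_threshold must be in [0, 100]")


@dataclass
class VTAssignment:
    """Partition of sequences into virtual taxa."""

    members: dict[str, list[str]]  # vt_id -> sequence ids
    representatives: dict[str, str]  # vt_id -> representative sequence id
    provenance: dict[str, Provenance]  # sequence id -> tag
    tree: phylo.SupportTree | None = None
    otus: list[OTU] = field(default_factory=list)

    @property
    def n_vts(self) -> int:
        return len(self.members)

    def vt_of(self) -> dict[str, str]:
        """sequence id -> vt id."""
        return {s: vt for vt, mem in self.members.items() for s in mem}

    def validate(self) -> None:
        seen: set[str] = set()
        for vt, mem in self.members.items():
            if not mem:
                raise ValueError(f"virtual taxon {vt} is empty")
            if self.representatives[vt] not in mem:
                raise ValueError(f"representative of {vt} not among its members")
            for s in mem:
                if s in seen:
                    raise ValueError(f"sequence {s} assigned to more than one VT")
                seen.add(s)


def assign_by_similarity(
    orphans: list[str],
    groups: list[list[str]],
    dm: DistanceMatrix,
    threshold: float,
) -> tuple[list[list[str]], dict[str, Provenance]]:
    """Fallback placement of representatives no supported clade absorbed.

    Orphans are processed in lexicographic order; each joins the group holding
    its most-similar representative if that identity >= ``threshold`` (ties to
    the first group in order), else it seeds a new singleton group — which is
    itself a candidate for later orphans.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    groups = [list(g) for g in groups]
    tags: dict[str, Provenance] = {}
    for orp in sorted(orphans):
        best_gi, best_ident = None, -1.0
        for gi, g in enumerate(groups):
            for rep in g:
                ident = 1.0 - dm[orp, rep]
                if ident > best_ident:
                    best_ident, best_gi = ident, gi
        if best_gi is not None and best_ident >= threshold:
            groups[best_gi].append(orp)
            tags[orp] = "similarity"
        else:
            groups.append([orp])
            tags[orp] = "singleton"
    return groups, tags


def _similarity_grouping(
    reps: list[str], dm: DistanceMatrix, threshold: float
) -> tuple[list[list[str]], dict[str, Provenance]]:
    """Pure similarity grouping used when too few representatives for a tree."""
    return assign_by_similarity(reps, [], dm, threshold)


def delimit_vts(records: list[SequenceRecord], cfg: VTConfig | None = None) -> VTAssignment:
    """Run the full two-step virtual-taxon delimitation pipeline."""
    cfg = cfg or VTConfig()
    if not records:
        raise ValueError("need at least 1 record")
    by_id = {r.id: r for r in records}
    if len(by_id) != len(records):
        raise ValueError("duplicate sequence ids")

    if len(records) == 1:
        rid = records[0].id
        return VTAssignment(
            members={"VT0001": [rid]},
            representatives={"VT0001": rid},
            provenance={rid: "singleton"},
        )

    dm = seqops.distance_matrix(records)
    otus = seqops.cluster_otus(dm, threshold=cfg.otu_threshold, linkage=cfg.linkage)
    rep_of_otu = {o.representative: o for o in otus}
    reps = sorted(rep_of_otu)

    tree: phylo.SupportTree | None = None
    if len(reps) == 1:
        groups = [[reps[0]]]
        tags: dict[str, Provenance] = {reps[0]: "singleton"}
    elif len(reps) <= 3:
        groups, tags = _similarity_grouping(reps, dm, cfg.similarity_threshold)
    else:
        rep_records = [by_id[r] for r in reps]
        msa = seqops.center_star_msa(rep_records, dm=dm.filter(reps))
        tree = phylo.bootstrap_support(
            msa, n_reps=cfg.bootstrap_reps, seed=cfg.seed
        )
        groups, tags = _agglomerate_clades(reps, tree, dm, cfg)
        # representatives still alone after clade agglomeration fall back
        orphans = sorted(g[0] for g in groups if len(g) == 1)
        kept = [g for g in groups if len(g) > 1]
        groups, fb_tags = assign_by_similarity(
            orphans, kept, dm, cfg.similarity_threshold
        )
        tags.update(fb_tags)

    # expand representative groups to full OTU membership
    vt_members: list[list[str]] = []
    vt_prov: dict[str, Provenance] = {}
    for g in groups:
        members: list[str] = []
        for rep in g:
            otu_members = rep_of_otu[rep].members
            members.extend(otu_members)
            for m in otu_members:
                vt_prov[m] = tags[rep]
        vt_members.append(sorted(members))
    vt_members.sort(key=lambda m: m[0])

    members_map: dict[str, list[str]] = {}
    reps_map: dict[str, str] = {}
    for k, mem in enumerate(vt_members, start=1):
        vt_id = f"VT{k:04d}"
        members_map[vt_id] = mem
        if len(mem) == 1:
            reps_map[vt_id] = mem[0]
        else:
            otu = OTU(otu_id=vt_id, members=mem, representative=mem[0])
            reps_map[vt_id] = seqops.pick_representative(otu, dm)

    out = VTAssignment(
        members=members_map,
        representatives=reps_map,
        provenance=vt_prov,
        tree=tree,
        otus=otus,
    )
    out.validate()
    return out


def _agglomerate_clades(
    reps: list[str],
    tree: phylo.SupportTree,
    dm: DistanceMatrix,
    cfg: VTConfig,
) -> tuple[list[list[str]], dict[str, Provenance]]:
    """Bottom-up merge of representative groups through supported clades.

    Clades (plus the trivial whole-set clade, which every replicate recovers)
    are visited smallest first; a clade merges the groups inside it only when
    all between-group representative identities meet the similarity envelope.
    """
    groups: list[list[str]] = [[r] for r in reps]
    tags: dict[str, Provenance] = {r: "singleton" for r in reps}
    clades = phylo.supported_clades(tree, min_support=cfg.support_threshold)
    clades.append(frozenset(reps))  # whole set: trivially supported
    max_d = 1.0 - cfg.similarity_threshold

    for clade in clades:
        inside = [g for g in groups if set(g) <= clade]
        if len(inside) < 2:
            continue
        flat = [r for g in inside for r in g]
        ok = True
        for gi in range(len(inside)):
            for gj in range(gi + 1, len(inside)):
                for x in inside[gi]:
                    for y in inside[gj]:
                        if dm[x, y] > max_d:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if not ok:
            continue
        groups = [g for g in groups if not set(g) <= clade] + [sorted(flat)]
        for r in flat:
            tags[r] = "clade"
    return groups, tags


def vt_summary(assignment: VTAssignment) -> dict:
    """Richness summary: VT count, singleton/doubleton counts, size histogram."""
    sizes = sorted(len(m) for m in assignment.members.values())
    hist: dict[int, int] = {}
    for s in sizes:
        hist[s] = hist.get(s, 0) + 1
    return {
        "n_vts": len(sizes),
        "n_sequences": int(sum(sizes)),
        "singletons": hist.get(1, 0),
        "doubletons": hist.get(2, 0),
        "size_histogram": hist,
    }


def write_vt_tsv(assignment: VTAssignment, path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tvt_id\tprovenance\n")
        for vt_id in sorted(assignment.members):
            for s in assignment.members[vt_id]:
                fh.write(f"{s}\t{vt_id}\t{assignment.provenance[s]}\n")


def write_vt_summary(assignment: VTAssignment, path) -> None:
    summary = vt_summary(assignment)
    summary["size_histogram"] = {str(k): v for k, v in summary["size_histogram"].items()}
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
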