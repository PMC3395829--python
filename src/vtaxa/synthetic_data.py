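"""Seeded synthetic ITS-like data with planted ground truth.

Real glomeromycotan ITS corpora cannot be regenerated on demand, so every
downstream stage is exercised on synthetic data with known structure:

* ``generate_taxa`` plants K well-separated sequence taxa — each taxon is an
  ancestor sequence plus members mutated i.i.d. per site — with uneven
  (geometric by default) abundances, so singletons and doubletons occur;
* ``attach_metadata`` assigns categorical metadata (host order, functional
  group, ecosystem, continent, realm, climate, location, origin) with a
  controllable fraction of taxa endemic to exactly one label per scheme;
* ``generate_path_data`` draws linear-Gaussian tables whose population
  standardized path coefficients are exactly the planted ones, for the
  structural-path stage.

Substitutions are uniform over the three alternative bases (Jukes-Cantor
style), matching the corrected distances used by the tree stage.  Indels are
off by default so planted identities stay analytically controllable; an indel
rate can be switched on to exercise the aligner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqops import SequenceRecord

BASES = np.array(list("ACGT"))

#: controlled vocabularies shared with the occurrence module
VOCABULARIES: dict[str, tuple[str, ...]] = {
    "host_order": (
        "Asparagales", "Asterales", "Fabales", "Fagales", "Lamiales",
        "Malpighiales", "Poales", "Rosales",
    ),
    "functional_group": ("forb", "grass", "woody"),
    "ecosystem": ("anthropogenic", "forest", "grassland", "shrubland", "successional"),
    "continent": ("Africa", "Asia", "Europe", "North America", "Oceania", "South America"),
    "realm": (
        "Afrotropic", "Antarctic", "Australasia", "Indo-Malay", "Nearctic",
        "Neotropic", "Oceania", "Palearctic",
    ),
    "climate": ("arid", "equatorial", "polar", "snow", "warm temperate"),
    "origin": ("root", "soil", "spore"),
}

#: schemes attach_metadata plants endemism in (origin and location are separate)
DEFAULT_SCHEMES: dict[str, tuple[str, ...]] = {
    k: VOCABULARIES[k]
    for k in ("host_order", "functional_group", "ecosystem", "continent", "realm", "climate")
}

METADATA_COLUMNS = (
    "seq_id", "host_order", "functional_group", "ecosystem", "continent",
    "realm", "climate", "location_id", "origin",
)


@dataclass(frozen=True)
class TaxonTruth:
    """Planted taxon: its id, member sequence ids, and ancestor residues."""

    taxon_id: str
    member_ids: tuple[str, ...]
    ancestor: str


@dataclass
class SynthConfig:
    """Parameters of the planted-taxon sequence generator.

    members_per_taxon may be an int (constant), a sequence of per-taxon
    counts, or "geometric" (support {1, 2, ...}, parameter ``geometric_p``),
    which produces the uneven abundances — singletons, doubletons — seen in
    real sequence corpora.
    """

    n_taxa: int = 5
    members_per_taxon: int | Sequence[int] | str = "geometric"
    geometric_p: float = 0.5
    seq_length: int = 400
    intra_mut: float = 0.02
    inter_div: float = 0.20
    indel_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be >= 1")
        if self.seq_length < 50:
            raise ValueError("seq_length must be >= 50")
        if not 0.0 <= self.intra_mut < self.inter_div <= 0.75:
            raise ValueError("need 0 <= intra_mut < inter_div <= 0.75")
        if isinstance(self.members_per_taxon, str) and self.members_per_taxon != "geometric":
            raise ValueError("members_per_taxon must be int, sequence or 'geometric'")


@dataclass
class MetaConfig:
    """Parameters of the categorical-metadata generator."""

    category_schemes: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_SCHEMES)
    )
    endemism_fraction: float = 0.8
    n_locations: int = 10
    origin: str | None = "root"  # fixed origin; None draws from origin_probs
    origin_probs: tuple[float, float, float] = (0.7, 0.2, 0.1)  # root, soil, spore
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.endemism_fraction <= 1.0:
            raise ValueError("endemism_fraction must be in [0, 1]")
        if not self.category_schemes:
            raise ValueError("category_schemes must be nonempty")
        for scheme, labels in self.category_schemes.items():
            if scheme not in VOCABULARIES:
                raise ValueError(f"unknown scheme {scheme!r}")
            bad = set(labels) - set(VOCABULARIES[scheme])
            if bad:
                raise ValueError(f"labels {sorted(bad)} not in vocabulary of {scheme!r}")


# ---------------------------------------------------------------------------
# Sequence generation
# ---------------------------------------------------------------------------

def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with prob ``rate``, uniformly to another base."""
    out = seq.copy()
    hit = rng.random(len(seq)) < rate
    if hit.any():
        shift = rng.integers(1, 4, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 4
    return out


def _apply_indels(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    keep = rng.random(len(seq)) >= rate / 2.0
    out = seq[keep]
    ins_mask = rng.random(len(out) + 1) < rate / 2.0
    if ins_mask.any():
        pieces = []
        for i, ch in enumerate(out):
            if ins_mask[i]:
                pieces.append(rng.integers(0, 4))
            pieces.append(ch)
        if ins_mask[len(out)]:
            pieces.append(rng.integers(0, 4))
        out = np.array(pieces, dtype=seq.dtype)
    return out


def generate_taxa(
    cfg: SynthConfig, max_retries: int = 50
) -> tuple[list[SequenceRecord], list[TaxonTruth]]:
    """Plant K taxa: diverged ancestors, i.i.d.-mutated members.

    Ancestors are drawn by mutating a common root at rate ``inter_div`` per
    ancestor and accepted only if every pair differs at >= ``inter_div`` of
    sites; after ``max_retries`` failed draws the placement is declared
    impossible.
    """
    rng = np.random.default_rng(cfg.seed)
    L, K = cfg.seq_length, cfg.n_taxa
    min_diff = int(np.ceil(cfg.inter_div * L))

    ancestors = None
    for _ in range(max_retries):
        root = rng.integers(0, 4, size=L)
        cand = [_mutate(root, cfg.inter_div, rng) for _ in range(K)] if K > 1 else [root]
        ok = all(
            (cand[i] != cand[j]).sum() >= min_diff
            for i in range(K)
            for j in range(i + 1, K)
        )
        if ok:
            ancestors = cand
            break
    if ancestors is None:
        raise RuntimeError(
            f"could not place {K} ancestors with pairwise divergence >= "
            f"{cfg.inter_div} after {max_retries} attempts"
        )

    if isinstance(cfg.members_per_taxon, str):
        counts = rng.geometric(cfg.geometric_p, size=K)
    elif isinstance(cfg.members_per_taxon, int):
        counts = np.full(K, cfg.members_per_taxon)
    else:
        counts = np.asarray(list(cfg.members_per_taxon))
        if len(counts) != K:
            raise ValueError("members_per_taxon sequence length must equal n_taxa")
    if (counts < 1).any():
        raise ValueError("every taxon needs at least 1 member")

    records: list[SequenceRecord] = []
    truth: list[TaxonTruth] = []
    s = 0
    for k in range(K):
        taxon_id = f"T{k + 1:03d}"
        member_ids = []
        for _ in range(int(counts[k])):
            s += 1
            sid = f"S{s:05d}"
            seq = _mutate(ancestors[k], cfg.intra_mut, rng)
            if cfg.indel_rate > 0:
                seq = _apply_indels(seq, cfg.indel_rate, rng)
            records.append(SequenceRecord(id=sid, seq="".join(BASES[seq])))
            member_ids.append(sid)
        truth.append(
            TaxonTruth(
                taxon_id=taxon_id,
                member_ids=tuple(member_ids),
                ancestor="".join(BASES[ancestors[k]]),
            )
        )
    return records, truth


# ---------------------------------------------------------------------------
# Metadata generation
# ---------------------------------------------------------------------------

def attach_metadata(truth: Sequence[TaxonTruth], mcfg: MetaConfig) -> pd.DataFrame:
    """Assign one label per scheme (and a location, an origin) per sequence.

    Per scheme, ``round(endemism_fraction * n_taxa)`` taxa are endemic: all
    members share one label.  The rest are spread over >= 2 labels, which
    requires them to have >= 2 members (singleton taxa are unavoidably
    endemic); an error is raised if too few multi-member taxa exist.
    """
    rng = np.random.default_rng(mcfg.seed)
    K = len(truth)
    n_endemic = int(round(mcfg.endemism_fraction * K))
    multi = [i for i, t in enumerate(truth) if len(t.member_ids) >= 2]
    n_spread = K - n_endemic
    if n_spread > len(multi):
        raise ValueError(
            f"cannot spread {n_spread} taxa over multiple labels: only "
            f"{len(multi)} taxa have >= 2 members"
        )

    rows: dict[str, dict[str, str]] = {
        s: {} for t in truth for s in t.member_ids
    }
    for scheme, labels in mcfg.category_schemes.items():
        labels = list(labels)
        if len(labels) < 2 and n_spread > 0:
            raise ValueError(f"scheme {scheme!r} needs >= 2 labels to spread taxa")
        spread_idx = set(rng.choice(multi, size=n_spread, replace=False)) if n_spread else set()
        for i, t in enumerate(truth):
            if i in spread_idx:
                # at least two distinct labels across members
                lab = rng.choice(labels, size=len(t.member_ids))
                if len(set(lab)) < 2:
                    alt = [l for l in labels if l != lab[0]]
                    lab[int(rng.integers(0, len(lab)))] = alt[int(rng.integers(0, len(alt)))]
                for s, l in zip(t.member_ids, lab):
                    rows[s][scheme] = str(l)
            else:
                l = str(rng.choice(labels))
                for s in t.member_ids:
                    rows[s][scheme] = l

    loc_labels = [f"L{i + 1:03d}" for i in range(mcfg.n_locations)]
    for t in truth:
        for s in t.member_ids:
            rows[s]["location_id"] = str(rng.choice(loc_labels))
            if mcfg.origin is not None:
                rows[s]["origin"] = mcfg.origin
            else:
                rows[s]["origin"] = str(
                    rng.choice(VOCABULARIES["origin"], p=mcfg.origin_probs)
                )

    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "seq_id"
    df = df.reset_index()
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    return df[list(METADATA_COLUMNS)]


# ---------------------------------------------------------------------------
# Path-model data generation
# ---------------------------------------------------------------------------

PATH_VARIABLES = ("ecosystem", "climate", "continent", "biogeography", "plant", "amf")


def generate_path_data(
    n: int,
    coeffs: Mapping[tuple[str, str], float],
    seed: int | None = None,
    variables: Sequence[str] = PATH_VARIABLES,
    standardize: bool = True,
) -> pd.DataFrame:
    """Linear-Gaussian table whose population standardized paths are ``coeffs``.

    Exogenous variables are independent standard normals; each endogenous
    variable is the planted linear combination of its parents plus Gaussian
    noise scaled so its population variance is 1 (hence coefficients are
    standardized).  Columns are z-scored in-sample when ``standardize``.
    """
    variables = list(variables)
    for (src, dst) in coeffs:
        if src not in variables or dst not in variables:
            raise ValueError(f"edge ({src!r}, {dst!r}) uses unknown variable")
    order = _topological_order(variables, coeffs)

    rng = np.random.default_rng(seed)
    idx = {v: i for i, v in enumerate(variables)}
    data = np.zeros((n, len(variables)))
    cov = np.zeros((len(variables), len(variables)))  # implied, for variance math
    placed: list[str] = []
    for v in order:
        parents = sorted(set(s for (s, d) in coeffs if d == v))
        beta = np.array([coeffs[(p, v)] for p in parents])
        if len(parents) == 0:
            data[:, idx[v]] = rng.standard_normal(n)
            cov[idx[v], idx[v]] = 1.0
        else:
            P = [idx[p] for p in parents]
            var_pred = float(beta @ cov[np.ix_(P, P)] @ beta)
            resid = 1.0 - var_pred
            if resid < 0:
                raise ValueError(
                    f"planted coefficients give variance > 1 for {v!r}"
                )
            data[:, idx[v]] = data[:, P] @ beta + np.sqrt(resid) * rng.standard_normal(n)
            # implied covariances with everything placed so far
            for w in placed:
                cov[idx[v], idx[w]] = cov[idx[w], idx[v]] = float(
                    beta @ cov[P, idx[w]]
                )
            cov[idx[v], idx[v]] = 1.0
        placed.append(v)

    df = pd.DataFrame(data, columns=variables)
    if standardize:
        df = (df - df.mean()) / df.std(ddof=1)
    return df


def _topological_order(
    variables: Sequence[str], coeffs: Mapping[tuple[str, str], float]
) -> list[str]:
    """Kahn topological sort; raises on cyclic edge structures."""
    parents: dict[str, set[str]] = {v: set() for v in variables}
    for (s, d) in coeffs:
        parents[d].add(s)
    order: list[str] = []
    remaining = set(variables)
    while remaining:
        ready = sorted(v for v in remaining if parents[v] <= set(order))
        if not ready:
            raise ValueError("path coefficient structure is cyclic")
        order.extend(ready)
        remaining -= set(ready)
    return order


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_truth(truth: Sequence[TaxonTruth], cfg: SynthConfig, path) -> None:
    """JSON truth file: taxon memberships plus the planted parameters."""
    payload = {
        "parameters": {
            "n_taxa": cfg.n_taxa,
            "seq_length": cfg.seq_length,
            "intra_mut": cfg.intra_mut,
            "inter_div": cfg.inter_div,
            "indel_rate": cfg.indel_rate,
            "seed": cfg.seed,
        },
        "taxa": {t.taxon_id: list(t.member_ids) for t in truth},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth(path) -> dict[str, list[str]]:
    with open(path) as fh:
        return json.load(fh)["taxa"]


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
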