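"""Mitochondrial p-distances, haplogroup assignment and molecular dating.

Distances are uncorrected proportions of differing sites (p-distance) with
pairwise deletion: any position where either sequence carries a gap or an
ambiguity code is excluded from that pair's comparison.  Dating applies a
percent-per-million-years substitution rate directly to the pairwise
distance (T = p / r); the per-lineage alternative (T = p / 2r) is available
behind a flag.  Coalescent times in generations are converted to years with
a configurable generation time (default 2 years).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = ["Alignment", "DatingConfig", "p_distance", "group_mean_p_distance",
           "distance_matrix", "date_from_pdistance", "generations_to_years",
           "assign_haplogroups"]

_CODE = {c: i for i, c in enumerate("ACGT")}


def _encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3; gaps and ambiguity codes -> -1 (ignored pairwise)."""
    return np.array([_CODE.get(c, -1) for c in seq.upper()], dtype=np.int8)


@dataclass
class Alignment:
    """Equal-length nucleotide sequences with a group label per sequence."""

    ids: list[str]
    seqs: np.ndarray                  # int8 (n_seqs, length)
    groups: list[str]

    def __post_init__(self):
        if self.seqs.ndim != 2:
            raise ValueError("sequence matrix must be 2D")
        if not (len(self.ids) == self.seqs.shape[0] == len(self.groups)):
            raise ValueError("ids, sequences and groups must align")

    @property
    def length(self) -> int:
        return self.seqs.shape[1]

    @classmethod
    def from_sequences(cls, records: dict[str, str],
                       groups: dict[str, str]) -> "Alignment":
        ids = list(records)
        lengths = {len(s) for s in records.values()}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        seqs = np.vstack([_encode(records[i]) for i in ids])
        return cls(ids, seqs, [groups[i] for i in ids])

    @classmethod
    def from_fasta(cls, path, groups: dict[str, str] | None = None) -> "Alignment":
        """Read an aligned FASTA; group defaults to the ID prefix before
        the first underscore when no group map is given."""
        records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
        if not records:
            raise ValueError(f"no sequences in {path}")
        if groups is None:
            groups = {i: i.split("_")[0] for i in records}
        return cls.from_sequences(records, groups)

    def group_indices(self, group: str) -> np.ndarray:
        idx = np.array([i for i, g in enumerate(self.groups) if g == group])
        if idx.size == 0:
            raise KeyError(f"empty or unknown group {group!r}")
        return idx


@dataclass(frozen=True)
class DatingConfig:
    """Substitution-rate range (fraction per My) and generation time (years)."""

    rate_low: float = 0.025
    rate_high: float = 0.031
    generation_time: float = 2.0

    def __post_init__(self):
        if self.rate_low <= 0 or self.rate_high <= 0 or self.generation_time <= 0:
            raise ValueError("rates and generation time must be positive")


def _pairwise(a: np.ndarray, b: np.ndarray) -> float:
    both = (a >= 0) & (b >= 0)
    n = int(both.sum())
    if n == 0:
        raise ValueError("no comparable sites between sequences")
    return float((a[both] != b[both]).sum()) / n


def p_distance(a, b) -> float:
    """Proportion of differing sites among pairwise-comparable positions."""
    av = _encode(a) if isinstance(a, str) else np.asarray(a)
    bv = _encode(b) if isinstance(b, str) else np.asarray(b)
    if av.shape != bv.shape:
        raise ValueError(f"length mismatch: {av.shape[0]} vs {bv.shape[0]}")
    return _pairwise(av, bv)


def group_mean_p_distance(aln: Alignment, group_a: str,
                          group_b: str | None = None) -> float:
    """Unweighted mean pairwise p-distance between (or within) groups.

    Within-group mode (``group_b`` omitted or equal) averages over all
    unordered pairs and needs >= 2 sequences.
    """
    ia = aln.group_indices(group_a)
    if group_b is None or group_b == group_a:
        if ia.size < 2:
            raise ValueError(f"within-group distance needs >= 2 sequences "
                             f"in {group_a!r}")
        pairs = [(ia[i], ia[j]) for i in range(ia.size)
                 for j in range(i + 1, ia.size)]
    else:
        ib = aln.group_indices(group_b)
        pairs = [(i, j) for i in ia for j in ib]
    return float(np.mean([_pairwise(aln.seqs[i], aln.seqs[j])
                          for i, j in pairs]))


def distance_matrix(aln: Alignment, groups: list[str] | None = None) -> pd.DataFrame:
    """Group-by-group mean p-distance matrix: within-group on the diagonal,
    between-group off-diagonal."""
    if groups is None:
        seen = []
        for g in aln.groups:
            if g not in seen:
                seen.append(g)
        groups = seen
    mat = pd.DataFrame(index=groups, columns=groups, dtype=float)
    for i, ga in enumerate(groups):
        for j, gb in enumerate(groups):
            if i == j and aln.group_indices(ga).size < 2:
                mat.loc[ga, gb] = np.nan
            else:
                mat.loc[ga, gb] = group_mean_p_distance(aln, ga, gb)
    return mat


def date_from_pdistance(p: float, rate: float, per_lineage: bool = False) -> float:
    """Divergence time in years from a p-distance and a rate in fraction/My.

    Default applies the rate to the pairwise distance directly (T = p/r);
    with ``per_lineage`` the distance is halved first (T = p/2r).
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if p < 0:
        raise ValueError("p-distance must be non-negative")
    div = 2.0 * rate if per_lineage else rate
    return p / div * 1.0e6


def generations_to_years(g: float, gen_time: float = 2.0) -> float:
    """Convert generations to years with the given generation time."""
    if g < 0 or gen_time < 0:
        raise ValueError("inputs must be non-negative")
    return g * gen_time


def assign_haplogroups(aln: Alignment, reference_groups: list[str],
                       query_ids: list[str] | None = None) -> pd.DataFrame:
    """Assign each query to the reference group with the smallest mean
    p-distance; exact ties are flagged ambiguous, never silently broken.

    Returns a DataFrame indexed by query ID with columns ``group`` (None
    when ambiguous), ``ambiguous`` and one mean-distance column per
    reference group.
    """
    if not reference_groups:
        raise ValueError("reference_groups must be non-empty")
    ref_idx = {g: aln.group_indices(g) for g in reference_groups}
    if query_ids is None:
        query_ids = [i for i, g in zip(aln.ids, aln.groups)
                     if g not in reference_groups]
    rows = {}
    for qid in query_ids:
        qi = aln.ids.index(qid)
        dists = {}
        for g, idx in ref_idx.items():
            others = idx[idx != qi]
            if others.size == 0:
                raise ValueError(f"reference group {g!r} has no sequence "
                                 f"other than the query")
            dists[g] = float(np.mean([_pairwise(aln.seqs[qi], aln.seqs[j])
                                      for j in others]))
        dmin = min(dists.values())
        winners = [g for g, d in dists.items() if d == dmin]
        rows[qid] = {"group": winners[0] if len(winners) == 1 else None,
                     "ambiguous": len(winners) > 1, **dists}
    return pd.DataFrame.from_dict(rows, orient="index")
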