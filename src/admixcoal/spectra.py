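"""Folded (minor-allele) 1D and 2D joint site frequency spectra.

Spectra are built from :class:`~admixcoal.genotypes.GenotypeTable` objects
(ALT is the counted allele before folding) and are read/written in a
fastsimcoal2-style observed-SFS text dialect.  Axis 0 always indexes
population 1's allele count, axis 1 population 2's.

Folding convention: a cell whose pooled allele count exceeds half the
pooled sample size is added into its complement cell; an exact-half cell
keeps the orientation whose population-1 count is smaller (as-is when the
two orientations have equal population-1 counts).  This tie rule is
deterministic and independent of input order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .genotypes import GenotypeTable

__all__ = ["JointSFS", "joint_sfs_from_genotypes", "sfs_1d", "fold",
           "write_obs", "read_obs"]


@dataclass
class JointSFS:
    """A 1D or 2D site frequency spectrum (observed counts or proportions)."""

    data: np.ndarray                   # (n1+1,) or (n1+1, n2+1)
    sample_sizes: tuple[int, ...]      # haploid sample size(s)
    folded: bool = False
    pop_labels: tuple[str, ...] = ()

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.sample_sizes = tuple(int(n) for n in self.sample_sizes)
        if self.data.ndim != len(self.sample_sizes):
            raise ValueError("dimension does not match number of sample sizes")
        expected_shape = tuple(n + 1 for n in self.sample_sizes)
        if self.data.shape != expected_shape:
            raise ValueError(
                f"shape {self.data.shape} does not match sample sizes "
                f"{self.sample_sizes} (expected {expected_shape})")
        if np.any(self.data < 0):
            raise ValueError("SFS entries must be non-negative")
        if not self.pop_labels:
            self.pop_labels = tuple(f"pop{i+1}" for i in range(self.data.ndim))

    # -- index bookkeeping -------------------------------------------------
    def _fold_map(self, idx: tuple[int, ...]) -> tuple[int, ...]:
        ns = self.sample_sizes
        pooled = sum(idx)
        ntot = sum(ns)
        comp = tuple(n - i for n, i in zip(ns, idx))
        if 2 * pooled > ntot:
            return comp
        if 2 * pooled == ntot and comp[0] < idx[0]:
            return comp
        return idx

    def polymorphic_mask(self) -> np.ndarray:
        """Boolean mask of cells that can carry segregating-site mass."""
        mask = np.zeros(self.data.shape, dtype=bool)
        ntot = sum(self.sample_sizes)
        for idx in np.ndindex(*self.data.shape):
            pooled = sum(idx)
            if pooled == 0 or pooled == ntot:
                continue
            if self.folded and self._fold_map(idx) != idx:
                continue
            mask[idx] = True
        return mask

    @property
    def total_sites(self) -> float:
        """Mass over polymorphic cells (= number of segregating sites)."""
        return float(self.data[self.polymorphic_mask()].sum())

    def normalized(self) -> "JointSFS":
        """Proportions over polymorphic cells (monomorphic cells zeroed)."""
        mask = self.polymorphic_mask()
        tot = self.data[mask].sum()
        if tot <= 0:
            raise ValueError("cannot normalize a spectrum with no polymorphic mass")
        out = np.where(mask, self.data / tot, 0.0)
        return replace(self, data=out)

    def fold(self) -> "JointSFS":
        """Fold to minor-allele orientation; idempotent."""
        out = np.zeros_like(self.data)
        for idx in np.ndindex(*self.data.shape):
            out[self._fold_map(idx)] += self.data[idx]
        return replace(self, data=out, folded=True)

    def marginal(self, axis_keep: int) -> "JointSFS":
        """Marginal 1D spectrum over the other population (unfolded input only).

        Folding does not commute with marginalization, so marginals of folded
        spectra are refused; fold at the end instead.
        """
        if self.data.ndim != 2:
            raise ValueError("marginal() requires a 2D spectrum")
        if self.folded:
            raise ValueError("marginalize before folding, not after")
        other = 1 - axis_keep
        return JointSFS(self.data.sum(axis=other),
                        (self.sample_sizes[axis_keep],),
                        folded=False,
                        pop_labels=(self.pop_labels[axis_keep],))

    def transpose(self) -> "JointSFS":
        if self.data.ndim != 2:
            raise ValueError("transpose() requires a 2D spectrum")
        return JointSFS(self.data.T.copy(), self.sample_sizes[::-1],
                        folded=self.folded, pop_labels=self.pop_labels[::-1])


def fold(sfs: JointSFS) -> JointSFS:
    return sfs.fold()


def _counts_for_pops(table: GenotypeTable, pops) -> tuple[np.ndarray, ...]:
    per_pop = []
    for pop in pops:
        alt, called = table.alt_counts(pop)
        n_hap = 2 * int(table.pop_mask(pop).sum())
        if np.any(called != n_hap):
            raise ValueError(
                f"missing genotypes in population {pop!r}; apply the "
                "completeness filter before building a spectrum")
        per_pop.append((alt, n_hap))
    return per_pop


def joint_sfs_from_genotypes(table: GenotypeTable, pops: tuple[str, str],
                             folded: bool = True) -> JointSFS:
    """2D joint SFS: cell (i, j) counts SNPs with i ALT alleles in ``pops[0]``
    and j in ``pops[1]``; folded to minor-allele orientation by default."""
    (alt1, n1), (alt2, n2) = _counts_for_pops(table, pops)
    data = np.zeros((n1 + 1, n2 + 1))
    np.add.at(data, (alt1, alt2), 1.0)
    sfs = JointSFS(data, (n1, n2), folded=False, pop_labels=tuple(pops))
    return sfs.fold() if folded else sfs


def sfs_1d(table: GenotypeTable, pop: str, folded: bool = True) -> JointSFS:
    """1D (minor-)allele-count histogram over one population's haploid sample."""
    ((alt, n),) = _counts_for_pops(table, (pop,))
    data = np.bincount(alt, minlength=n + 1).astype(np.float64)
    sfs = JointSFS(data, (n,), folded=False, pop_labels=(pop,))
    return sfs.fold() if folded else sfs


# -- fastsimcoal2-style observed-SFS text dialect --------------------------

def write_obs(sfs: JointSFS, path) -> None:
    """Write ``1 observations`` header, d0_i column labels, d1_j row labels."""
    n1 = sfs.sample_sizes[0]
    with open(path, "w") as fh:
        fh.write("1 observations\n")
        fh.write("\t".join(f"d0_{i}" for i in range(n1 + 1)) + "\n")
        if sfs.data.ndim == 1:
            fh.write("\t".join(_fmt(v) for v in sfs.data) + "\n")
        else:
            n2 = sfs.sample_sizes[1]
            for j in range(n2 + 1):
                row = "\t".join(_fmt(sfs.data[i, j]) for i in range(n1 + 1))
                fh.write(f"d1_{j}\t{row}\n")


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def read_obs(path, folded: bool = True,
             pop_labels: tuple[str, ...] = ()) -> JointSFS:
    """Read the observed-SFS dialect written by :func:`write_obs`.

    The file does not record foldedness; pass ``folded`` explicitly
    (default True, the minor-allele convention used throughout).
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise ValueError(f"{path}: truncated observed-SFS file")
    if "observations" not in lines[0]:
        raise ValueError(f"{path}: malformed header line {lines[0]!r}")
    cols = lines[1].split("\t")
    if not all(c.startswith("d0_") for c in cols):
        raise ValueError(f"{path}: malformed column-label line")
    n1 = len(cols) - 1
    body = lines[2:]
    if body[0].split("\t")[0].startswith("d1_"):
        rows = []
        for ln in body:
            parts = ln.split("\t")
            if not parts[0].startswith("d1_"):
                raise ValueError(f"{path}: malformed row label {parts[0]!r}")
            vals = [float(v) for v in parts[1:]]
            if len(vals) != n1 + 1:
                raise ValueError(f"{path}: ragged matrix row {parts[0]!r}")
            rows.append(vals)
        data = np.array(rows).T  # rows are d1_j -> axis 1
        if np.any(data < 0):
            raise ValueError(f"{path}: negative SFS entries")
        return JointSFS(data, (n1, len(rows) - 1), folded=folded,
                        pop_labels=pop_labels)
    if len(body) != 1:
        raise ValueError(f"{path}: expected a single data row for a 1D spectrum")
    vals = [float(v) for v in body[0].split("\t")]
    if len(vals) != n1 + 1:
        raise ValueError(f"{path}: ragged 1D spectrum")
    if any(v < 0 for v in vals):
        raise ValueError(f"{path}: negative SFS entries")
    return JointSFS(np.array(vals), (n1,), folded=folded, pop_labels=pop_labels)


def to_tsv(sfs: JointSFS, path) -> None:
    """Plain TSV matrix export (no labels)."""
    np.savetxt(path, np.atleast_2d(sfs.data), delimiter="\t", fmt="%.10g")
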