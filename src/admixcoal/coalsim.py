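"""Backward-in-time coalescent simulation over independent RAD-style loci.

This module is both the simulation engine behind the composite-likelihood
fits (expected SFS under a candidate demography) and the synthetic-data
generator for the whole pipeline.  Defaults emulate the study design: two
diploid populations of 10 individuals, 4,703 unlinked loci of 51 bp, and a
mutation rate of 3.5e-9 per site per generation.

Mutation model is infinite sites (every mutation a new biallelic SNP), no
intra-locus recombination, loci fully unlinked.  Haploid sequences are
paired at random into diploids, so Hardy-Weinberg proportions hold by
construction.  Reproducibility: one master seed; per-locus streams are
derived deterministically with numpy's SeedSequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernel
from .genotypes import GenotypeTable
from .models import ModelSpec
from .spectra import JointSFS

__all__ = ["SimulationConfig", "LocusGenealogy", "simulate_genealogy",
           "drop_mutations", "simulate_dataset", "expected_sfs",
           "simulate_sfs_counts", "locus_seeds_for"]

_NUC = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for synthetic ddRAD data.

    sample_sizes are diploid individuals per population; ts_fraction is the
    probability that a simulated SNP is a transition (default matches the
    transition fraction of the study's 1,552-SNP panel, 887/1,552).
    """

    sample_sizes: tuple[int, ...] = (10, 10)
    n_loci: int = 4703
    locus_length: int = 51
    mu: float = 3.5e-9
    seed: int = 0
    ts_fraction: float = 887.0 / 1552.0

    def __post_init__(self):
        if any(n <= 0 for n in self.sample_sizes):
            raise ValueError("sample sizes must be positive")
        if self.n_loci < 0 or self.locus_length <= 0:
            raise ValueError("n_loci must be >= 0 and locus_length positive")
        if not 0.0 < self.mu < 1e-6:
            raise ValueError(f"mu must be in (0, 1e-6), got {self.mu}")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)

    def haploid_sizes(self, n_pops: int) -> tuple[int, ...]:
        if len(self.sample_sizes) < n_pops:
            raise ValueError(
                f"model samples {n_pops} populations but config provides "
                f"{len(self.sample_sizes)} sample sizes")
        return tuple(2 * n for n in self.sample_sizes[:n_pops])

    @property
    def theta_branch(self) -> float:
        """Per-branch mutation intensity mu * locus_length."""
        return self.mu * self.locus_length


@dataclass
class LocusGenealogy:
    """A single-locus coalescent tree (node times in generations)."""

    parent: np.ndarray
    lchild: np.ndarray
    rchild: np.ndarray
    node_time: np.ndarray
    sample_pop: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.sample_pop.shape[0]

    @property
    def tmrca(self) -> float:
        return float(self.node_time[-1])

    @property
    def coalescence_times(self) -> np.ndarray:
        return self.node_time[self.n_samples:]

    def branch_lengths(self) -> np.ndarray:
        bl = np.zeros_like(self.node_time)
        has_parent = self.parent >= 0
        bl[has_parent] = (self.node_time[self.parent[has_parent]]
                          - self.node_time[has_parent])
        return bl

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())


def locus_seeds_for(master_seed: int, n: int, stream: int = 0) -> np.ndarray:
    """Deterministic per-locus RNG seeds derived from one master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(stream)])
    state = ss.generate_state(n, dtype=np.uint32).astype(np.int64)
    return state & np.int64(0x7FFFFFFF)


def _sample_pop_vector(model: ModelSpec, config: SimulationConfig) -> np.ndarray:
    hap = config.haploid_sizes(model.n_sampled_pops)
    return np.repeat(np.arange(len(hap), dtype=np.int64), hap)


def simulate_genealogy(model: ModelSpec, config: SimulationConfig,
                       locus_index: int = 0) -> LocusGenealogy:
    """Genealogy of locus ``locus_index`` under ``model`` (exact, continuous time)."""
    dem = model.compile()
    sample_pop = _sample_pop_vector(model, config)
    seed = int(locus_seeds_for(config.seed, locus_index + 1)[locus_index])
    parent, lchild, rchild, node_time = _kernel.sim_one(
        *dem.as_tuple(), sample_pop, seed)
    return LocusGenealogy(parent, lchild, rchild, node_time, sample_pop)


def drop_mutations(genealogy: LocusGenealogy, locus_length: int, mu: float,
                   seed: int = 0) -> np.ndarray:
    """Infinite-sites mutations: (n_sites, n_samples) derived-state matrix.

    Each branch receives Poisson(branch_length * mu * locus_length)
    mutations, each of which is a new segregating site carried by every
    sampled lineage below the branch.
    """
    return _kernel.mutate_locus_seeded(
        genealogy.parent, genealogy.lchild, genealogy.rchild,
        genealogy.node_time, genealogy.n_samples,
        mu * locus_length, int(seed))


def _draw_ref_alt(rng: np.random.Generator, ts_fraction: float) -> tuple[str, str]:
    ref = str(rng.choice(_NUC))
    if rng.random() < ts_fraction:
        return ref, _TRANSITION[ref]
    return ref, _TRANSVERSIONS[ref][rng.integers(2)]


def simulate_dataset(model: ModelSpec, config: SimulationConfig,
                     pop_labels: tuple[str, ...] = ()) -> GenotypeTable:
    """Simulate a complete genotype table (no missing calls).

    Haploid sequences 2i and 2i+1 form diploid individual i; REF/ALT
    nucleotides are drawn with the configured transition fraction (ALT is
    the derived allele).  Bit-identical across runs for a fixed seed.
    """
    dem = model.compile()
    sample_pop = _sample_pop_vector(model, config)
    n_pops = model.n_sampled_pops
    if not pop_labels:
        pop_labels = tuple(model.populations[:n_pops])
    seeds = locus_seeds_for(config.seed, max(config.n_loci, 1))
    nuc_rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 1]))
    theta = config.theta_branch

    dip_per_pop = config.sample_sizes[:n_pops]
    samples = [f"{pop_labels[p]}_{i+1:02d}"
               for p in range(n_pops) for i in range(dip_per_pop[p])]
    pops = np.array([pop_labels[p]
                     for p in range(n_pops) for _ in range(dip_per_pop[p])],
                    dtype=object)

    loci, positions, refs, alts, rows = [], [], [], [], []
    width = max(4, len(str(config.n_loci)))
    for l in range(config.n_loci):
        sites = _kernel.sim_sites_one(*dem.as_tuple(), sample_pop,
                                      int(seeds[l]), theta)
        n_sites = sites.shape[0]
        if n_sites == 0:
            continue
        if n_sites > config.locus_length:
            raise RuntimeError(
                f"locus {l}: {n_sites} mutations exceed locus length "
                f"{config.locus_length}; infinite-sites assumption broken")
        pos = np.sort(nuc_rng.choice(config.locus_length, size=n_sites,
                                     replace=False)) + 1
        name = f"locus_{l:0{width}d}"
        # pair haploids into diploid dosages
        dosage = sites[:, 0::2].astype(np.int8) + sites[:, 1::2].astype(np.int8)
        for s in range(n_sites):
            ref, alt = _draw_ref_alt(nuc_rng, config.ts_fraction)
            loci.append(name)
            positions.append(int(pos[s]))
            refs.append(ref)
            alts.append(alt)
            rows.append(dosage[s])
    snps = pd.DataFrame({"locus": loci, "pos": positions,
                         "ref": refs, "alt": alts})
    geno = (np.vstack(rows) if rows
            else np.empty((0, len(samples)), dtype=np.int8))
    return GenotypeTable(snps, geno, samples, pops)


def expected_sfs(model: ModelSpec, config: SimulationConfig,
                 n_replicates: int, folded: bool = True,
                 locus_seeds: np.ndarray | None = None,
                 return_mean_tree_length: bool = False):
    """Monte-Carlo expected SFS: probability a segregating site falls in
    each (folded) joint-SFS cell, estimated by branch-length weighting.

    Branch weighting integrates the mutation process out analytically
    (each cell's probability is proportional to the expected branch length
    subtending it), which removes all Poisson noise relative to sampling
    mutations; ``n_replicates`` is the number of independent locus
    genealogies averaged.

    With ``return_mean_tree_length`` the per-locus mean total branch length
    (generations) is returned alongside — the quantity that, multiplied by
    the per-site mutation rate, gives the probability that a site is
    polymorphic (used by the monomorphic-class likelihood term).
    """
    if n_replicates < 1 and locus_seeds is None:
        raise ValueError("n_replicates must be >= 1")
    dem = model.compile()
    sample_pop = _sample_pop_vector(model, config)
    if locus_seeds is None:
        locus_seeds = locus_seeds_for(config.seed, n_replicates)
    hap = config.haploid_sizes(model.n_sampled_pops)
    n1 = hap[0]
    n2 = hap[1] if len(hap) > 1 else 0
    mass = _kernel.branch_sfs_many(*dem.as_tuple(), sample_pop,
                                   np.asarray(locus_seeds, dtype=np.int64),
                                   n1, n2)
    total_mass = mass.sum()
    if total_mass <= 0:
        raise ValueError("no branch mass accumulated; check the model")
    mean_tree_length = total_mass / len(locus_seeds)
    if model.n_sampled_pops == 1:
        sfs = JointSFS(mass[:, 0], (n1,), folded=False,
                       pop_labels=tuple(model.populations[:1]))
    else:
        sfs = JointSFS(mass, (n1, n2), folded=False,
                       pop_labels=tuple(model.populations[:2]))
    if folded:
        sfs = sfs.fold()
    sfs = sfs.normalized()
    if return_mean_tree_length:
        return sfs, mean_tree_length
    return sfs


def simulate_sfs_counts(model: ModelSpec, config: SimulationConfig,
                        folded: bool = True) -> JointSFS:
    """Sampled SFS counts (Poisson mutations), bypassing the genotype table.

    With the same config this matches the spectrum of
    :func:`simulate_dataset` exactly (shared per-locus streams).
    """
    dem = model.compile()
    sample_pop = _sample_pop_vector(model, config)
    seeds = locus_seeds_for(config.seed, max(config.n_loci, 1))
    hap = config.haploid_sizes(model.n_sampled_pops)
    n1 = hap[0]
    n2 = hap[1] if len(hap) > 1 else 0
    counts = _kernel.count_sfs_many(*dem.as_tuple(), sample_pop,
                                    seeds[:config.n_loci], config.theta_branch,
                                    n1, n2)
    if model.n_sampled_pops == 1:
        sfs = JointSFS(counts[:, 0], (n1,), folded=False,
                       pop_labels=tuple(model.populations[:1]))
    else:
        sfs = JointSFS(counts, (n1, n2), folded=False,
                       pop_labels=tuple(model.populations[:2]))
    return sfs.fold() if folded else sfs
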