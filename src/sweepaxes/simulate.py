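"""Forward Wright-Fisher simulator of phased multi-population haplotypes.

The simulator is the test substrate for the whole pipeline: several
populations descend from a common ancestral population, drift apart, and
optionally experience positive selection at configured loci, producing the
hitchhiking structure the scan statistics assume — with the ancestral
state of every SNP known by construction.

Model
-----
Discrete generations; each population holds ``2 * N_e`` haplotypes paired
into diploids.  Every generation each child haplotype picks a parent
diploid (fitness-weighted multinomial under selection, uniform otherwise)
and recombines its two haplotypes with a Poisson number of crossovers
placed uniformly in genetic distance.  Mutation is infinite-sites-style
onto a fixed grid of pre-allocated SNP slots (ancestral = 0): new
mutations land on slots currently empty in every population, so all
populations stay aligned to one SNP map.  Selection at a sweep site is
genotype viability (1, 1 + s/2, 1 + s per derived copy).  Population sizes
are desk-scale; diffusion scaling (same 4*N_e*mu, 4*N_e*r, 2*N_e*s) maps
them to realistic parameter regimes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .io import HaplotypeSet, SnpMap

log = logging.getLogger(__name__)


@dataclass
class SweepSpec:
    population: str
    snp_index: int
    s: float                 # selection coefficient per derived copy
    start_gen: int
    rescue: bool = True      # re-seed the allele if lost (<= 100 attempts)
    init_copies: int = 1     # 1 = de novo mutation; >1 = standing variant


@dataclass
class SimConfig:
    """Full description of one simulation run (seed mandatory)."""

    seed: int
    n_snps: int = 20_000
    chrom_length_bp: int = 20_000_000
    mutation_rate: float = 1e-7          # per bp per generation
    recomb_rate_cm_per_mb: float = 10.0
    N_e: int = 200                       # diploids, every population
    split_schedule: list = field(default_factory=list)  # (gen, parent, children)
    total_gen: int = 950
    sample_size: int = 50                # haplotypes per population (even)
    sweeps: list = field(default_factory=list)
    init: str = "stationary"             # or "monomorphic"
    init_freq: float = None              # overrides init: fixed derived freq
    drop_monomorphic: bool = True
    root_pop: str = "ancestral"

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        times = [t for t, _, _ in self.split_schedule]
        if times != sorted(times):
            raise ValueError("split times must be ordered")
        for sw in self.sweeps:
            if not (0.0 < sw.s <= 1.0):
                raise ValueError("selection coefficient must be in (0, 1]")
            if not (0 <= sw.snp_index < self.n_snps):
                raise ValueError("sweep snp_index outside the SNP grid")
        if self.sample_size > 2 * self.N_e:
            raise ValueError("sample_size exceeds 2*N_e")
        if self.sample_size % 2:
            raise ValueError("sample_size must be even (phased diploids)")


@dataclass
class SweepOutcome:
    population: str
    snp_index: int
    snp_id: str
    pos_bp: int
    s: float
    final_freq: float        # derived frequency in the full population at the end
    attempts: int
    lost: bool


@dataclass
class SimTruth:
    sweeps: list
    split_gens: dict         # population pair -> generations since split at sampling


def _theta(config: SimConfig) -> float:
    return 4.0 * config.N_e * config.mutation_rate * config.chrom_length_bp


def _stationary_init(rng, n2, m, theta):
    """Draw the neutral equilibrium SFS: E[# sites at derived count i] =
    theta / i, assigned independently per slot (no LD; the burn-in builds
    the genealogical correlation)."""
    H = np.zeros((n2, m), dtype=np.uint8)
    a = np.sum(1.0 / np.arange(1, n2))
    q = min(0.98, theta * a / m)
    occupied = rng.random(m) < q
    probs = (1.0 / np.arange(1, n2))
    probs = probs / probs.sum()
    for j in np.flatnonzero(occupied):
        i = rng.choice(np.arange(1, n2), p=probs)
        rows = rng.choice(n2, size=i, replace=False)
        H[rows, j] = 1
    return H


def simulate(config: SimConfig):
    """Run the simulation; returns (HaplotypeSet, SnpMap, SimTruth)."""
    rng = np.random.default_rng(config.seed)
    m = config.n_snps
    n2 = 2 * config.N_e
    spacing = max(1, config.chrom_length_bp // m)
    pos_bp = spacing * np.arange(1, m + 1, dtype=np.int64)
    pos_cm = pos_bp * (config.recomb_rate_cm_per_mb / 1e6)
    total_cm = float(pos_cm[-1] - pos_cm[0])
    morgans = total_cm / 100.0
    mu_genome = config.mutation_rate * config.chrom_length_bp

    if config.init_freq is not None:
        H0 = np.zeros((n2, m), dtype=np.uint8)
        cnt0 = int(round(n2 * config.init_freq))
        for j in range(m):
            H0[rng.choice(n2, size=cnt0, replace=False), j] = 1
    elif config.init == "stationary":
        H0 = _stationary_init(rng, n2, m, _theta(config))
    elif config.init == "monomorphic":
        H0 = np.zeros((n2, m), dtype=np.uint8)
    else:
        raise ValueError(f"unknown init {config.init!r}")

    pops = {config.root_pop: H0}
    counts = {config.root_pop: H0.sum(axis=0).astype(np.int64)}
    children_buf = {config.root_pop: np.empty_like(H0)}
    split_at = {t: (parent, kids) for t, parent, kids in config.split_schedule}
    pop_born = {config.root_pop: 0}

    sweep_state = [{"spec": sw, "attempts": 0, "active": False, "lost": False}
                   for sw in config.sweeps]
    reserved = {sw.snp_index for sw in config.sweeps}
    fitness_table = {}

    for gen in range(config.total_gen):
        if gen in split_at:
            parent, kids = split_at[gen]
            H = pops.pop(parent)
            counts.pop(parent)
            children_buf.pop(parent)
            for kid in kids:
                pops[kid] = H.copy()
                counts[kid] = pops[kid].sum(axis=0).astype(np.int64)
                children_buf[kid] = np.empty_like(H)
                pop_born[kid] = gen
        # start (or rescue) sweeps
        for st in sweep_state:
            sw = st["spec"]
            if sw.population not in pops:
                continue
            if gen == sw.start_gen and not st["active"]:
                _seed_sweep(pops[sw.population], counts[sw.population], sw, st, rng)
            elif st["active"] and not st["lost"] and \
                    counts[sw.population][sw.snp_index] == 0:
                if sw.rescue:
                    if st["attempts"] >= 100:
                        raise RuntimeError(
                            f"sweep at SNP {sw.snp_index} lost 100 times")
                    _seed_sweep(pops[sw.population], counts[sw.population],
                                sw, st, rng)
                else:
                    st["lost"] = True

        # free slots: empty in every population (reserved sweep slots excluded)
        free = np.ones(m, dtype=bool)
        for c in counts.values():
            free &= c == 0
        for r in reserved:
            free[r] = False
        free_idx = np.flatnonzero(free)

        for name, H in pops.items():
            N = H.shape[0] // 2
            # parent choice
            active = [st for st in sweep_state
                      if st["active"] and not st["lost"]
                      and st["spec"].population == name]
            if active:
                w = np.ones(N)
                for st in active:
                    sw = st["spec"]
                    g = (H[0::2, sw.snp_index].astype(np.int64)
                         + H[1::2, sw.snp_index])
                    tab = fitness_table.setdefault(
                        sw.s, np.array([1.0, 1.0 + sw.s / 2.0, 1.0 + sw.s]))
                    w = w * tab[g]
                cw = np.cumsum(w)
                parents = np.searchsorted(cw, rng.random(2 * N) * cw[-1])
            else:
                parents = rng.integers(0, N, size=2 * N)
            pa = (2 * parents).astype(np.int64)
            pb = pa + 1
            start_hap = rng.integers(0, 2, size=2 * N).astype(np.int64)
            ncx = rng.poisson(morgans, size=2 * N)
            k_total = int(ncx.sum())
            bk_off = np.zeros(2 * N + 1, dtype=np.int64)
            np.cumsum(ncx, out=bk_off[1:])
            if k_total:
                u = rng.random(k_total) * total_cm + pos_cm[0]
                bk = np.searchsorted(pos_cm, u).astype(np.int64)
                for i in np.flatnonzero(ncx > 1):
                    bk[bk_off[i]:bk_off[i + 1]].sort()
            else:
                bk = np.zeros(0, dtype=np.int64)
            cnt = counts[name]
            cnt[:] = 0
            child = children_buf[name]
            K.wf_generation(H, child, pa, pb, start_hap, bk, bk_off, cnt)
            pops[name], children_buf[name] = child, H

            # mutation onto free slots
            n_mut = rng.poisson(2 * N * mu_genome)
            if n_mut and free_idx.size:
                n_mut = min(n_mut, free_idx.size)
                slots = rng.choice(free_idx, size=n_mut, replace=False)
                haps = rng.integers(0, 2 * N, size=n_mut)
                Hn = pops[name]
                for slot, hap in zip(slots, haps):
                    if Hn[hap, slot] == 0:
                        Hn[hap, slot] = 1
                        cnt[slot] += 1
                # keep this generation's placements disjoint across populations
                free_idx = np.setdiff1d(free_idx, slots, assume_unique=True)

    # sample haplotypes
    sampled, labels = [], []
    for name in sorted(pops):
        H = pops[name]
        N = H.shape[0] // 2
        dips = rng.choice(N, size=config.sample_size // 2, replace=False)
        rows = np.sort(np.concatenate([2 * dips, 2 * dips + 1]))
        sampled.append(H[rows])
        labels.extend([name] * rows.size)
    alleles = np.vstack(sampled)

    snp_id = np.asarray([f"snp{j}" for j in range(m)], dtype=object)
    snp_map = SnpMap(np.asarray(["1"] * m, dtype=object), pos_bp, pos_cm,
                     snp_id, np.asarray(["A"] * m, dtype=object))

    outcomes = []
    for st in sweep_state:
        sw = st["spec"]
        freq = (counts[sw.population][sw.snp_index] /
                pops[sw.population].shape[0]) if sw.population in pops else 0.0
        outcomes.append(SweepOutcome(sw.population, sw.snp_index,
                                     str(snp_id[sw.snp_index]),
                                     int(pos_bp[sw.snp_index]), sw.s,
                                     float(freq), st["attempts"], st["lost"]))
    split_gens = {}
    names = sorted(pops)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            t = config.total_gen - max(pop_born[names[i]], pop_born[names[j]])
            split_gens[(names[i], names[j])] = t

    if config.drop_monomorphic:
        c = alleles.sum(axis=0)
        keep = np.flatnonzero((c > 0) & (c < alleles.shape[0]))
        alleles = alleles[:, keep]
        snp_map = snp_map.take(keep)
    haps = HaplotypeSet(alleles, labels, snp_map)
    return haps, snp_map, SimTruth(outcomes, split_gens)


def _seed_sweep(H, cnt, sw, st, rng):
    k = min(sw.init_copies, H.shape[0])
    rows = rng.choice(H.shape[0], size=k, replace=False)
    H[rows, sw.snp_index] = 1
    cnt[sw.snp_index] = int(H[:, sw.snp_index].sum())
    st["active"] = True
    st["attempts"] += 1


# ---------------------------------------------------------------------------
# presets: the documented desk-scale study conditions

def preset_neutral(seed: int = 0) -> SimConfig:
    """Two populations, 20k SNP slots over 20 Mb, stationary start plus a
    4*N_e-generation burn-in, split 150 generations before sampling, 50
    haplotypes sampled per population.

    Parameters are a lambda = 10 diffusion rescaling of a cattle-like
    scenario (N_e = 2000, mu = 1e-8/bp, r = 1 cM/Mb): N_e = 200,
    mu = 1e-7, r = 10 cM/Mb, so 4*N_e*mu and 4*N_e*r per bp — the
    quantities the scan statistics respond to — match the emulated
    population."""
    return SimConfig(seed=seed,
                     split_schedule=[(800, "ancestral", ["pop1", "pop2"])],
                     total_gen=950)


def preset_sweep(seed: int = 0, s: float = 0.5) -> SimConfig:
    """The neutral preset plus one sweep at the midpoint SNP of pop1,
    started after the split and sampled mid-sweep.

    At desk-scale N_e = 200 the selection coefficient is diffusion-scaled
    to keep 2*N_e*s in the strongly selected regime (2*N_e*s = 200 at the
    default s = 0.5); a single-copy (hard-sweep) introduction keeps the
    swept class on one haplotype background, and the 35-generation
    selection window typically leaves the allele at intermediate-to-high
    frequency at sampling — the regime where haplotype-length statistics
    are informative.  Losses are rescued (single origin preserved: a
    re-seed only ever happens when no copy is left)."""
    cfg = preset_neutral(seed)
    cfg.sweeps = [SweepSpec("pop1", cfg.n_snps // 2, s,
                            start_gen=cfg.total_gen - 35)]
    return cfg


def preset_seven_pops(seed: int = 0) -> SimConfig:
    """Seven populations of 48 sampled haplotypes each, star split from one
    ancestral population, on a smaller 5-Mb/5k-SNP genome."""
    return SimConfig(seed=seed, n_snps=5000, chrom_length_bp=5_000_000,
                     split_schedule=[(800, "ancestral",
                                      [f"pop{i}" for i in range(1, 8)])],
                     total_gen=920, sample_size=48)
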