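"""Forward-in-time diploid Wright-Fisher simulation of deleterious variation.

Simulates coding sequence organized as equal-length genes on autosomes, with
free recombination between chromosomes, a fixed crossover probability
between adjacent genes, and complete linkage within genes.  Mutations are
drawn from a discrete DFE with per-bin dominance; fitness is multiplicative
across sites with per-site genotype fitnesses 1 (reference homozygote),
1 - s*h (heterozygote) and 1 - s (mutant homozygote).

Selection here uses the *simulator convention*: s in [0, 1], where s = 1 is
a recessive lethal.  Models fit in the inference convention (homozygote
fitness 1 - 2s, s in [0, 0.5]) are converted by doubling s and the bin
edges; h and the bin proportions are unchanged.

Reported metrics, per replicate and population, from a sample of
``sample_size`` individuals:

* genetic load: 1 - mean multiplicative fitness (segregating + fixed sites),
* inbreeding load B (haploid lethal equivalents):
  sum over segregating sites of s q (1-q) (1-2h), truncated at 0 per site,
* derived allele count: mean derived deleterious alleles per individual,
  counting fixed sites twice.

The engine stores each haplotype as a sorted array of 64-bit keys packing
(gene index << 40 | mutation id), which makes homozygote detection a linear
merge and recombination a sparse walk over mutated genes only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

from .dfe import DiscreteDFE, DominanceMap

__all__ = [
    "GenomeModel",
    "TwoPopDemography",
    "SimulatorDFE",
    "SimulationOutput",
    "MU_DEL",
    "convert_inference_to_sim",
    "draw_mutation_effects",
    "run_two_pop_simulation",
    "run_single_pop_simulation",
    "compute_genetic_load",
    "compute_inbreeding_load",
    "project_half_genome",
]

#: deleterious (nonsynonymous) per-site mutation rate:
#: total coding rate 1.5e-8 times the nonsynonymous fraction 2.31/3.31
MU_DEL = 1.5e-8 * (2.31 / 3.31)

_GENE_SHIFT = 40
_ID_MASK = (1 << _GENE_SHIFT) - 1


@dataclass(frozen=True)
class GenomeModel:
    """Coding-genome architecture for the simulator."""

    n_chromosomes: int = 22
    genes_total: int = 22_500
    gene_length: int = 1340
    r_between_genes: float = 0.001
    r_between_chromosomes: float = 0.5
    r_within_genes: float = 0.0
    mu_del: float = MU_DEL

    @property
    def total_length(self) -> int:
        return self.genes_total * self.gene_length

    @property
    def U(self) -> float:
        """Diploid deleterious mutation rate per individual per generation."""
        return 2.0 * self.total_length * self.mu_del

    @property
    def genes_per_chromosome(self) -> int:
        return -(-self.genes_total // self.n_chromosomes)


@dataclass(frozen=True)
class TwoPopDemography:
    """Two-population out-of-Africa history (sizes diploid, times generations).

    After burn-in at ``N_anc`` the (African) population grows to
    ``N_afr_growth`` for ``T_pre_split`` generations; the European population
    then splits off at ``N_bottleneck`` and stays there until the final
    ``T_growth`` generations, during which both populations grow
    exponentially to their final sizes.  The published epoch lengths
    (1,120 bottleneck + 204 growth) leave the remainder of the 2,040
    generations since the split at the bottleneck size, which is how the gap
    is resolved here.
    """

    N_anc: int = 7_310
    N_afr_growth: int = 14_474
    T_split: int = 2_040
    N_bottleneck: int = 1_861
    T_bottleneck: int = 1_120
    T_growth: int = 204
    N_afr_final: int = 424_000
    N_eur_final: int = 512_000
    T_pre_split: int = 3_880

    def __post_init__(self) -> None:
        if min(self.N_anc, self.N_afr_growth, self.N_bottleneck,
               self.N_afr_final, self.N_eur_final) <= 0:
            raise ValueError("population sizes must be positive")
        if min(self.T_split, self.T_growth) <= 0 or self.T_growth > self.T_split:
            raise ValueError("need 0 < T_growth <= T_split")

    def size_schedule(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-generation (African, European) sizes after the split."""
        T, Tg = self.T_split, self.T_growth
        afr = np.full(T, self.N_afr_growth, dtype=np.int64)
        eur = np.full(T, self.N_bottleneck, dtype=np.int64)
        t = np.arange(1, Tg + 1) / Tg
        afr[T - Tg:] = np.round(
            self.N_afr_growth * (self.N_afr_final / self.N_afr_growth) ** t
        )
        eur[T - Tg:] = np.round(
            self.N_bottleneck * (self.N_eur_final / self.N_bottleneck) ** t
        )
        return afr, eur

    def rescaled(self, factor: float, size_cap: int | None = None) -> "TwoPopDemography":
        """Miniature history: sizes and times divided by ``factor``.

        Selection coefficients are deliberately *not* rescaled (a full
        population-genetic rescaling would push the strongly deleterious bin
        past the lethal bound), so reduced-scale runs are qualitative.
        ``size_cap`` truncates the final growth phase.
        """
        def sz(x):
            v = max(2, int(round(x / factor)))
            return min(v, size_cap) if size_cap else v

        return TwoPopDemography(
            N_anc=sz(self.N_anc),
            N_afr_growth=sz(self.N_afr_growth),
            T_split=max(2, int(round(self.T_split / factor))),
            N_bottleneck=sz(self.N_bottleneck),
            T_bottleneck=max(1, int(round(self.T_bottleneck / factor))),
            T_growth=max(1, int(round(self.T_growth / factor))),
            N_afr_final=sz(self.N_afr_final),
            N_eur_final=sz(self.N_eur_final),
            T_pre_split=max(1, int(round(self.T_pre_split / factor))),
        )


@dataclass
class SimulatorDFE:
    """Discrete DFE in the simulator convention (hom fitness 1 - s, s <= 1)."""

    edges: np.ndarray        # |s| bin boundaries, length n_bins + 1
    proportions: np.ndarray
    h_per_bin: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, float)
        self.proportions = np.asarray(self.proportions, float)
        self.h_per_bin = np.asarray(self.h_per_bin, float)
        if self.edges[-1] > 1.0 + 1e-12:
            raise ValueError("simulator-convention s cannot exceed 1")


def convert_inference_to_sim(
    dfe: DiscreteDFE, dmap: DominanceMap
) -> SimulatorDFE:
    """Double s (and the bin edges); h and proportions are unchanged."""
    edges = np.asarray(dfe.edges, float)
    if edges[-1] > 0.5 + 1e-12:
        raise ValueError("inference-convention s cannot exceed 0.5")
    return SimulatorDFE(
        edges=2.0 * edges,
        proportions=np.asarray(dfe.proportions, float).copy(),
        h_per_bin=np.asarray(dmap.h_per_bin, float).copy(),
    )


def draw_mutation_effects(
    model: SimulatorDFE, size: int, variable_h: bool, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (s, h, bin_id) for ``size`` new mutations.

    The bin is chosen by the model proportions, s is uniform within the bin,
    and h is the bin's mean (fixed mode) or uniform on [0, 2*h_bar]
    (variable mode).
    """
    b = rng.choice(len(model.proportions), size=size, p=model.proportions)
    s = rng.uniform(model.edges[b], model.edges[b + 1])
    if variable_h:
        h = rng.uniform(0.0, 2.0 * model.h_per_bin[b])
    else:
        h = model.h_per_bin[b].copy()
    return s, h, b


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _seed_numba(seed):
    np.random.seed(seed)


@njit(cache=True)
def _fitness_kernel(data, off, n_ind, mut_s, mut_h, out_w):
    for i in range(n_ind):
        a, a1 = off[2 * i], off[2 * i + 1]
        b, b1 = off[2 * i + 1], off[2 * i + 2]
        w = 1.0
        while a < a1 and b < b1:
            ka, kb = data[a], data[b]
            if ka == kb:
                mid = ka & _ID_MASK
                w *= 1.0 - mut_s[mid]
                a += 1
                b += 1
            elif ka < kb:
                mid = ka & _ID_MASK
                w *= 1.0 - mut_s[mid] * mut_h[mid]
                a += 1
            else:
                mid = kb & _ID_MASK
                w *= 1.0 - mut_s[mid] * mut_h[mid]
                b += 1
        while a < a1:
            mid = data[a] & _ID_MASK
            w *= 1.0 - mut_s[mid] * mut_h[mid]
            a += 1
        while b < b1:
            mid = data[b] & _ID_MASK
            w *= 1.0 - mut_s[mid] * mut_h[mid]
            b += 1
        out_w[i] = max(w, 0.0)


@njit(cache=True)
def _gamete_kernel(
    data, a, a1, b, b1, genes_per_chrom, flip_base, out, m0
):
    """Recombinant gamete of one parent into out[m0:]; returns new end index.

    ``flip_base`` = 1 - 2*r_between_genes; the probability that the source
    haplotype flips across d gene boundaries is (1 - flip_base**d) / 2.
    """
    cur = 0 if np.random.random() < 0.5 else 1
    last_gene = np.int64(-1)
    last_chrom = np.int64(-1)
    m = m0
    while a < a1 or b < b1:
        if a < a1 and (b >= b1 or data[a] <= data[b]):
            key = data[a]
            in_a = True
            in_b = b < b1 and data[b] == key
        else:
            key = data[b]
            in_a = False
            in_b = True
        gene = key >> _GENE_SHIFT
        if gene != last_gene:
            chrom = gene // genes_per_chrom
            if last_chrom >= 0:
                if chrom != last_chrom:
                    cur = 0 if np.random.random() < 0.5 else 1
                else:
                    d = gene - last_gene
                    p_flip = 0.5 * (1.0 - flip_base ** d)
                    if np.random.random() < p_flip:
                        cur = 1 - cur
            last_gene, last_chrom = gene, chrom
        if (in_a and in_b) or (in_a and cur == 0) or (in_b and cur == 1):
            out[m] = key
            m += 1
        if in_a:
            a += 1
        if in_b:
            b += 1
    return m


@njit(cache=True)
def _step_kernel(
    data, off, n_par,
    mut_s, mut_h, n_muts,
    N_next, genes_total, genes_per_chrom, flip_base,
    u_gamete,
    p_cum, edge_lo, edge_hi, h_bar, variable_h,
    new_data, new_off,
    new_s, new_h,
):
    """One Wright-Fisher generation.  Returns (n_muts_out, total_entries).

    Returns (-1, -1) if the output buffers are too small (caller regrows) and
    (-2, -2) if every parent has fitness zero.
    """
    w = np.empty(n_par)
    _fitness_kernel(data, off, n_par, mut_s, mut_h, w)
    tot = 0.0
    for i in range(n_par):
        tot += w[i]
    if tot <= 0.0:
        return -2, -2
    cum = np.empty(n_par)
    acc = 0.0
    for i in range(n_par):
        acc += w[i]
        cum[i] = acc

    cap_data = new_data.shape[0]
    cap_mut = new_s.shape[0]
    nm = n_muts
    m = 0
    new_off[0] = 0
    for child in range(N_next):
        for side in range(2):
            r = np.random.random() * tot
            p = np.searchsorted(cum, r)
            if p >= n_par:
                p = n_par - 1
            a, a1 = off[2 * p], off[2 * p + 1]
            b, b1 = off[2 * p + 1], off[2 * p + 2]
            if m + (a1 - a) + (b1 - b) + 64 > cap_data:
                return -1, -1
            start = m
            m = _gamete_kernel(
                data, a, a1, b, b1, genes_per_chrom, flip_base, new_data, m
            )
            n_new = np.random.poisson(u_gamete)
            if n_new > 0:
                if nm + n_new > cap_mut or m + n_new > cap_data:
                    return -1, -1
                for _ in range(n_new):
                    # draw bin, then s uniform within it
                    rb = np.random.random()
                    bin_id = np.searchsorted(p_cum, rb)
                    if bin_id >= p_cum.shape[0]:
                        bin_id = p_cum.shape[0] - 1
                    s_val = edge_lo[bin_id] + np.random.random() * (
                        edge_hi[bin_id] - edge_lo[bin_id]
                    )
                    if variable_h:
                        h_val = np.random.random() * 2.0 * h_bar[bin_id]
                    else:
                        h_val = h_bar[bin_id]
                    gene = np.int64(np.random.random() * genes_total)
                    new_s[nm] = s_val
                    new_h[nm] = h_val
                    new_data[m] = (gene << _GENE_SHIFT) | nm
                    nm += 1
                    m += 1
                # keep the haplotype sorted after appending new mutations
                seg = np.sort(new_data[start:m])
                new_data[start:m] = seg
            new_off[2 * child + side + 1] = m
    return nm, m


@njit(cache=True)
def _occupancy_kernel(data, n_entries, counts):
    for i in range(n_entries):
        counts[data[i] & _ID_MASK] += 1


# ---------------------------------------------------------------------------
# python-level engine
# ---------------------------------------------------------------------------

class _Population:
    """CSR haplotype store: data[off[k]:off[k+1]] are haplotype k's keys."""

    def __init__(self, n_ind: int):
        self.n_ind = n_ind
        self.data = np.empty(0, dtype=np.int64)
        self.off = np.zeros(2 * n_ind + 1, dtype=np.int64)
        self.fixed_s: list[float] = []
        self.fixed_h: list[float] = []

    @property
    def fixed_log_w(self) -> float:
        s = np.asarray(self.fixed_s)
        if np.any(s >= 1.0):
            return -np.inf
        return float(np.sum(np.log1p(-s))) if len(s) else 0.0


class _Engine:
    def __init__(self, genome: GenomeModel, model: SimulatorDFE,
                 variable_h: bool, seed: int):
        self.genome = genome
        self.model = model
        self.variable_h = variable_h
        self.mut_s = np.zeros(1024)
        self.mut_h = np.zeros(1024)
        self.n_muts = 0
        p = model.proportions / model.proportions.sum()
        self.p_cum = np.cumsum(p)
        self.edge_lo = model.edges[:-1].copy()
        self.edge_hi = model.edges[1:].copy()
        self.h_bar = model.h_per_bin.copy()
        self.flip_base = 1.0 - 2.0 * genome.r_between_genes
        _seed_numba(seed % (2**31 - 1))

    def _grow_muts(self, needed: int) -> None:
        cap = len(self.mut_s)
        while cap < needed:
            cap *= 2
        if cap > len(self.mut_s):
            self.mut_s = np.resize(self.mut_s, cap)
            self.mut_h = np.resize(self.mut_h, cap)

    def step(self, pop: _Population, N_next: int) -> _Population:
        out = _Population(N_next)
        cap = max(4 * len(pop.data) // 2 + 4096, int(2.5 * len(pop.data) * N_next / max(pop.n_ind, 1)) + 4096)
        u_gamete = self.genome.U / 2.0
        while True:
            self._grow_muts(self.n_muts + int(8 * N_next * u_gamete) + 1024)
            new_data = np.empty(cap, dtype=np.int64)
            new_off = np.zeros(2 * N_next + 1, dtype=np.int64)
            nm, m = _step_kernel(
                pop.data, pop.off, pop.n_ind,
                self.mut_s, self.mut_h, self.n_muts,
                N_next, self.genome.genes_total,
                self.genome.genes_per_chromosome, self.flip_base,
                u_gamete,
                self.p_cum, self.edge_lo, self.edge_hi, self.h_bar,
                self.variable_h,
                new_data, new_off,
                self.mut_s, self.mut_h,
            )
            if nm == -2:
                raise RuntimeError("population extinct: all parental fitness is zero")
            if nm >= 0:
                break
            cap *= 2
        self.n_muts = nm
        out.data = new_data[:m].copy()
        out.off = new_off
        out.fixed_s = pop.fixed_s
        out.fixed_h = pop.fixed_h
        return out

    def compact(self, pops: list[_Population]) -> None:
        """Drop lost mutations, move per-population fixations to the fixed
        registries, and renumber the remaining mutation ids."""
        if self.n_muts == 0:
            return
        counts = [np.zeros(self.n_muts, dtype=np.int64) for _ in pops]
        for pop, cnt in zip(pops, counts):
            _occupancy_kernel(pop.data, len(pop.data), cnt)
        # per-pop fixation: remove from that pop, record its effect
        for pop, cnt in zip(pops, counts):
            fixed = cnt == 2 * pop.n_ind
            if np.any(fixed):
                ids = pop.data & _ID_MASK
                keep = ~fixed[ids]
                pop.data = pop.data[keep]
                self._rebuild_offsets(pop, keep)
                fx = np.nonzero(fixed)[0]
                pop.fixed_s.extend(self.mut_s[fx].tolist())
                pop.fixed_h.extend(self.mut_h[fx].tolist())
                cnt[fx] = 0
        total = np.sum(counts, axis=0)
        alive = total > 0
        n_alive = int(alive.sum())
        remap = np.full(self.n_muts, -1, dtype=np.int64)
        remap[alive] = np.arange(n_alive)
        new_s = np.zeros(max(1024, 2 * n_alive))
        new_h = np.zeros_like(new_s)
        new_s[:n_alive] = self.mut_s[: self.n_muts][alive]
        new_h[:n_alive] = self.mut_h[: self.n_muts][alive]
        self.mut_s, self.mut_h, self.n_muts = new_s, new_h, n_alive
        for pop in pops:
            ids = pop.data & _ID_MASK
            genes = pop.data >> _GENE_SHIFT
            pop.data = (genes << _GENE_SHIFT) | remap[ids]

    @staticmethod
    def _rebuild_offsets(pop: _Population, keep: np.ndarray) -> None:
        removed_before = np.concatenate(([0], np.cumsum(~keep)))
        pop.off = pop.off - removed_before[pop.off]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def compute_genetic_load(
    sample_w: np.ndarray, fixed_log_w: float = 0.0
) -> float:
    """1 - mean multiplicative fitness over sampled individuals."""
    return float(1.0 - np.mean(sample_w) * np.exp(fixed_log_w))


def compute_inbreeding_load(
    q: np.ndarray, s: np.ndarray, h: np.ndarray
) -> float:
    """Haploid lethal equivalents B = sum s q (1-q) (1-2h), per-site >= 0.

    This is the difference in expected log fitness between fully inbred
    (F = 1) and outbred (F = 0) genotype proportions under per-site
    Hardy-Weinberg-with-inbreeding, to first order in s.  Sites with
    h = 0.5 contribute nothing; fixed sites (q = 1) contribute nothing.
    """
    contrib = s * q * (1.0 - q) * (1.0 - 2.0 * h)
    return float(np.sum(np.clip(contrib, 0.0, None)))


@dataclass
class SimulationOutput:
    """Per-replicate, per-population load metrics (tidy table)."""

    table: pd.DataFrame
    projected: bool = False
    meta: dict = field(default_factory=dict)

    def population_mean(self, metric: str) -> pd.Series:
        return self.table.groupby("population")[metric].mean()


def project_half_genome(output: SimulationOutput) -> SimulationOutput:
    """Project half-genome results to a full genome.

    Mean fitness w is squared (load 1 - w -> 1 - w^2); the inbreeding load
    and derived allele counts double (they are sums across chromosomes).
    """
    if output.projected:
        raise ValueError("output has already been projected")
    t = output.table.copy()
    t["genetic_load"] = 1.0 - (1.0 - t["genetic_load"]) ** 2
    t["inbreeding_load_B"] = 2.0 * t["inbreeding_load_B"]
    t["derived_allele_count"] = 2.0 * t["derived_allele_count"]
    return SimulationOutput(table=t, projected=True, meta=dict(output.meta))


# ---------------------------------------------------------------------------
# top-level simulations
# ---------------------------------------------------------------------------

def _equilibrium_burnin(
    engine: _Engine, N: int, generations: int, compact_every: int = 50
) -> _Population:
    pop = _Population(N)
    for g in range(generations):
        pop = engine.step(pop, N)
        if (g + 1) % compact_every == 0:
            engine.compact([pop])
    return pop


def _measure(
    engine: _Engine, pop: _Population, sample_size: int, rng: np.random.Generator
) -> dict:
    n_s = min(sample_size, pop.n_ind)
    idx = rng.choice(pop.n_ind, size=n_s, replace=False)
    # sample CSR
    lengths = np.diff(pop.off)
    parts = [pop.data[pop.off[2 * i]: pop.off[2 * i + 2]] for i in idx]
    sd = np.concatenate(parts) if parts else np.empty(0, np.int64)
    soff = np.zeros(2 * n_s + 1, dtype=np.int64)
    pos = 0
    for k, i in enumerate(idx):
        l0 = lengths[2 * i]
        l1 = lengths[2 * i + 1]
        soff[2 * k + 1] = pos + l0
        soff[2 * k + 2] = pos + l0 + l1
        pos += l0 + l1
    w = np.empty(n_s)
    _fitness_kernel(sd, soff, n_s, engine.mut_s, engine.mut_h, w)
    counts = np.zeros(max(engine.n_muts, 1), dtype=np.int64)
    _occupancy_kernel(sd, len(sd), counts)
    q = counts / (2.0 * n_s)
    seg = (counts > 0) & (counts < 2 * n_s)
    B = compute_inbreeding_load(
        q[seg], engine.mut_s[: len(q)][seg], engine.mut_h[: len(q)][seg]
    )
    # population-fixed sites live in the fixed registry, not the haplotypes,
    # so their fitness cost enters through fixed_log_w
    load = compute_genetic_load(w, pop.fixed_log_w)
    derived = float(len(sd) / n_s + 2.0 * len(pop.fixed_s))
    return {
        "genetic_load": load,
        "inbreeding_load_B": B,
        "derived_allele_count": derived,
    }


def sample_sfs_counts(
    engine: _Engine, pop: _Population, n_hap: int, rng: np.random.Generator
) -> np.ndarray:
    """Unfolded derived-allele SFS (length n_hap - 1) from sampled haplotypes."""
    total_h = 2 * pop.n_ind
    hap_idx = rng.choice(total_h, size=n_hap, replace=False)
    parts = [pop.data[pop.off[k]: pop.off[k + 1]] for k in hap_idx]
    sd = np.concatenate(parts) if parts else np.empty(0, np.int64)
    counts = np.zeros(max(engine.n_muts, 1), dtype=np.int64)
    _occupancy_kernel(sd, len(sd), counts)
    occ = counts[(counts > 0) & (counts < n_hap)]
    return np.bincount(occ, minlength=n_hap)[1:n_hap].astype(float)


def run_two_pop_simulation(
    genome: GenomeModel,
    demog: TwoPopDemography,
    dfe: DiscreteDFE,
    dmap: DominanceMap,
    n_replicates: int = 25,
    variable_h: bool = False,
    seed: int = 0,
    burnin_factor: float = 10.0,
    sample_size: int = 100,
    compact_every: int = 50,
) -> SimulationOutput:
    """Burn-in, African growth, split, European bottleneck, joint growth.

    Returns a tidy table with one row per replicate x population.  The model
    is given in the inference convention and converted internally.
    """
    model = convert_inference_to_sim(dfe, dmap)
    records = []
    for rep in range(n_replicates):
        rep_seed = seed * 100_003 + rep
        rng = np.random.default_rng(rep_seed)
        engine = _Engine(genome, model, variable_h, rep_seed)
        burn = int(burnin_factor * 2 * demog.N_anc)
        pop = _equilibrium_burnin(engine, demog.N_anc, burn, compact_every)
        # African growth before the split
        for g in range(demog.T_pre_split):
            pop = engine.step(pop, demog.N_afr_growth)
            if (g + 1) % compact_every == 0:
                engine.compact([pop])
        # split: Europeans are founded from the African gene pool
        afr_sizes, eur_sizes = demog.size_schedule()
        afr = pop
        eur = engine.step(pop, int(eur_sizes[0]))
        afr = engine.step(afr, int(afr_sizes[0]))
        for g in range(1, demog.T_split):
            afr = engine.step(afr, int(afr_sizes[g]))
            eur = engine.step(eur, int(eur_sizes[g]))
            if (g + 1) % compact_every == 0:
                engine.compact([afr, eur])
        engine.compact([afr, eur])
        for name, p in (("AF", afr), ("EU", eur)):
            rec = _measure(engine, p, sample_size, rng)
            rec.update(replicate=rep, population=name, seed=rep_seed)
            records.append(rec)
    table = pd.DataFrame.from_records(records)
    return SimulationOutput(
        table=table,
        projected=False,
        meta={
            "variable_h": variable_h,
            "seed": seed,
            "burnin_factor": burnin_factor,
            "genome": genome,
            "demog": demog,
        },
    )


def run_single_pop_simulation(
    genome: GenomeModel,
    N_anc: int,
    epochs: list[tuple[int, int]],
    dfe: DiscreteDFE,
    dmap: DominanceMap,
    n_sample_hap: int,
    seed: int = 0,
    variable_h: bool = False,
    burnin_factor: float = 10.0,
    compact_every: int = 50,
) -> np.ndarray:
    """Single-population run; returns the unfolded sample SFS (derived counts).

    ``epochs`` is a list of (diploid size, generations) applied after
    burn-in at ``N_anc``.
    """
    model = convert_inference_to_sim(dfe, dmap)
    rng = np.random.default_rng(seed)
    engine = _Engine(genome, model, variable_h, seed)
    pop = _equilibrium_burnin(
        engine, N_anc, int(burnin_factor * 2 * N_anc), compact_every
    )
    for N, gens in epochs:
        for g in range(gens):
            pop = engine.step(pop, N)
            if (g + 1) % compact_every == 0:
                engine.compact([pop])
    engine.compact([pop])
    return sample_sfs_counts(engine, pop, n_sample_hap, rng)
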