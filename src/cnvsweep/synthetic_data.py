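"""Synthetic inputs with the statistical structure the analysis assumes.

Provides (a) a discrete-generation Wright-Fisher forward simulator with an
optional additive selective sweep, returning phased haplotype samples;
(b) a two-group scenario with a frequency-differentiated site; (c) true
copy-number profiles emitted as noisy call sets by three pseudo-callers with
distinct error models; (d) toy GFF3 gene models and QTL tables.  Every
generator is fully reproducible from its seed.

Default simulation scale is a desk-size rescaling of a cattle resequencing
study: N = 200 diploids over L = 500 kb, with the mutation rate set so that
equilibrium diversity matches cattle autosomes (theta = 4*N*mu = 1.2e-3 per
bp) and the recombination rate set so that a hard sweep with s = 0.05 leaves
a footprint on the scale of the 50 kb analysis windows (rho = 4e-4 per bp,
footprint half-width ~ s / (r * ln 2Ns) ~ 27 kb).  Samples are 30 diploids
split 14/16 into two phenotype groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .cnv_consensus import SvCall
from .genomic_io import (
    CnvSweepError,
    GeneModel,
    GroupAssignment,
    HaplotypeMatrix,
    QtlRecord,
    write_gff,
    write_qtl_table,
)

logger = logging.getLogger("cnvsweep")

CALLERS = ("longread", "splitread", "readdepth")


@dataclass(frozen=True)
class SimParams:
    """Wright-Fisher forward-simulation parameters."""

    n_diploid: int = 200  # population size N
    chrom_length: int = 500_000  # L, bp
    mu: float = 1.5e-6  # per-bp per-generation mutation rate (theta = 1.2e-3/bp)
    rec: float = 5e-7  # per-bp per-generation recombination rate (rho = 4e-4/bp)
    s: float = 0.0  # additive selection coefficient at the sweep site
    sweep_pos: int | None = None  # 0-based bp; default L // 2
    generations: int | None = None  # neutral burn-in; default 10 N
    n_sample: int = 30  # sampled diploids
    group_sizes: tuple[int, int] = (14, 16)
    seed: int = 0
    fixation_retries: int = 500
    chrom: str = "1"

    def __post_init__(self) -> None:
        if min(self.mu, self.rec) < 0 or self.s < 0:
            raise CnvSweepError("rates and selection coefficient must be >= 0")
        if self.n_sample > self.n_diploid:
            raise CnvSweepError("cannot sample more diploids than the population")

    @property
    def burn_in(self) -> int:
        return self.generations if self.generations is not None else 10 * self.n_diploid

    @property
    def sweep_site(self) -> int:
        return self.sweep_pos if self.sweep_pos is not None else self.chrom_length // 2


# ---------------------------------------------------------------------------
# forward Wright-Fisher core
# ---------------------------------------------------------------------------


class _Population:
    """2N haplotypes over the currently segregating sites (infinite-sites on
    integer positions; colliding mutation positions are re-drawn)."""

    def __init__(self, params: SimParams, rng: np.random.Generator):
        self.p = params
        self.rng = rng
        self.n2 = 2 * params.n_diploid
        self.pop = np.zeros((self.n2, 0), dtype=np.uint8)
        self.positions = np.zeros(0, dtype=np.int64)

    def state(self) -> tuple[np.ndarray, np.ndarray]:
        return self.pop.copy(), self.positions.copy()

    def restore(self, state: tuple[np.ndarray, np.ndarray]) -> None:
        self.pop, self.positions = state[0].copy(), state[1].copy()

    def sweep_col(self) -> int | None:
        idx = np.searchsorted(self.positions, self.p.sweep_site)
        if idx < self.positions.size and self.positions[idx] == self.p.sweep_site:
            return int(idx)
        return None

    def step(self, fitness: np.ndarray | None = None, protect_pos: int | None = None):
        p, rng, n2 = self.p, self.rng, self.n2
        N = p.n_diploid
        if fitness is None:
            parent = rng.integers(N, size=n2)
        else:
            parent = rng.choice(N, size=n2, p=fitness / fitness.sum())
        which = rng.integers(2, size=n2)
        child = self.pop[2 * parent + which]  # fancy indexing copies

        rl = p.rec * p.chrom_length
        if rl > 0 and self.positions.size:
            nx = rng.poisson(rl, size=n2)
            other_rows = 2 * parent + 1 - which
            # single and double crossovers are the overwhelming majority;
            # handle them in batch, rarer multi-crossover children one by one
            one = np.flatnonzero(nx == 1)
            if one.size:
                b = rng.integers(0, p.chrom_length, size=one.size)
                mask = self.positions[None, :] >= b[:, None]
                child[one] = np.where(mask, self.pop[other_rows[one]], child[one])
            two = np.flatnonzero(nx == 2)
            if two.size:
                b = rng.integers(0, p.chrom_length, size=(two.size, 2))
                lo = b.min(axis=1)[:, None]
                hi = b.max(axis=1)[:, None]
                mask = (self.positions[None, :] >= lo) & (self.positions[None, :] < hi)
                child[two] = np.where(mask, self.pop[other_rows[two]], child[two])
            for i in np.flatnonzero(nx >= 3):
                bps = np.sort(rng.integers(0, p.chrom_length, size=nx[i]))
                take_other = (
                    np.searchsorted(bps, self.positions, side="right") % 2 == 1
                )
                child[i] = np.where(take_other, self.pop[other_rows[i]], child[i])

        n_mut = rng.poisson(n2 * p.mu * p.chrom_length)
        if n_mut:
            # draw positions in batch; collisions with existing sites (or the
            # protected sweep site) are re-drawn, keeping infinite sites
            avoid = self.positions
            if protect_pos is not None:
                avoid = np.append(avoid, protect_pos)
            cand = np.empty(0, dtype=np.int64)
            while cand.size < n_mut:
                draw = rng.integers(0, p.chrom_length, size=2 * n_mut + 16)
                cand = np.setdiff1d(draw, avoid)
            new_pos = rng.permutation(cand)[:n_mut]
            cols = np.zeros((n2, n_mut), dtype=np.uint8)
            cols[rng.integers(n2, size=n_mut), np.arange(n_mut)] = 1
            self.pop = np.concatenate([child, cols], axis=1)
            self.positions = np.concatenate([self.positions, np.asarray(new_pos)])
            order = np.argsort(self.positions, kind="stable")
            self.positions = self.positions[order]
            self.pop = self.pop[:, order]
        else:
            self.pop = child

    def prune(self, keep_pos: int | None = None) -> None:
        c = self.pop.sum(axis=0)
        keep = (c > 0) & (c < self.n2)
        if keep_pos is not None:
            keep |= self.positions == keep_pos
        if not keep.all():
            self.pop = self.pop[:, keep]
            self.positions = self.positions[keep]


def _sample_matrix(
    popn: _Population, params: SimParams, rng: np.random.Generator
) -> HaplotypeMatrix:
    ids = np.sort(rng.choice(params.n_diploid, size=params.n_sample, replace=False))
    rows = np.ravel(np.column_stack([2 * ids, 2 * ids + 1]))
    sub = popn.pop[rows]
    c = sub.sum(axis=0)
    seg = (c > 0) & (c < sub.shape[0])
    sample_names = [f"S{i + 1:02d}" for i in range(params.n_sample)]
    return HaplotypeMatrix(
        chrom=params.chrom,
        positions=popn.positions[seg] + 1,  # to 1-based VCF coordinates
        alleles=sub[:, seg],
        sample_ids=[s for s in sample_names for _ in range(2)],
        ancestral_is_ref=np.ones(int(seg.sum()), dtype=bool),
    )


def simulate_population(params: SimParams) -> HaplotypeMatrix:
    """Forward Wright-Fisher simulation, optionally with a hard sweep.

    Runs a neutral burn-in of ``params.burn_in`` generations; with ``s > 0``
    a beneficial allele (additive fitness 1 : 1+s : 1+2s) is then introduced
    on one haplotype at the sweep site and the run is conditioned on its
    fixation, restarting from the saved pre-sweep state on loss (up to
    ``fixation_retries`` attempts).  Returns a phased sample of
    ``n_sample`` diploids restricted to sites segregating in the sample.
    """
    rng = np.random.default_rng(params.seed)
    popn = _Population(params, rng)
    protect = params.sweep_site if params.s > 0 else None
    for _ in range(params.burn_in):
        popn.step(protect_pos=protect)
        popn.prune()

    if params.s > 0:
        base_state = popn.state()
        fixed = False
        for attempt in range(params.fixation_retries):
            popn.restore(base_state)
            # introduce the beneficial allele on one random haplotype
            col = np.zeros((popn.n2, 1), dtype=np.uint8)
            col[rng.integers(popn.n2), 0] = 1
            ins = np.searchsorted(popn.positions, params.sweep_site)
            popn.pop = np.concatenate(
                [popn.pop[:, :ins], col, popn.pop[:, ins:]], axis=1
            )
            popn.positions = np.insert(popn.positions, ins, params.sweep_site)
            while True:
                j = popn.sweep_col()
                if j is None:
                    freq = 0
                else:
                    freq = int(popn.pop[:, j].sum())
                if freq == 0 or freq == popn.n2:
                    break
                g = popn.pop[:, j].reshape(params.n_diploid, 2).sum(axis=1)
                fitness = 1.0 + params.s * g
                popn.step(fitness=fitness, protect_pos=params.sweep_site)
                popn.prune(keep_pos=params.sweep_site)
            if freq == popn.n2:
                fixed = True
                logger.info(
                    "simulate_population: sweep fixed on attempt %d", attempt + 1
                )
                break
        if not fixed:
            raise CnvSweepError(
                f"sweep allele lost in all {params.fixation_retries} attempts"
            )
        popn.prune()  # the fixed sweep column drops out here

    return _sample_matrix(popn, params, rng)


def simulate_two_groups(
    params: SimParams,
    diff_site_freqs: tuple[float, float],
    diff_pos: int | None = None,
    group_labels: tuple[str, str] = ("HSM", "PSM"),
) -> tuple[HaplotypeMatrix, GroupAssignment]:
    """Neutral shared background plus one site with group allele frequencies
    ``(f1, f2)`` (independent Bernoulli draws per haplotype).

    Samples are split into the two phenotype groups by ``params.group_sizes``
    (default 14 / 16).
    """
    f1, f2 = diff_site_freqs
    if not (0 <= f1 <= 1 and 0 <= f2 <= 1):
        raise CnvSweepError("group allele frequencies must lie in [0, 1]")
    n1, n2 = params.group_sizes
    if n1 + n2 != params.n_sample:
        params = replace(params, n_sample=n1 + n2)
    hm = simulate_population(replace(params, s=0.0))
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 7]))

    pos0 = diff_pos if diff_pos is not None else params.chrom_length // 2
    pos1 = pos0 + 1  # 1-based
    while pos1 in hm.positions:
        pos1 += 1

    samples = hm.samples
    assignment = {
        s: (group_labels[0] if i < n1 else group_labels[1])
        for i, s in enumerate(samples)
    }
    groups = GroupAssignment(assignment)

    col = np.zeros(hm.n_hap, dtype=np.uint8)
    for i, s in enumerate(hm.sample_ids):
        f = f1 if assignment[s] == group_labels[0] else f2
        col[i] = 1 if (f >= 1.0 or rng.random() < f) and f > 0 else 0
    ins = int(np.searchsorted(hm.positions, pos1))
    hm = HaplotypeMatrix(
        chrom=hm.chrom,
        positions=np.insert(hm.positions, ins, pos1),
        alleles=np.concatenate(
            [hm.alleles[:, :ins], col[:, None], hm.alleles[:, ins:]], axis=1
        ),
        sample_ids=hm.sample_ids,
        ancestral_is_ref=np.insert(hm.ancestral_is_ref, ins, True),
    )
    return hm, groups


# ---------------------------------------------------------------------------
# copy-number truth and pseudo-callers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CnvTruthRegion:
    chrom: str
    start: int
    end: int
    svtype: str  # DEL / DUP
    copy_numbers: dict[str, int]  # carrier sample -> true integer CN (non-carriers are 2)
    differentiated: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise CnvSweepError("degenerate truth region")
        if any(cn < 0 for cn in self.copy_numbers.values()):
            raise CnvSweepError("true copy numbers must be >= 0")


@dataclass(frozen=True)
class CnvTruth:
    samples: tuple[str, ...]
    regions: tuple[CnvTruthRegion, ...]


def make_cnv_truth(
    samples: Sequence[str],
    groups: GroupAssignment | None = None,
    n_neutral: int = 100,
    chrom_length: int = 120_000_000,
    chrom: str = "2",
    planted_deletion: tuple[int, int] | None = (101_427_467, 101_429_883),
    seed: int = 0,
) -> CnvTruth:
    """Neutral CNV regions plus, optionally, a group-differentiated deletion.

    The planted deletion emulates a fully penetrant fertility-associated
    event: copy number 0 in every sample of the second group and in half of
    the first group, diploid elsewhere.  Neutral regions get 2-8 carrier
    samples chosen independently of group, with integer CN 0/1 (DEL) or
    3/4 (DUP).
    """
    rng = np.random.default_rng(seed)
    regions: list[CnvTruthRegion] = []

    starts = np.sort(rng.choice(chrom_length // 10_000, size=n_neutral, replace=False))
    for i in range(n_neutral):
        start = int(starts[i]) * 10_000 + int(rng.integers(0, 2_000))
        length = int(np.exp(rng.uniform(np.log(100), np.log(5_000))))
        svtype = "DEL" if rng.random() < 0.7 else "DUP"
        k = int(rng.integers(2, 9))
        carriers = rng.choice(len(samples), size=k, replace=False)
        cn_choices = (0, 1) if svtype == "DEL" else (3, 4)
        cns = {
            samples[j]: int(rng.choice(cn_choices, p=[0.3, 0.7]))
            for j in carriers
        }
        regions.append(
            CnvTruthRegion(chrom, start, start + length, svtype, cns, False)
        )

    if planted_deletion is not None:
        if groups is None:
            raise CnvSweepError("planted differentiated deletion requires groups")
        lab1, lab2 = groups.labels
        by_group = groups.groups()
        cns: dict[str, int] = {}
        for s in by_group[lab2]:
            cns[s] = 0
        g1 = by_group[lab1]
        for s in g1[: len(g1) // 2]:
            cns[s] = 0
        start, end = planted_deletion
        regions.append(CnvTruthRegion(chrom, start, end, "DEL", cns, True))

    regions.sort(key=lambda r: (r.chrom, r.start))
    return CnvTruth(samples=tuple(samples), regions=tuple(regions))


def simulate_cnv_callsets(
    truth: CnvTruth,
    callers: Sequence[str] = CALLERS,
    jitter_sd: float = 30.0,
    fp_rate: float = 0.02,
    fn_rate: float = 0.05,
    support_mean: float = 10.0,
    imprecise_frac: float = 0.1,
    cn_noise_sd: float = 0.15,
    chrom_length: int = 120_000_000,
    seed: int = 0,
) -> dict[str, list[SvCall]]:
    """Emit each true event per carrier as noisy per-caller calls.

    Per caller and carrier, an event is emitted with probability 1 - fn_rate,
    with Gaussian breakpoint jitter (sd ``jitter_sd`` bp), Poisson supporting
    reads (mean ``support_mean``), and a fraction flagged IMPRECISE.  Only
    the read-depth caller annotates copy number (true CN plus Gaussian noise,
    floored at 0).  False positives are placed uniformly at rate ``fp_rate``
    per sample per caller.
    """
    if jitter_sd < 0 or not (0 <= fp_rate <= 1 and 0 <= fn_rate <= 1):
        raise CnvSweepError("invalid error-model parameters")
    rng = np.random.default_rng(seed)
    out: dict[str, list[SvCall]] = {c: [] for c in callers}
    for caller in callers:
        annotates_cn = caller == "readdepth"
        for region in truth.regions:
            for sample, cn in sorted(region.copy_numbers.items()):
                if cn == 2:
                    continue
                if rng.random() < fn_rate:
                    continue
                start = region.start + int(round(rng.normal(0, jitter_sd))) if jitter_sd else region.start
                end = region.end + int(round(rng.normal(0, jitter_sd))) if jitter_sd else region.end
                start = max(0, start)
                if end <= start:
                    end = start + 1
                support = int(rng.poisson(support_mean))
                precise = rng.random() >= imprecise_frac if imprecise_frac else True
                cn_val = gt = None
                if annotates_cn:
                    cn_val = max(0.0, cn + float(rng.normal(0, cn_noise_sd))) if cn_noise_sd else float(cn)
                else:
                    # breakpoint callers genotype the event instead
                    gt = "hom" if cn in (0, 4) else "het"
                out[caller].append(
                    SvCall(
                        caller=caller,
                        sample_id=sample,
                        chrom=region.chrom,
                        start=start,
                        end=end,
                        svtype=region.svtype,
                        precise=precise,
                        support_reads=support,
                        copy_number=cn_val,
                        genotype=gt,
                    )
                )
        n_fp = rng.poisson(fp_rate * len(truth.samples))
        for _ in range(n_fp):
            start = int(rng.integers(0, chrom_length - 5_000))
            length = int(np.exp(rng.uniform(np.log(100), np.log(2_000))))
            svtype = "DEL" if rng.random() < 0.5 else "DUP"
            sample = truth.samples[int(rng.integers(len(truth.samples)))]
            out[caller].append(
                SvCall(
                    caller=caller,
                    sample_id=sample,
                    chrom=truth.regions[0].chrom if truth.regions else "2",
                    start=start,
                    end=start + length,
                    svtype=svtype,
                    precise=rng.random() >= imprecise_frac,
                    support_reads=int(rng.poisson(support_mean)),
                    copy_number=None,
                )
            )
    return out


# ---------------------------------------------------------------------------
# toy annotation fixtures
# ---------------------------------------------------------------------------


def make_fixtures(
    n_genes: int,
    n_qtls: int,
    chrom_length: int,
    seed: int = 0,
    chrom: str = "1",
    gff_path: str | Path | None = None,
    qtl_path: str | Path | None = None,
) -> tuple[list[GeneModel], list[QtlRecord]]:
    """Random non-pathological gene models (2-8 exons) and QTL intervals with
    trait classes and P-values; optionally written as GFF3 / TSV."""
    if n_genes < 0 or n_qtls < 0:
        raise CnvSweepError("fixture counts must be >= 0")
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    for i in range(n_genes):
        length = int(rng.integers(2_000, 30_000))
        start = int(rng.integers(0, max(1, chrom_length - length)))
        n_exons = int(rng.integers(2, 9))
        cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_exons, replace=False))
        exons = tuple(
            (start + int(cuts[2 * j]), start + int(cuts[2 * j + 1]))
            for j in range(n_exons)
        )
        genes.append(
            GeneModel(f"gene{i + 1:04d}", chrom, start, start + length, exons)
        )
    trait_pool = ["immunity", "meat", "milk", "production", "reproduction", "health"]
    qtls: list[QtlRecord] = []
    for i in range(n_qtls):
        length = int(rng.integers(5_000, 100_000))
        start = int(rng.integers(0, max(1, chrom_length - length)))
        qtls.append(
            QtlRecord(
                qtl_id=f"qtl{i + 1:04d}",
                chrom=chrom,
                start=start,
                end=start + length,
                trait_class=trait_pool[int(rng.integers(len(trait_pool)))],
                p_value=round(float(rng.uniform(0, 0.05)), 4),
            )
        )
    if gff_path is not None:
        write_gff(genes, gff_path)
    if qtl_path is not None:
        write_qtl_table(qtls, qtl_path)
    return genes, qtls


# ---------------------------------------------------------------------------
# VCF writer for simulated haplotypes
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def write_vcf(hm: HaplotypeMatrix, path: str | Path, chrom_length: int | None = None) -> None:
    """Write a phased VCF 4.2 with AA (ancestral allele) INFO annotations.

    REF is the ancestral allele (deterministically chosen base per position),
    so polarity round-trips through :func:`cnvsweep.genomic_io.read_genotypes`.
    """
    samples = hm.samples
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if chrom_length:
            fh.write(f"##contig=<ID={hm.chrom},length={chrom_length}>\n")
        else:
            fh.write(f"##contig=<ID={hm.chrom}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j in range(hm.n_sites):
            pos = int(hm.positions[j])
            ref = _BASES[pos % 4]
            alt = _BASES[(pos + 1) % 4]
            anc = ref if hm.ancestral_is_ref[j] else alt
            col = hm.alleles[:, j]
            gts = "\t".join(
                f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(len(samples))
            )
            fh.write(
                f"{hm.chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\tAA={anc}\tGT\t{gts}\n"
            )
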