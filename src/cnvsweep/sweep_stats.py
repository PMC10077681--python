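"""SNP-based selection statistics.

Implements the four scan statistics used for sweep detection on phased
haplotype data — windowed nucleotide diversity (pi), Tajima's D,
Weir & Cockerham (1984) F_ST between two groups, and the integrated
haplotype score (iHS) — plus a composite likelihood ratio (CLR) scan that
contrasts a selective-sweep site-frequency model against the empirical
background spectrum.

All statistics run on a :class:`~cnvsweep.genomic_io.HaplotypeMatrix` and are
aggregated over sliding windows into a per-window table.  This module is
fully deterministic: there is no randomness, and ranking ties downstream are
broken by (chrom, start) order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom, hypergeom

from .genomic_io import CnvSweepError, HaplotypeMatrix, Window

logger = logging.getLogger("cnvsweep")

EHH_CUTOFF = 0.05
MAF_MIN = 0.05
IHS_BINS = 50


# ---------------------------------------------------------------------------
# nucleotide diversity and Tajima's D
# ---------------------------------------------------------------------------


def site_heterozygosity(alt_counts: np.ndarray, n_hap: int) -> np.ndarray:
    """Per-site expected heterozygosity 2*c*(n-c) / (n*(n-1)); this is the
    per-site mean number of pairwise differences."""
    c = np.asarray(alt_counts, dtype=np.float64)
    return 2.0 * c * (n_hap - c) / (n_hap * (n_hap - 1))


def window_pi(hm: HaplotypeMatrix, w: Window) -> tuple[float, int]:
    """Nucleotide diversity per bp and segregating-site count in a window.

    pi is the mean pairwise difference count summed over sites in the window,
    divided by the window length in bp.
    """
    if hm.n_hap < 2:
        raise CnvSweepError("window_pi requires at least 2 haplotypes")
    sl = hm.site_slice(w)
    c = hm.alleles[:, sl].sum(axis=0)
    seg = (c > 0) & (c < hm.n_hap)
    pi_sum = float(site_heterozygosity(c, hm.n_hap).sum())
    return pi_sum / w.length, int(seg.sum())


def tajima_constants(n: int) -> dict[str, float]:
    """The canonical constants a1..e2 of Tajima (1989) for n haplotypes."""
    if n < 2:
        raise CnvSweepError("Tajima's D requires n >= 2 haplotypes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(S: int, pi_total: float, n: int) -> tuple[float, bool]:
    """Tajima's D from the segregating-site count and the summed mean pairwise
    differences of a window.

    Returns ``(D, defined)``; with ``S == 0`` the statistic is undefined and
    reported as ``(0.0, False)``.
    """
    k = tajima_constants(n)
    if S < 0:
        raise CnvSweepError("negative segregating-site count")
    if S == 0:
        return 0.0, False
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if var <= 0:
        return 0.0, False
    return (pi_total - S / k["a1"]) / math.sqrt(var), True


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) F_ST, haploid data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FstComponents:
    """WC84 variance components for one site (haploid data: h_bar = 0, c = 0)."""

    a: float
    b: float
    c: float
    p_bar: float
    s2: float
    n_bar: float
    n_c: float
    r: int = 2

    @property
    def theta(self) -> float | None:
        den = self.a + self.b + self.c
        return self.a / den if den != 0 else None


def wc_fst_site(
    counts_pop1: tuple[int, int], counts_pop2: tuple[int, int]
) -> FstComponents | None:
    """WC84 components for one biallelic site from haploid (haplotype-level)
    allele counts ``(n_ref, n_alt)`` per population.

    A site where either population has zero observations is skipped (None).
    With haplotype data the within-individual heterozygosity term vanishes
    (h_bar = 0), so the c component is identically 0.
    """
    n1 = sum(counts_pop1)
    n2 = sum(counts_pop2)
    if n1 == 0 or n2 == 0:
        return None
    r = 2
    p1 = counts_pop1[1] / n1
    p2 = counts_pop2[1] / n2
    n_bar = (n1 + n2) / r
    n_c = (n1 + n2) - (n1**2 + n2**2) / (n1 + n2)  # * 1/(r-1) with r = 2
    p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    if n_bar <= 1:
        return None
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - s2 * (r - 1) / r)
    return FstComponents(a=a, b=b, c=0.0, p_bar=p_bar, s2=s2, n_bar=n_bar, n_c=n_c, r=r)


def wc_fst_components(
    alt1: np.ndarray, n1: int, alt2: np.ndarray, n2: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-site (a, b) components for fixed haploid sample sizes."""
    r = 2
    p1 = np.asarray(alt1, dtype=np.float64) / n1
    p2 = np.asarray(alt2, dtype=np.float64) / n2
    n_bar = (n1 + n2) / r
    n_c = (n1 + n2) - (n1**2 + n2**2) / (n1 + n2)
    p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r) / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - s2 * (r - 1) / r)
    return a, b


def window_fst(components: list[FstComponents | None]) -> float:
    """Ratio-of-sums ("weighted") window F_ST over per-site components.

    Negative values are reported as computed, matching the vcftools
    convention; windows with no usable site return NaN.
    """
    num = den = 0.0
    any_site = False
    for comp in components:
        if comp is None:
            continue
        any_site = True
        num += comp.a
        den += comp.a + comp.b + comp.c
    if not any_site or den == 0.0:
        return float("nan")
    return num / den


# ---------------------------------------------------------------------------
# EHH and iHS
# ---------------------------------------------------------------------------


@dataclass
class IhsRecord:
    """Per-site integrated haplotype score."""

    site: int
    position: int
    derived_freq: float
    ihh_a: float
    ihh_d: float
    ihs_raw: float
    ihs_std: float | None = None
    ok: bool = True  # False when EHH hit a chromosome end before the cutoff


def ehh(
    hm: HaplotypeMatrix,
    core_site: int,
    core_allele: int,
    direction: int,
    cutoff: float = EHH_CUTOFF,
    alleles: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Extended haplotype homozygosity from a core site outward.

    At each successive site, EHH is the probability that two random carriers
    of ``core_allele`` are identical over the stretch from the core to that
    site: ``sum_h C(count_h, 2) / C(n_core, 2)`` over distinct extended
    haplotypes h.  Extension stops once EHH drops below ``cutoff`` (the
    sub-cutoff value is included in the output) or at the chromosome end.

    Returns ``(positions, ehh_values, reached_cutoff)``; the first entry is
    the core site itself with EHH exactly 1.
    """
    if direction not in (1, -1):
        raise CnvSweepError("direction must be +1 (right) or -1 (left)")
    A = hm.alleles if alleles is None else alleles
    carriers = np.flatnonzero(A[:, core_site] == core_allele)
    if carriers.size < 2:
        raise CnvSweepError("EHH undefined: fewer than 2 core-allele carriers")
    n_pairs = carriers.size * (carriers.size - 1) // 2
    labels = np.zeros(carriers.size, dtype=np.int64)
    positions = [int(hm.positions[core_site])]
    values = [1.0]
    reached = False
    j = core_site + direction
    while 0 <= j < hm.n_sites:
        key = labels * 2 + A[carriers, j]
        _, labels = np.unique(key, return_inverse=True)
        counts = np.bincount(labels)
        e = float((counts * (counts - 1) // 2).sum() / n_pairs)
        positions.append(int(hm.positions[j]))
        values.append(e)
        if e < cutoff:
            reached = True
            break
        j += direction
    return np.asarray(positions), np.asarray(values), reached


def _ihh_one_side(hm, core_site, allele, direction, cutoff, alleles) -> tuple[float, bool]:
    pos, vals, reached = ehh(hm, core_site, allele, direction, cutoff, alleles)
    d = np.abs(pos - pos[0]).astype(np.float64)
    return float(np.trapezoid(vals, d)), reached


def ihs(
    hm: HaplotypeMatrix,
    site: int,
    maf: float = MAF_MIN,
    cutoff: float = EHH_CUTOFF,
    derived: np.ndarray | None = None,
) -> IhsRecord | None:
    """Unstandardized iHS at one site: ``ln(iHH_A / iHH_D)`` with iHH the
    trapezoidal integral of EHH against physical distance, summed over both
    directions, for the ancestral (A) and derived (D) core alleles.

    Sites with minor derived frequency below ``maf`` return None.  Sites
    where EHH never reaches the cutoff before a chromosome end are flagged
    ``ok=False`` (dropped by default in the scan).
    """
    D = hm.derived() if derived is None else derived
    n = hm.n_hap
    cnt = int(D[:, site].sum())
    freq = cnt / n
    if min(freq, 1.0 - freq) < maf:
        return None
    ok = True
    ihh = {}
    for allele in (0, 1):
        total = 0.0
        for direction in (-1, 1):
            val, reached = _ihh_one_side(hm, site, allele, direction, cutoff, D)
            total += val
            ok = ok and reached
        ihh[allele] = total
    if ihh[0] <= 0 or ihh[1] <= 0:
        return IhsRecord(site, int(hm.positions[site]), freq, ihh[0], ihh[1],
                         float("nan"), ok=False)
    return IhsRecord(
        site=site,
        position=int(hm.positions[site]),
        derived_freq=freq,
        ihh_a=ihh[0],
        ihh_d=ihh[1],
        ihs_raw=math.log(ihh[0] / ihh[1]),
        ok=ok,
    )


def standardize_ihs(records: list[IhsRecord], n_bins: int = IHS_BINS) -> list[IhsRecord]:
    """Standardize raw iHS within equal-width derived-allele-frequency bins
    over [0, 1]: ``ihs_std = (ihs_raw - bin mean) / bin sd``.

    Bins with fewer than 2 records or zero spread yield flagged missing
    scores (``ihs_std`` stays None).
    """
    if not records:
        return records
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    freqs = np.array([r.derived_freq for r in records])
    raw = np.array([r.ihs_raw for r in records])
    bins = np.clip(np.digitize(freqs, edges) - 1, 0, n_bins - 1)
    for b in np.unique(bins):
        idx = np.flatnonzero(bins == b)
        vals = raw[idx]
        usable = idx[np.isfinite(vals)]
        vals = raw[usable]
        if usable.size < 2:
            continue
        mu = vals.mean()
        sd = vals.std(ddof=0)
        if sd == 0:
            continue
        for i in usable:
            records[i].ihs_std = float((raw[i] - mu) / sd)
    return records


# ---------------------------------------------------------------------------
# CLR sweep scan
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SfsBackground:
    """Empirical background site-frequency spectrum for n haplotypes.

    ``probs[i]`` is the probability of derived count i; only the polymorphic
    classes 1..n-1 carry mass (invariant and fixed classes are excluded).
    """

    n: int
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=np.float64)
        if p.size != self.n + 1:
            raise CnvSweepError("SFS vector must have length n + 1")
        if not math.isclose(float(p.sum()), 1.0, rel_tol=0, abs_tol=1e-9):
            raise CnvSweepError("SFS probabilities must sum to 1")
        object.__setattr__(self, "probs", p)


@dataclass(frozen=True)
class SweepModelFit:
    """CLR model fit at one grid position."""

    grid_pos: int
    alpha: float
    clr: float
    loglik_sweep: float
    loglik_bg: float


def background_sfs(hm: HaplotypeMatrix) -> SfsBackground:
    """Empirical spectrum of derived counts over segregating sites."""
    cnt = hm.derived_counts()
    seg = cnt[(cnt > 0) & (cnt < hm.n_hap)]
    if seg.size == 0:
        raise CnvSweepError("background_sfs: no segregating sites")
    probs = np.bincount(seg, minlength=hm.n_hap + 1).astype(np.float64)
    return SfsBackground(n=hm.n_hap, probs=probs / probs.sum())


def escape_kernel(bg: SfsBackground) -> np.ndarray:
    """Q[k, j] = P(observed derived count j | k of n lineages escape the sweep).

    Conditional on k escapees, the pre-sweep sub-sample of size k+1 (the k
    escapees plus one lineage standing for the entire swept class) has its
    derived count drawn by hypergeometric downsampling of the background
    spectrum; the swept-class lineage then contributes its allele as n - k
    copies.  Row k = n (everything escapes) reproduces the background exactly.
    """
    n = bg.n
    Q = np.zeros((n + 1, n + 1))
    i_arr = np.arange(n + 1)
    for k in range(n):
        m = k + 1
        # downsample n -> m: P_m(c) = sum_i bg(i) * Hypergeom(c; n, i, m)
        c_arr = np.arange(m + 1)
        H = hypergeom.pmf(c_arr[:, None], n, i_arr[None, :], m)  # (m+1, n+1)
        P_m = H @ bg.probs
        for c in range(m + 1):
            if P_m[c] == 0:
                continue
            # the representative of the swept class is one random lineage of m
            p_rep_derived = c / m
            j_if_derived = (c - 1) + (n - k)
            if 0 <= j_if_derived <= n:
                Q[k, j_if_derived] += P_m[c] * p_rep_derived
            if 0 <= c <= n:
                Q[k, c] += P_m[c] * (1.0 - p_rep_derived)
    Q[n, :] = bg.probs
    return Q


def default_alpha_grid(n_points: int = 40) -> np.ndarray:
    """Geometric grid of sweep-intensity values (1/bp) spanning a near
    fully-swept regime at 1e-7 (escape unlikely within ~1 Mb) to near
    background at 1e-2 (escape certain beyond ~1 kb), plus the exact
    background limit (alpha = inf, escape probability 1 everywhere)."""
    return np.append(np.geomspace(1e-7, 1e-2, n_points), np.inf)


def clr_at(
    grid_pos: int,
    alpha: float,
    positions: np.ndarray,
    derived_counts: np.ndarray,
    bg: SfsBackground,
    Q: np.ndarray | None = None,
) -> SweepModelFit:
    """Composite likelihood of the sweep model at one grid position and one
    sweep intensity alpha.

    Each lineage escapes the sweep independently with p_e = 1 - exp(-alpha*d)
    at distance d from the grid position; the per-site sweep likelihood mixes
    the escape kernel over Binomial(n, p_e) escapee counts and is conditioned
    on polymorphism (observed sites are polymorphic).  The CLR is
    2*(log L_sweep - log L_background); maximization over the alpha grid is
    done by :func:`clr_max`.
    """
    n = bg.n
    if Q is None:
        Q = escape_kernel(bg)
    positions = np.asarray(positions, dtype=np.float64)
    counts = np.asarray(derived_counts, dtype=np.int64)
    d = np.abs(positions - grid_pos)
    if np.isinf(alpha):
        p_e = np.ones_like(d)
    else:
        p_e = -np.expm1(-alpha * d)
    k_arr = np.arange(n + 1)
    W = binom.pmf(k_arr[None, :], n, p_e[:, None])  # (n_sites, n+1)
    p_obs = np.einsum("sk,ks->s", W, Q[:, counts])
    z_poly = W @ Q[:, 1:n].sum(axis=1)  # normalizer over polymorphic classes
    with np.errstate(divide="ignore", invalid="ignore"):
        ll_sweep = float(np.sum(np.log(p_obs) - np.log(z_poly)))
    ll_bg = float(np.sum(np.log(bg.probs[counts])))
    return SweepModelFit(
        grid_pos=int(grid_pos),
        alpha=float(alpha),
        clr=2.0 * (ll_sweep - ll_bg),
        loglik_sweep=ll_sweep,
        loglik_bg=ll_bg,
    )


def clr_max(
    grid_pos: int,
    positions: np.ndarray,
    derived_counts: np.ndarray,
    bg: SfsBackground,
    alphas: np.ndarray | None = None,
    Q: np.ndarray | None = None,
) -> SweepModelFit:
    """Maximize the CLR over the alpha grid at one grid position.

    The grid contains the exact background limit, so the maximized CLR is
    >= 0 up to round-off; it is clipped at 0.
    """
    if alphas is None:
        alphas = default_alpha_grid()
    if Q is None:
        Q = escape_kernel(bg)
    best: SweepModelFit | None = None
    for alpha in alphas:
        fit = clr_at(grid_pos, alpha, positions, derived_counts, bg, Q=Q)
        if not math.isfinite(fit.clr):
            continue
        if best is None or fit.clr > best.clr:
            best = fit
    if best is None or best.clr < 0:
        return SweepModelFit(int(grid_pos), math.inf, 0.0,
                             best.loglik_bg if best else 0.0,
                             best.loglik_bg if best else 0.0)
    return best


def clr_scan(
    hm: HaplotypeMatrix,
    chrom_length: int,
    grid_spacing: int = 50_000,
    alphas: np.ndarray | None = None,
) -> pd.DataFrame:
    """CLR at one grid point per ``grid_spacing`` bp (tile centers), using the
    chromosome-wide empirical SFS as background and all segregating sites."""
    bg = background_sfs(hm)
    Q = escape_kernel(bg)
    cnt = hm.derived_counts()
    seg = (cnt > 0) & (cnt < hm.n_hap)
    positions = hm.positions[seg] - 1  # 0-based for distance/grid arithmetic
    counts = cnt[seg]
    grid = np.arange(0, chrom_length, grid_spacing)
    rows = []
    for g in grid:
        fit = clr_max(int(g), positions, counts, bg, alphas=alphas, Q=Q)
        rows.append((hm.chrom, int(g), fit.clr, fit.alpha))
    return pd.DataFrame(rows, columns=["chrom", "grid_pos", "clr", "alpha"])


# ---------------------------------------------------------------------------
# windowed scan
# ---------------------------------------------------------------------------


def ihs_scan(
    hm: HaplotypeMatrix,
    maf: float = MAF_MIN,
    cutoff: float = EHH_CUTOFF,
    n_bins: int = IHS_BINS,
    drop_edge_flagged: bool = True,
) -> list[IhsRecord]:
    """iHS at every eligible site, standardized within frequency bins."""
    D = hm.derived()
    records = []
    for site in range(hm.n_sites):
        cnt = int(D[:, site].sum())
        if cnt < 2 or hm.n_hap - cnt < 2:
            continue
        rec = ihs(hm, site, maf=maf, cutoff=cutoff, derived=D)
        if rec is None:
            continue
        if drop_edge_flagged and not rec.ok:
            continue
        records.append(rec)
    return standardize_ihs(records, n_bins=n_bins)


def sweep_scan(
    hm: HaplotypeMatrix,
    windows: list[Window],
    methods: tuple[str, ...] = ("pi", "tajima_d"),
    groups=None,
    chrom_length: int | None = None,
    grid_spacing: int = 50_000,
    ihs_records: list[IhsRecord] | None = None,
) -> pd.DataFrame:
    """Per-window table of the requested statistics.

    ``methods`` may contain "pi", "tajima_d", "fst" (requires ``groups``),
    "clr" (requires ``chrom_length``) and "ihs".  Component failures in a
    window become missing values; the scan never aborts.
    """
    kc = tajima_constants(hm.n_hap)
    alt = hm.alleles.sum(axis=0)
    n = hm.n_hap
    het = site_heterozygosity(alt, n)
    seg = (alt > 0) & (alt < n)

    fst_a = fst_ab = None
    if "fst" in methods:
        if groups is None:
            raise CnvSweepError("fst scan requires a group assignment")
        groups.check_samples(hm.samples)
        by_group = groups.groups()
        lab1, lab2 = groups.labels
        rows1 = hm.rows_of(by_group[lab1])
        rows2 = hm.rows_of(by_group[lab2])
        a, b = wc_fst_components(
            hm.alleles[rows1].sum(axis=0), len(rows1),
            hm.alleles[rows2].sum(axis=0), len(rows2),
        )
        fst_a, fst_ab = a, a + b

    clr_table = None
    if "clr" in methods:
        if chrom_length is None:
            raise CnvSweepError("clr scan requires chrom_length")
        clr_table = clr_scan(hm, chrom_length, grid_spacing=grid_spacing)

    if "ihs" in methods and ihs_records is None:
        ihs_records = ihs_scan(hm)
    ihs_pos = ihs_std = None
    if ihs_records is not None:
        kept = [r for r in ihs_records if r.ihs_std is not None]
        ihs_pos = np.array([r.position for r in kept], dtype=np.int64)
        ihs_std = np.array([abs(r.ihs_std) for r in kept])

    rows = []
    for w in windows:
        sl = hm.site_slice(w)
        row: dict = {
            "chrom": w.chrom,
            "start": w.start,
            "end": w.end,
            "n_sites": int(seg[sl].sum()),
        }
        if "pi" in methods:
            row["pi"] = float(het[sl].sum()) / w.length
        if "tajima_d" in methods:
            d, defined = tajimas_d(int(seg[sl].sum()), float(het[sl].sum()), n)
            row["tajima_d"] = d if defined else float("nan")
        if fst_a is not None:
            num = float(fst_a[sl][seg[sl]].sum())
            den = float(fst_ab[sl][seg[sl]].sum())
            row["fst_num"] = num
            row["fst_den"] = den
            row["fst"] = num / den if den != 0 and seg[sl].any() else float("nan")
        if clr_table is not None:
            in_w = clr_table[
                (clr_table["grid_pos"] >= w.start) & (clr_table["grid_pos"] < w.end)
            ]
            row["clr"] = float(in_w["clr"].max()) if len(in_w) else float("nan")
        if ihs_pos is not None:
            m = (ihs_pos - 1 >= w.start) & (ihs_pos - 1 < w.end)
            row["mean_abs_ihs"] = float(ihs_std[m].mean()) if m.any() else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
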