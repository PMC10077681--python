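"""Multi-caller CNV consensus and CNVR construction.

The chain mirrors a conservative short+long-read CNV discovery workflow:

1. per-caller structural-variant calls are filtered (precise breakpoints,
   length >= 50 bp, >= 4 supporting reads, caller quality pass);
2. per-sample loci reported by at least two callers with the same type (and
   a direction-consistent read-depth copy number, when annotated) become
   consensus calls on the intersection interval;
3. consensus calls are merged across samples into copy-number-variable
   regions (CNVRs); only regions supported by at least two animals are kept;
4. CNVRs are typed (deletion / duplication / both) and placed in genomic
   context (exonic / intronic / intergenic).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genomic_io import CnvSweepError, GeneModel

logger = logging.getLogger("cnvsweep")

MIN_SV_LENGTH = 50
MIN_SUPPORT_READS = 4
MIN_ANIMALS = 2
CN_NEUTRAL_BAND = (1.75, 2.25)

SV_TSV_COLUMNS = [
    "sample_id", "chrom", "start", "end", "svtype",
    "precise", "support_reads", "copy_number", "genotype",
]


@dataclass(frozen=True)
class SvCall:
    """One caller's per-sample structural-variant call (0-based half-open)."""

    caller: str
    sample_id: str
    chrom: str
    start: int
    end: int
    svtype: str  # DEL / DUP (others carried but ignored downstream)
    precise: bool = True
    support_reads: int = 0
    quality_pass: bool = True
    copy_number: float | None = None  # diploid baseline 2
    genotype: str | None = None  # "hom" / "het" when the caller genotypes

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise CnvSweepError(
                f"SV call with end <= start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.support_reads < 0:
            raise CnvSweepError("negative supporting-read count")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Cnvr:
    """A cross-sample merged copy-number-variable region."""

    cnvr_id: str
    chrom: str
    start: int
    end: int
    cnvr_type: str  # deletion / duplication / both
    n_samples: int
    member_calls: list[SvCall] = field(default_factory=list)
    context: str | None = None  # exonic / intronic / intergenic

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# call-set readers
# ---------------------------------------------------------------------------


def read_sv_tsv(path: str | Path, caller: str) -> list[SvCall]:
    """Read one caller's call set from a headered TSV.

    Columns: sample_id, chrom, start, end (0-based half-open), svtype,
    precise (0/1), support_reads, copy_number ("NA" when unannotated),
    genotype (hom/het, "NA" when the caller does not genotype).
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in SV_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise CnvSweepError(f"{path}: SV table missing columns {missing}")
    calls = []
    for row in df.itertuples(index=False):
        cn = None if pd.isna(row.copy_number) else float(row.copy_number)
        gt = None if pd.isna(row.genotype) else str(row.genotype)
        calls.append(
            SvCall(
                caller=caller,
                sample_id=str(row.sample_id),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                svtype=str(row.svtype),
                precise=bool(int(row.precise)),
                support_reads=int(row.support_reads),
                copy_number=cn,
                genotype=gt,
            )
        )
    return calls


def write_sv_tsv(calls: Sequence[SvCall], path: str | Path) -> None:
    rows = [
        (
            c.sample_id, c.chrom, c.start, c.end, c.svtype,
            int(c.precise), c.support_reads,
            "NA" if c.copy_number is None else f"{c.copy_number:.4g}",
            "NA" if c.genotype is None else c.genotype,
        )
        for c in calls
    ]
    pd.DataFrame(rows, columns=SV_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sv_vcf(path: str | Path, caller: str) -> list[SvCall]:
    """Read an SV VCF (SVTYPE/END/IMPRECISE and RE or SUPPORT INFO keys read
    when present; per-sample CN FORMAT read when present)."""
    import cyvcf2

    vcf = cyvcf2.VCF(str(path))
    samples = list(vcf.samples)
    calls = []
    for v in vcf:
        svtype = v.INFO.get("SVTYPE")
        if svtype is None:
            continue
        end = v.INFO.get("END")
        if end is None:
            continue
        precise = v.INFO.get("IMPRECISE") is None
        support = v.INFO.get("RE") or v.INFO.get("SUPPORT") or 0
        quality_pass = v.FILTER is None or v.FILTER == "PASS"
        start0 = v.POS - 1
        if int(end) <= start0:
            logger.warning("read_sv_vcf: rejected record with end <= start at %s:%s",
                           v.CHROM, v.POS)
            continue
        cn_arr = None
        try:
            cn_arr = v.format("CN")
        except KeyError:
            cn_arr = None
        for i, sample in enumerate(samples or ["sample0"]):
            cn = None
            if cn_arr is not None:
                val = float(cn_arr[i][0])
                cn = None if np.isnan(val) else val
            calls.append(
                SvCall(
                    caller=caller,
                    sample_id=sample,
                    chrom=v.CHROM,
                    start=start0,
                    end=int(end),
                    svtype=str(svtype),
                    precise=precise,
                    support_reads=int(support),
                    quality_pass=quality_pass,
                    copy_number=cn,
                )
            )
    return calls


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def filter_sv_calls(
    calls: Iterable[SvCall],
    min_len: int = MIN_SV_LENGTH,
    min_support: int = MIN_SUPPORT_READS,
    drop_quality_fail: bool = True,
) -> tuple[list[SvCall], dict[str, int]]:
    """Apply the three SV filters: drop IMPRECISE breakpoints (and caller
    quality failures), drop calls shorter than ``min_len``, drop calls with
    fewer than ``min_support`` reads.  Thresholds are inclusive: a precise
    50 bp call with 4 reads survives.

    Returns the retained calls and a rejection-reason tally.
    """
    kept = []
    reasons = {"imprecise": 0, "low_quality": 0, "too_short": 0, "low_support": 0}
    for c in calls:
        if not c.precise:
            reasons["imprecise"] += 1
        elif drop_quality_fail and not c.quality_pass:
            reasons["low_quality"] += 1
        elif c.length < min_len:
            reasons["too_short"] += 1
        elif c.support_reads < min_support:
            reasons["low_support"] += 1
        else:
            kept.append(c)
    n_rejected = sum(reasons.values())
    if n_rejected:
        logger.info("filter_sv_calls: rejected %d calls (%s)", n_rejected, reasons)
    return kept, reasons


# ---------------------------------------------------------------------------
# per-sample cross-caller consensus
# ---------------------------------------------------------------------------


def _cluster_transitive(calls: list[SvCall]) -> list[list[SvCall]]:
    """Transitively merge >= 1 bp-overlapping calls (same chrom assumed)."""
    calls = sorted(calls, key=lambda c: (c.start, c.end))
    clusters: list[list[SvCall]] = []
    cur: list[SvCall] = []
    cur_end = -1
    for c in calls:
        if cur and c.start < cur_end:
            cur.append(c)
            cur_end = max(cur_end, c.end)
        else:
            if cur:
                clusters.append(cur)
            cur = [c]
            cur_end = c.end
    if cur:
        clusters.append(cur)
    return clusters


def _cn_direction_ok(svtype: str, cns: list[float],
                     band: tuple[float, float]) -> bool:
    lo, hi = band
    for cn in cns:
        if lo <= cn <= hi:
            return False  # copy-number neutral: no depth evidence
        if svtype == "DEL" and cn > lo:
            return False
        if svtype == "DUP" and cn < hi:
            return False
    return True


def consensus_calls(
    calls: Iterable[SvCall],
    min_callers: int = 2,
    cn_neutral_band: tuple[float, float] = CN_NEUTRAL_BAND,
) -> list[SvCall]:
    """Per-sample cross-caller consensus.

    A per-sample locus is retained when at least ``min_callers`` distinct
    callers report overlapping calls of identical svtype and every
    copy-number annotation present agrees in direction (CN below the neutral
    band for DEL, above it for DUP).  The retained call takes the
    intersection interval of the agreeing calls; its copy number is the mean
    of the member annotations.
    """
    by_key: dict[tuple[str, str, str], list[SvCall]] = defaultdict(list)
    for c in calls:
        if c.svtype not in ("DEL", "DUP"):
            continue
        by_key[(c.sample_id, c.chrom, c.svtype)].append(c)

    out: list[SvCall] = []
    for (sample, chrom, svtype), group in sorted(by_key.items()):
        for cluster in _cluster_transitive(group):
            callers = {c.caller for c in cluster}
            if len(callers) < min_callers:
                continue
            start = max(c.start for c in cluster)
            end = min(c.end for c in cluster)
            if end <= start:
                continue  # transitive chain with empty common core
            cns = [c.copy_number for c in cluster if c.copy_number is not None]
            if cns and not _cn_direction_ok(svtype, cns, cn_neutral_band):
                continue
            gts = [c.genotype for c in cluster if c.genotype is not None]
            out.append(
                SvCall(
                    caller="consensus:" + "+".join(sorted(callers)),
                    sample_id=sample,
                    chrom=chrom,
                    start=start,
                    end=end,
                    svtype=svtype,
                    precise=True,
                    support_reads=max(c.support_reads for c in cluster),
                    copy_number=float(np.mean(cns)) if cns else None,
                    genotype=max(gts, key=gts.count) if gts else None,
                )
            )
    out.sort(key=lambda c: (c.chrom, c.start, c.end, c.sample_id, c.svtype))
    return out


# ---------------------------------------------------------------------------
# CNVR construction
# ---------------------------------------------------------------------------


def build_cnvrs(calls: Iterable[SvCall], min_animals: int = MIN_ANIMALS) -> list[Cnvr]:
    """Merge consensus calls (any svtype) across samples into CNVRs.

    Per chromosome, transitively >= 1 bp-overlapping calls merge into one
    region spanning the union of member intervals; regions supported by
    fewer than ``min_animals`` distinct samples are discarded.  Output is
    sorted and pairwise disjoint per chromosome.
    """
    by_chrom: dict[str, list[SvCall]] = defaultdict(list)
    for c in calls:
        by_chrom[c.chrom].append(c)

    cnvrs: list[Cnvr] = []
    for chrom in sorted(by_chrom):
        for cluster in _cluster_transitive(by_chrom[chrom]):
            samples = {c.sample_id for c in cluster}
            if len(samples) < min_animals:
                continue
            cnvrs.append(
                Cnvr(
                    cnvr_id="",
                    chrom=chrom,
                    start=min(c.start for c in cluster),
                    end=max(c.end for c in cluster),
                    cnvr_type=classify_cnvr_members(cluster),
                    n_samples=len(samples),
                    member_calls=list(cluster),
                )
            )
    cnvrs.sort(key=lambda r: (r.chrom, r.start))
    for i, r in enumerate(cnvrs, 1):
        r.cnvr_id = f"cnvr_{i:05d}"
    return cnvrs


def classify_cnvr_members(members: Sequence[SvCall]) -> str:
    """deletion if all members are DEL, duplication if all DUP, both when at
    least one of each is present."""
    types = {c.svtype for c in members}
    if not types:
        raise CnvSweepError("classify_cnvr: no member calls")
    if not types <= {"DEL", "DUP"}:
        raise CnvSweepError(f"classify_cnvr: unexpected member types {types}")
    if types == {"DEL"}:
        return "deletion"
    if types == {"DUP"}:
        return "duplication"
    return "both"


def classify_cnvr(cnvr: Cnvr) -> str:
    return classify_cnvr_members(cnvr.member_calls)


# ---------------------------------------------------------------------------
# genomic-context annotation
# ---------------------------------------------------------------------------


def annotate_cnvr(cnvrs: Sequence[Cnvr], genes: Sequence[GeneModel]) -> list[Cnvr]:
    """Set the genomic context of each CNVR with precedence
    exon > intron > intergenic (>= 1 bp overlap)."""
    exon_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    gene_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        gene_trees[g.chrom].addi(g.start, g.end, g.gene_id)
        for s, e in g.exons:
            exon_trees[g.chrom].addi(s, e, g.gene_id)
    for r in cnvrs:
        if exon_trees[r.chrom].overlap(r.start, r.end):
            r.context = "exonic"
        elif gene_trees[r.chrom].overlap(r.start, r.end):
            r.context = "intronic"
        else:
            r.context = "intergenic"
    return list(cnvrs)


# ---------------------------------------------------------------------------
# length histogram
# ---------------------------------------------------------------------------

DEFAULT_LENGTH_BINS = [0, 100, 500, 1_000, 5_000, 10_000, 50_000]


def length_histogram(
    cnvrs: Sequence[Cnvr], bin_edges: Sequence[int] = DEFAULT_LENGTH_BINS
) -> pd.DataFrame:
    """Counts and fractions of CNVR lengths per bin ``[edge_i, edge_{i+1})``,
    with a final overflow bin for lengths beyond the last edge."""
    edges = list(bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise CnvSweepError("bin edges must be ascending")
    lengths = np.array([r.length for r in cnvrs], dtype=np.int64)
    full_edges = edges + [np.inf]
    counts, _ = np.histogram(lengths, bins=full_edges)
    labels = [
        f"{lo}-{hi}" if np.isfinite(hi) else f">{lo}"
        for lo, hi in zip(full_edges[:-1], full_edges[1:])
    ]
    total = counts.sum()
    fractions = counts / total if total else np.zeros_like(counts, dtype=float)
    return pd.DataFrame({"bin": labels, "count": counts, "fraction": fractions})


def write_cnvr_bed(cnvrs: Sequence[Cnvr], path: str | Path) -> None:
    from .genomic_io import write_bed

    write_bed(
        (
            (r.chrom, r.start, r.end, r.cnvr_id, r.cnvr_type, r.n_samples,
             r.context or "NA")
            for r in cnvrs
        ),
        path,
    )
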