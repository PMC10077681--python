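"""Group-differentiation scans and result integration.

V_ST — an F_ST-analogous statistic for copy number — is computed per CNVR as
``(V_T - V_S) / V_T`` where V_T is the variance of normalized copy number
across all individuals and V_S the size-weighted mean within-group variance.
Outlier scans apply the empirical-percentile rules used for two-group
contrasts: top 2% of V_ST for CNVRs, top 1% of F_ST for SNP windows;
positively selected genes (PSGs) are genes supported by the top windows of
at least two scan statistics.  Gene and QTL overlaps follow the
bedtools-intersect contract (every >= 1 bp overlapping pair is emitted with
both records).
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .cnv_consensus import Cnvr, SvCall
from .genomic_io import CnvSweepError, GeneModel, GroupAssignment, QtlRecord

logger = logging.getLogger("cnvsweep")

VST_TOP_FRACTION = 0.02
FST_TOP_FRACTION = 0.01
PSG_MIN_METHODS = 2


# ---------------------------------------------------------------------------
# copy-number matrix
# ---------------------------------------------------------------------------


@dataclass
class CopyNumberMatrix:
    """CNVRs x samples matrix of normalized copy numbers (diploid baseline 2).

    Samples without a call at a CNVR are imputed at 2 (absence of a call is
    evidence of the reference state in this pipeline), so the matrix has no
    missing entries.
    """

    values: pd.DataFrame  # index: cnvr_id, columns: sample_id
    cnvrs: list[Cnvr]

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise CnvSweepError("copy-number matrix has missing entries")
        if (self.values.values < 0).any():
            raise CnvSweepError("copy numbers must be >= 0")


def _call_copy_number(call: SvCall) -> float:
    if call.copy_number is not None:
        return max(0.0, call.copy_number)
    # no read-depth annotation: infer from the caller genotype when present
    # (homozygous DEL -> 0, het DEL -> 1, hom DUP -> 4, het DUP -> 3)
    if call.svtype == "DEL":
        return 0.0 if call.genotype == "hom" else 1.0
    return 4.0 if call.genotype == "hom" else 3.0


def copy_number_matrix(
    cnvrs: Sequence[Cnvr],
    samples: Sequence[str],
    groups: GroupAssignment | None = None,
) -> CopyNumberMatrix:
    """Per-CNVR, per-sample normalized copy numbers from the member calls.

    The entry is the caller copy-number annotation when present, else 1 for a
    DEL call without CN and 3 for a DUP call without CN, else the diploid 2.
    Multiple member calls of one sample at a CNVR average.
    """
    if groups is not None:
        groups.check_samples(samples)
    mat = pd.DataFrame(2.0, index=[r.cnvr_id for r in cnvrs], columns=list(samples))
    for r in cnvrs:
        per_sample: dict[str, list[float]] = defaultdict(list)
        for call in r.member_calls:
            if call.sample_id not in mat.columns:
                raise CnvSweepError(
                    f"sample {call.sample_id!r} in calls but not in sample list"
                )
            per_sample[call.sample_id].append(_call_copy_number(call))
        for sample, vals in per_sample.items():
            mat.loc[r.cnvr_id, sample] = float(np.mean(vals))
    return CopyNumberMatrix(values=mat, cnvrs=list(cnvrs))


# ---------------------------------------------------------------------------
# V_ST
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VstRecord:
    cnvr_id: str
    v_t: float
    v_s: float
    vst: float | None  # None when v_t == 0 (undefined)
    group_sizes: tuple[int, int]


def vst(
    values: Mapping[str, float],
    groups: GroupAssignment,
    ddof: int = 0,
    cnvr_id: str = "",
) -> VstRecord:
    """V_ST = (V_T - V_S) / V_T for one CNVR.

    V_T is the variance of copy number over all individuals; V_S the mean
    within-group variance weighted by group size.  Variances use the
    population denominator (``ddof=0``) by default.  ``vst`` is None when
    V_T = 0 (no copy-number variation).
    """
    by_group = groups.groups()
    lab1, lab2 = groups.labels
    g1 = [values[s] for s in by_group[lab1] if s in values]
    g2 = [values[s] for s in by_group[lab2] if s in values]
    if not g1 or not g2:
        raise CnvSweepError("vst requires both groups non-empty")
    allv = np.array(g1 + g2, dtype=np.float64)
    v_t = float(allv.var(ddof=ddof))
    n1, n2 = len(g1), len(g2)
    v_s = (n1 * np.array(g1).var(ddof=ddof) + n2 * np.array(g2).var(ddof=ddof)) / (
        n1 + n2
    )
    v = None if v_t == 0 else (v_t - float(v_s)) / v_t
    return VstRecord(cnvr_id=cnvr_id, v_t=v_t, v_s=float(v_s), vst=v,
                     group_sizes=(n1, n2))


def vst_table(
    cnm: CopyNumberMatrix, groups: GroupAssignment, ddof: int = 0
) -> pd.DataFrame:
    """Per-CNVR V_ST table (chrom, start, end, v_t, v_s, vst, group sizes)."""
    by_id = {r.cnvr_id: r for r in cnm.cnvrs}
    rows = []
    for cnvr_id, series in cnm.values.iterrows():
        rec = vst(series.to_dict(), groups, ddof=ddof, cnvr_id=cnvr_id)
        r = by_id[cnvr_id]
        rows.append(
            (cnvr_id, r.chrom, r.start, r.end, rec.v_t, rec.v_s,
             float("nan") if rec.vst is None else rec.vst,
             rec.group_sizes[0], rec.group_sizes[1])
        )
    return pd.DataFrame(
        rows,
        columns=["cnvr_id", "chrom", "start", "end", "v_t", "v_s", "vst",
                 "n_group1", "n_group2"],
    )


# ---------------------------------------------------------------------------
# candidate regions
# ---------------------------------------------------------------------------


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    statistic: str
    value: float
    rank: int  # 1-based within its scan
    percentile: float  # fraction of scanned items at or above this rank
    region_id: str = ""
    gene_ids: list[str] = field(default_factory=list)
    qtl_hits: list[QtlRecord] = field(default_factory=list)


def _top_cut(n_defined: int, top_fraction: float) -> int:
    return math.ceil(top_fraction * n_defined)


def vst_scan(
    cnm: CopyNumberMatrix,
    groups: GroupAssignment,
    top_fraction: float = VST_TOP_FRACTION,
    ddof: int = 0,
) -> tuple[list[CandidateRegion], pd.DataFrame]:
    """Rank CNVRs by V_ST descending and return the top
    ``ceil(top_fraction * N_defined)``, ties at the cut resolved by
    (chrom, start).  Also returns the full V_ST table."""
    table = vst_table(cnm, groups, ddof=ddof)
    defined = table.dropna(subset=["vst"])
    if defined.empty:
        logger.warning("vst_scan: every CNVR has undefined V_ST")
        return [], table
    n_top = _top_cut(len(defined), top_fraction)
    ranked = defined.sort_values(
        ["vst", "chrom", "start"], ascending=[False, True, True]
    ).reset_index(drop=True)
    out = []
    for i in range(n_top):
        row = ranked.iloc[i]
        out.append(
            CandidateRegion(
                chrom=row["chrom"],
                start=int(row["start"]),
                end=int(row["end"]),
                statistic="vst",
                value=float(row["vst"]),
                rank=i + 1,
                percentile=(i + 1) / len(defined),
                region_id=row["cnvr_id"],
            )
        )
    return out, table


def fst_scan(
    window_table: pd.DataFrame,
    top_fraction: float = FST_TOP_FRACTION,
    statistic: str = "fst",
    ascending: bool = False,
) -> list[CandidateRegion]:
    """Select the top ``ceil(top_fraction * N_defined)`` windows by the given
    statistic and merge adjacent/overlapping selected windows (bookended
    merge) into candidate regions.

    ``ascending=True`` selects the lowest values instead (used for the pi
    scan, where sweeps deplete diversity).
    """
    defined = window_table.dropna(subset=[statistic])
    if defined.empty:
        return []
    n_top = _top_cut(len(defined), top_fraction)
    ranked = defined.sort_values(
        [statistic, "chrom", "start"], ascending=[ascending, True, True]
    ).head(n_top)
    picked = ranked.sort_values(["chrom", "start"])

    merged: list[CandidateRegion] = []
    for row in picked.itertuples(index=False):
        val = float(getattr(row, statistic))
        if (
            merged
            and merged[-1].chrom == row.chrom
            and row.start <= merged[-1].end
        ):
            merged[-1].end = max(merged[-1].end, int(row.end))
            merged[-1].value = (
                min(merged[-1].value, val) if ascending else max(merged[-1].value, val)
            )
        else:
            merged.append(
                CandidateRegion(
                    chrom=row.chrom,
                    start=int(row.start),
                    end=int(row.end),
                    statistic=statistic,
                    value=val,
                    rank=len(merged) + 1,
                    percentile=n_top / len(defined),
                )
            )
    return merged


# ---------------------------------------------------------------------------
# PSG consensus and interval overlaps
# ---------------------------------------------------------------------------


def psg_consensus(
    method_genes: Mapping[str, Iterable[str]], min_methods: int = PSG_MIN_METHODS
) -> set[str]:
    """Genes supported by the top windows of at least ``min_methods`` scans."""
    if len(method_genes) < 2:
        raise CnvSweepError("psg_consensus requires at least two method gene sets")
    tally: dict[str, int] = defaultdict(int)
    for genes in method_genes.values():
        for g in set(genes):
            tally[g] += 1
    return {g for g, k in tally.items() if k >= min_methods}


def genes_in_regions(
    regions: Sequence[CandidateRegion], genes: Sequence[GeneModel]
) -> dict[int, list[str]]:
    """Map region index -> gene_ids whose span overlaps the region >= 1 bp.
    Also fills each region's ``gene_ids`` in place."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        trees[g.chrom].addi(g.start, g.end, g.gene_id)
    out: dict[int, list[str]] = {}
    for i, r in enumerate(regions):
        hits = sorted(iv.data for iv in trees[r.chrom].overlap(r.start, r.end))
        r.gene_ids = hits
        out[i] = hits
    return out


def qtl_overlap(
    items: Sequence,
    qtls: Sequence[QtlRecord],
    reciprocal: float | None = None,
) -> pd.DataFrame:
    """Every (item, QTL) pair with >= 1 bp overlap, one row per pair with
    both records (the bedtools ``-wa -wb`` contract).

    Items need ``chrom``/``start``/``end`` and one of ``region_id``,
    ``cnvr_id`` or ``gene_id`` attributes.  ``reciprocal`` optionally
    requires the overlap to cover at least that fraction of both intervals.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for q in qtls:
        trees[q.chrom].addi(q.start, q.end, q)
    rows = []
    for item in items:
        item_id = (
            getattr(item, "region_id", "")
            or getattr(item, "cnvr_id", "")
            or getattr(item, "gene_id", "")
        )
        for iv in sorted(trees[item.chrom].overlap(item.start, item.end)):
            q: QtlRecord = iv.data
            ov = min(item.end, q.end) - max(item.start, q.start)
            if reciprocal is not None:
                if ov < reciprocal * (item.end - item.start) or ov < reciprocal * (
                    q.end - q.start
                ):
                    continue
            rows.append(
                (
                    item_id, item.chrom, item.start, item.end,
                    q.qtl_id, q.start, q.end, q.trait_class, q.p_value, ov,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "item_id", "chrom", "item_start", "item_end",
            "qtl_id", "qtl_start", "qtl_end", "trait_class", "p_value",
            "overlap_bp",
        ],
    )


# ---------------------------------------------------------------------------
# CNVR summary
# ---------------------------------------------------------------------------


def summarize_cnvrs(cnvrs: Sequence[Cnvr], genome_length: int | None = None) -> dict:
    """Summary of a CNVR set: counts per type, total and mean length,
    genomic-context percentages (2 decimals), genome coverage when the
    genome length is known.

    Mean length is rounded to the nearest bp; type counts always sum to the
    total and context percentages to 100 (up to rounding).
    """
    n = len(cnvrs)
    if n == 0:
        return {
            "n_cnvr": 0,
            "counts_by_type": {"deletion": 0, "duplication": 0, "both": 0},
            "total_length_bp": 0,
            "mean_length_bp": 0,
            "context_percent": {},
            "empty": True,
        }
    counts = {"deletion": 0, "duplication": 0, "both": 0}
    for r in cnvrs:
        counts[r.cnvr_type] += 1
    total_len = int(sum(r.length for r in cnvrs))
    ctx_counts: dict[str, int] = defaultdict(int)
    for r in cnvrs:
        ctx_counts[r.context or "unannotated"] += 1
    context_percent = {
        k: round(100.0 * v / n, 2) for k, v in sorted(ctx_counts.items())
    }
    out = {
        "n_cnvr": n,
        "counts_by_type": counts,
        "total_length_bp": total_len,
        "mean_length_bp": round(total_len / n),
        "context_percent": context_percent,
        "empty": False,
    }
    if genome_length:
        out["genome_coverage_percent"] = round(100.0 * total_len / genome_length, 2)
    return out
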