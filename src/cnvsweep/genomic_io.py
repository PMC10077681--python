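"""Readers and writers for the genomic formats the pipeline touches.

Internal coordinate convention: every interval (windows, genes, exons, QTLs,
CNVRs) is 0-based half-open.  VCF and GFF3 coordinates (1-based inclusive)
are converted at the I/O boundary; BED is written natively.  Site positions
inside a :class:`HaplotypeMatrix` keep their 1-based VCF coordinate, so a
site at VCF position ``p`` lies in window ``[s, e)`` iff ``s <= p - 1 < e``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd

logger = logging.getLogger("cnvsweep")

TRAIT_CLASSES = frozenset(
    {"immunity", "meat", "milk", "production", "reproduction", "health", "other"}
)


class CnvSweepError(ValueError):
    """Raised on invalid inputs or configuration."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Window:
    """A genomic window, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise CnvSweepError(f"degenerate window [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos0: int) -> bool:
        """Whether a 0-based position falls inside the window."""
        return self.start <= pos0 < self.end


@dataclass
class HaplotypeMatrix:
    """Phased biallelic haplotypes: one row per haplotype, one column per site.

    ``alleles`` holds 0 (REF) / 1 (ALT); ``ancestral_is_ref[j]`` records the
    derived-allele polarity of site ``j``.  ``sample_ids`` names the owner of
    each haplotype row (every sample owns exactly two consecutive rows).
    """

    chrom: str
    positions: np.ndarray  # 1-based bp, strictly increasing
    alleles: np.ndarray  # (n_hap, n_sites) uint8 in {0, 1}
    sample_ids: list[str]
    ancestral_is_ref: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise CnvSweepError("alleles must be a 2-D matrix")
        if self.alleles.shape[1] != self.positions.size:
            raise CnvSweepError("positions / alleles column mismatch")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise CnvSweepError("positions must be strictly increasing")
        if self.alleles.size and self.alleles.max() > 1:
            raise CnvSweepError("alleles must be 0/1 (biallelic sites only)")
        n_samples = len(dict.fromkeys(self.sample_ids))
        if self.alleles.shape[0] != 2 * n_samples:
            raise CnvSweepError(
                f"{self.alleles.shape[0]} haplotype rows for {n_samples} samples "
                "(expected 2 per sample)"
            )
        if self.ancestral_is_ref is None:
            self.ancestral_is_ref = np.ones(self.positions.size, dtype=bool)
        else:
            self.ancestral_is_ref = np.asarray(self.ancestral_is_ref, dtype=bool)

    @property
    def n_hap(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.sample_ids))

    def derived(self) -> np.ndarray:
        """Allele matrix recoded so 1 is the derived allele at every site."""
        out = self.alleles.copy()
        flip = ~self.ancestral_is_ref
        out[:, flip] = 1 - out[:, flip]
        return out

    def derived_counts(self) -> np.ndarray:
        return self.derived().sum(axis=0).astype(np.int64)

    def site_slice(self, window: Window) -> slice:
        """Column slice of the sites falling inside ``window``."""
        lo = int(np.searchsorted(self.positions - 1, window.start, side="left"))
        hi = int(np.searchsorted(self.positions - 1, window.end, side="left"))
        return slice(lo, hi)

    def subset_rows(self, rows: Sequence[int]) -> "HaplotypeMatrix":
        rows = list(rows)
        return HaplotypeMatrix(
            chrom=self.chrom,
            positions=self.positions.copy(),
            alleles=self.alleles[rows],
            sample_ids=[self.sample_ids[i] for i in rows],
            ancestral_is_ref=self.ancestral_is_ref.copy(),
        )

    def rows_of(self, samples: Iterable[str]) -> list[int]:
        wanted = set(samples)
        return [i for i, s in enumerate(self.sample_ids) if s in wanted]


@dataclass(frozen=True)
class GeneModel:
    """A gene span with exon sub-intervals, 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise CnvSweepError(f"degenerate gene span for {self.gene_id}")
        for s, e in self.exons:
            if e <= s or s < self.start or e > self.end:
                raise CnvSweepError(
                    f"exon [{s},{e}) outside gene span of {self.gene_id}"
                )


@dataclass(frozen=True)
class QtlRecord:
    qtl_id: str
    chrom: str
    start: int
    end: int
    trait_class: str
    p_value: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise CnvSweepError(f"degenerate QTL interval for {self.qtl_id}")
        if not 0.0 <= self.p_value <= 1.0:
            raise CnvSweepError(f"QTL {self.qtl_id} p-value outside [0, 1]")


@dataclass
class GroupAssignment:
    """Sample -> group-label map with exactly two non-empty groups."""

    assignment: Mapping[str, str]

    def __post_init__(self) -> None:
        labels = sorted(set(self.assignment.values()))
        if len(labels) != 2:
            raise CnvSweepError(
                f"expected exactly two group labels, got {labels or 'none'}"
            )
        self._labels = tuple(labels)

    @property
    def labels(self) -> tuple[str, str]:
        return self._labels

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {lab: [] for lab in self._labels}
        for sample, lab in self.assignment.items():
            out[lab].append(sample)
        return out

    def of(self, sample: str) -> str:
        try:
            return self.assignment[sample]
        except KeyError:
            raise CnvSweepError(f"sample {sample!r} missing from group table") from None

    def check_samples(self, samples: Iterable[str]) -> None:
        missing = [s for s in samples if s not in self.assignment]
        if missing:
            raise CnvSweepError(
                "samples missing from group table: " + ", ".join(sorted(missing))
            )


# ---------------------------------------------------------------------------
# VCF genotypes
# ---------------------------------------------------------------------------


def read_genotypes(path: str | Path, region: str | None = None) -> HaplotypeMatrix:
    """Read phased biallelic SNPs from a VCF into a :class:`HaplotypeMatrix`.

    Multiallelic records, indels and sites with unphased or missing genotypes
    are skipped (counts logged).  Derived-allele polarity is taken from the
    ``AA`` INFO key when present; otherwise ALT is treated as derived and a
    warning is logged once.
    """
    import cyvcf2

    vcf = cyvcf2.VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise CnvSweepError(f"{path}: VCF has no samples / GT field")

    skipped = {"not_biallelic_snp": 0, "unphased_or_missing": 0}
    positions: list[int] = []
    cols: list[np.ndarray] = []
    anc_is_ref: list[bool] = []
    chrom: str | None = None
    missing_aa = False

    iterator = vcf(region) if region else vcf
    for v in iterator:
        if not v.is_snp or len(v.ALT) != 1:
            skipped["not_biallelic_snp"] += 1
            continue
        gts = v.genotypes  # [[a, b, phased], ...]
        ok = all(len(g) == 3 and g[2] and g[0] in (0, 1) and g[1] in (0, 1) for g in gts)
        if not ok:
            skipped["unphased_or_missing"] += 1
            continue
        if chrom is None:
            chrom = v.CHROM
        elif v.CHROM != chrom:
            continue  # single-chromosome matrix; other contigs need a region
        aa = v.INFO.get("AA")
        if aa is None:
            missing_aa = True
            anc_is_ref.append(True)
        else:
            anc_is_ref.append(str(aa).upper() == v.REF.upper())
        positions.append(v.POS)
        col = np.fromiter((a for g in gts for a in g[:2]), dtype=np.uint8, count=2 * len(gts))
        cols.append(col)

    n_skipped = sum(skipped.values())
    if n_skipped:
        logger.info(
            "read_genotypes(%s): skipped %d records (%s)", path, n_skipped, skipped
        )
    if missing_aa:
        logger.warning(
            "read_genotypes(%s): no AA annotation at some sites; ALT treated as derived",
            path,
        )
    if not positions:
        raise CnvSweepError(
            f"{path}: no usable records after filtering "
            "(kept: biallelic SNPs with fully phased GT)"
        )
    return HaplotypeMatrix(
        chrom=str(chrom),
        positions=np.asarray(positions, dtype=np.int64),
        alleles=np.column_stack(cols),
        sample_ids=[s for s in samples for _ in range(2)],
        ancestral_is_ref=np.asarray(anc_is_ref, dtype=bool),
    )


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


def make_windows(chrom_length: int, size: int, step: int, chrom: str = "1") -> list[Window]:
    """Sliding windows starting at 0, step, 2*step, ... for all starts below
    ``chrom_length``; trailing windows are clipped at the chromosome end."""
    if size <= 0 or step <= 0:
        raise CnvSweepError("window size and step must be positive")
    windows = []
    for start in range(0, chrom_length, step):
        windows.append(Window(chrom, start, min(start + size, chrom_length)))
    return windows


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------


def read_gff(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene + exon features) from GFF3, converting the
    1-based inclusive coordinates to 0-based half-open."""
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            keep_order=True,
            merge_strategy="create_unique",
            force=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        if g.end < g.start:
            logger.warning("read_gff: rejected gene %s with end < start", g.id)
            continue
        exons = []
        for e in db.children(g, featuretype="exon", order_by="start"):
            if e.end < e.start:
                logger.warning("read_gff: rejected exon of %s with end < start", g.id)
                continue
            exons.append((e.start - 1, e.end))
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                start=g.start - 1,
                end=g.end,
                exons=tuple(exons),
            )
        )
    return genes


def write_gff(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene + exon features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tcnvsweep\tgene\t{g.start + 1}\t{g.end}\t.\t+\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tcnvsweep\texon\t{s + 1}\t{e}\t.\t+\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# QTL table / group table
# ---------------------------------------------------------------------------

QTL_COLUMNS = ["qtl_id", "chrom", "start", "end", "trait_class", "p_value"]


def read_qtl_table(path: str | Path, p_max: float = 0.05) -> list[QtlRecord]:
    """Read a headered QTL TSV (1-based inclusive coordinates) and drop
    records with ``p_value > p_max``.  Malformed intervals are rejected and
    logged; unknown trait classes are mapped to ``other``."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in QTL_COLUMNS if c not in df.columns]
    if missing:
        raise CnvSweepError(f"{path}: QTL table missing columns {missing}")
    out: list[QtlRecord] = []
    n_rejected = n_dropped = 0
    for row in df.itertuples(index=False):
        if row.end < row.start:
            n_rejected += 1
            logger.warning("read_qtl_table: rejected %s (end < start)", row.qtl_id)
            continue
        if row.p_value > p_max:
            n_dropped += 1
            continue
        trait = str(row.trait_class).lower()
        if trait not in TRAIT_CLASSES:
            logger.info("read_qtl_table: trait class %r mapped to 'other'", trait)
            trait = "other"
        out.append(
            QtlRecord(
                qtl_id=str(row.qtl_id),
                chrom=str(row.chrom),
                start=int(row.start) - 1,
                end=int(row.end),
                trait_class=trait,
                p_value=float(row.p_value),
            )
        )
    if n_rejected or n_dropped:
        logger.info(
            "read_qtl_table(%s): %d malformed rejected, %d above p_max dropped",
            path,
            n_rejected,
            n_dropped,
        )
    return out


def write_qtl_table(qtls: Sequence[QtlRecord], path: str | Path) -> None:
    rows = [
        (q.qtl_id, q.chrom, q.start + 1, q.end, q.trait_class, q.p_value) for q in qtls
    ]
    pd.DataFrame(rows, columns=QTL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_group_table(path: str | Path) -> GroupAssignment:
    """Read a two-column headered TSV (sample_id, group)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise CnvSweepError(f"{path}: group table missing column {col!r}")
    return GroupAssignment(dict(zip(df["sample_id"].astype(str), df["group"].astype(str))))


def write_group_table(groups: GroupAssignment, path: str | Path) -> None:
    pd.DataFrame(
        sorted(groups.assignment.items()), columns=["sample_id", "group"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# generic writers
# ---------------------------------------------------------------------------


def write_bed(rows: Iterable[Sequence], path: str | Path) -> None:
    """Write rows (chrom, start, end, *extra) as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV output shared by every result table."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")
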