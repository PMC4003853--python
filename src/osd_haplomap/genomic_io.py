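"""Genomic file formats, interval arithmetic, and the fixed window grid.

Coordinate conventions are fixed package-wide and never mixed:

* VCF positions are 1-based (as in the format itself);
* every in-memory interval — windows, gaps, QTL, blocks — is 0-based,
  half-open, BED-style.

A variant at VCF position ``p`` therefore belongs to the window whose
``start <= p - 1 < end``.  Strand is irrelevant throughout: only variant
coordinates are used, never the sequence context.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "VariantSite",
    "FilterLog",
    "PairwiseVariants",
    "GenomeWindows",
    "IntervalSet",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_variants",
    "build_windows",
    "callable_mask",
]

DEFAULT_WINDOW_SIZE = 100_000

#: genotype call states used throughout the package
HOM_REF = "hom_ref"
HOM_ALT = "hom_alt"
HET = "het"
MISSING = "missing"
HOM_OTHER = "hom_other"  # homozygous for a different alternate allele

_BASES = frozenset("ACGT")


@dataclass
class VariantSite:
    """One biallelic site with per-strain genotype calls.

    ``pos`` is 1-based (VCF convention). ``genotypes`` maps strain name to
    one of ``hom_ref``/``hom_alt``/``het``/``missing``/``hom_other``.
    ``consequences`` and ``damage_class`` are optional annotations attached
    from an external predictor's output table.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: dict[str, str]
    variant_class: str = "SNV"
    consequences: tuple[str, ...] | None = None
    damage_class: str | None = None
    consequence_classes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"VCF position must be >= 1, got {self.pos}")

    @property
    def start(self) -> int:
        """0-based start coordinate of the site."""
        return self.pos - 1


@dataclass
class FilterLog:
    """Counts of sites dropped while reading a pairwise comparison."""

    n_records: int = 0
    n_sites: int = 0  # after multi-allelic decomposition
    n_het: int = 0
    n_missing: int = 0
    n_no_difference: int = 0
    n_other_alt: int = 0
    n_retained_snv: int = 0
    n_retained_indel: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(vars(self))


@dataclass
class PairwiseVariants:
    """Homozygous-difference sites between two strains, SNVs and indels apart."""

    strain_a: str
    strain_b: str
    snvs: list[VariantSite]
    indels: list[VariantSite]
    filter_log: FilterLog


class GenomeWindows:
    """Non-overlapping windows tiling each chromosome in order.

    All but possibly the last window per chromosome have length
    ``window_size``; a shorter trailing window is kept and flagged
    ``partial``.
    """

    def __init__(self, table: pd.DataFrame, window_size: int,
                 chrom_sizes: Mapping[str, int]):
        self.table = table
        self.window_size = int(window_size)
        self.chrom_sizes = dict(chrom_sizes)
        # per-chromosome (row offset, n windows) for O(1) window lookup
        self._offsets: dict[str, tuple[int, int]] = {}
        off = 0
        for chrom, sub in table.groupby("chrom", sort=False):
            self._offsets[chrom] = (off, len(sub))
            off += len(sub)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    def window_index(self, chrom: str, pos: int) -> int:
        """Global row index of the window containing 1-based position ``pos``."""
        if chrom not in self._offsets:
            raise KeyError(f"unknown chromosome {chrom!r}")
        off, n = self._offsets[chrom]
        if not 1 <= pos <= self.chrom_sizes[chrom]:
            raise ValueError(
                f"position {chrom}:{pos} outside chromosome "
                f"(length {self.chrom_sizes[chrom]})"
            )
        return off + (pos - 1) // self.window_size

    def n_full_windows(self) -> int:
        return int((~self.table["partial"]).sum())


@dataclass
class IntervalSet:
    """A set of labelled genomic intervals (0-based, half-open)."""

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start", "end", "label"]))

    def __post_init__(self) -> None:
        df = self.df.copy()
        if "label" not in df.columns:
            df["label"] = ""
        df = df[["chrom", "start", "end", "label"]]
        if len(df) and not (df["start"] < df["end"]).all():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValueError(
                f"interval with start >= end: {bad.chrom}:{bad.start}-{bad.end}")
        if len(df) and (df["start"] < 0).any():
            raise ValueError("negative interval start")
        self.df = df.sort_values(["chrom", "start", "end"],
                                 kind="mergesort").reset_index(drop=True)

    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple]) -> "IntervalSet":
        rows = []
        for t in tuples:
            chrom, start, end, *rest = t
            rows.append((chrom, int(start), int(end), rest[0] if rest else ""))
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))

    @classmethod
    def from_bed(cls, path: str | Path) -> "IntervalSet":
        rows = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{ln}: expected >= 3 BED columns")
                rows.append((parts[0], int(parts[1]), int(parts[2]),
                             parts[3] if len(parts) > 3 else ""))
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))

    def to_bed(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for row in self.df.itertuples(index=False):
                cols = [row.chrom, str(row.start), str(row.end)]
                if row.label:
                    cols.append(str(row.label))
                fh.write("\t".join(cols) + "\n")
        return path

    def __len__(self) -> int:
        return len(self.df)

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Sorted (starts, ends) arrays per chromosome (not merged)."""
        out = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            out[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy())
        return out

    def merged(self) -> "IntervalSet":
        """Union of the intervals per chromosome (labels dropped)."""
        rows = []
        for chrom, (starts, ends) in self.by_chrom().items():
            for s, e in _merge_sorted(starts, ends):
                rows.append((chrom, s, e, ""))
        return IntervalSet(pd.DataFrame(
            rows, columns=["chrom", "start", "end", "label"]))

    def total_bp(self) -> int:
        """Total bases covered, counting overlapping bases once."""
        m = self.merged().df
        return int((m["end"] - m["start"]).sum())


def _merge_sorted(starts: np.ndarray, ends: np.ndarray) -> list[tuple[int, int]]:
    """Merge possibly-overlapping intervals already sorted by start."""
    merged: list[tuple[int, int]] = []
    for s, e in zip(starts.tolist(), ends.tolist()):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def overlap_bp(a: IntervalSet, b: IntervalSet) -> int:
    """Bases covered by both interval sets (each taken as a union)."""
    am = a.merged().by_chrom()
    total = 0
    for chrom, (bs, be) in b.merged().by_chrom().items():
        if chrom not in am:
            continue
        s1, e1 = am[chrom]
        total += _pairwise_overlap(s1, e1, bs, be)
    return total


def _pairwise_overlap(s1, e1, s2, e2) -> int:
    """Overlap bp between two merged, sorted interval lists on one chromosome."""
    ov = np.minimum(e1[:, None], e2[None, :]) - np.maximum(s1[:, None], s2[None, :])
    return int(np.clip(ov, 0, None).sum())


# ---------------------------------------------------------------------------
# chrom.sizes


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column name/length TSV, keeping file order."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected 'name<TAB>length'")
            sizes[parts[0]] = int(parts[1])
    if not sizes:
        raise ValueError(f"{path}: no chromosomes found")
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")
    return path


# ---------------------------------------------------------------------------
# VCF reading


def _classify(gt: Sequence[int], allele_index: int) -> str:
    alleles = [a for a in gt[:-1]]  # cyvcf2 appends the phase flag
    if any(a < 0 for a in alleles):
        return MISSING
    if len(set(alleles)) > 1:
        return HET
    a = alleles[0]
    if a == allele_index:
        return HOM_ALT
    if a == 0:
        return HOM_REF
    return HOM_OTHER


def read_variants(vcf_path: str | Path,
                  strain_pair: tuple[str, str]) -> PairwiseVariants:
    """Read homozygous-difference sites between two strains from a VCF.

    Only sites where both strains carry homozygous, non-missing calls that
    differ from each other are retained — the filtering rule under which
    per-window strain differences are counted.  Heterozygous and missing
    calls, and sites where the two strains agree, are dropped and tallied
    in the returned :class:`FilterLog`.  Multi-allelic records are
    decomposed into biallelic sites first; SNVs and indels are routed to
    separate streams.
    """
    strain_a, strain_b = strain_pair
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    for strain in (strain_a, strain_b):
        if strain not in samples:
            raise ValueError(
                f"strain {strain!r} not in VCF; available samples: {samples}")
    ia, ib = samples.index(strain_a), samples.index(strain_b)

    log = FilterLog()
    snvs: list[VariantSite] = []
    indels: list[VariantSite] = []
    for rec in vcf:
        log.n_records += 1
        gts = rec.genotypes
        for alt_i, alt in enumerate(rec.ALT, start=1):
            log.n_sites += 1
            call_a = _classify(gts[ia], alt_i)
            call_b = _classify(gts[ib], alt_i)
            calls = (call_a, call_b)
            if HET in calls:
                log.n_het += 1
                continue
            if MISSING in calls:
                log.n_missing += 1
                continue
            if HOM_OTHER in calls:
                log.n_other_alt += 1
                continue
            if call_a == call_b:
                log.n_no_difference += 1
                continue
            site = VariantSite(
                chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=alt,
                genotypes={strain_a: call_a, strain_b: call_b},
                variant_class=_variant_class(rec.REF, alt),
            )
            if site.variant_class == "SNV":
                log.n_retained_snv += 1
                snvs.append(site)
            else:
                log.n_retained_indel += 1
                indels.append(site)
    return PairwiseVariants(strain_a, strain_b, snvs, indels, log)


def _variant_class(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1 and ref in _BASES and alt in _BASES:
        return "SNV"
    return "indel"


# ---------------------------------------------------------------------------
# window grid and callable mask


def build_windows(chrom_sizes: Mapping[str, int],
                  window_size: int = DEFAULT_WINDOW_SIZE) -> GenomeWindows:
    """Tile each chromosome with non-overlapping fixed-size windows.

    The trailing window of a chromosome whose length is not a multiple of
    ``window_size`` is shorter and flagged ``partial``.
    """
    if window_size < 1:
        raise ValueError("window_size must be positive")
    rows = []
    for chrom, length in chrom_sizes.items():
        length = int(length)
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length")
        start = 0
        while start < length:
            end = min(start + window_size, length)
            rows.append((chrom, start, end, end - start < window_size))
            start = end
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "partial"])
    return GenomeWindows(table, window_size, chrom_sizes)


def _masked_before(x: np.ndarray, gs: np.ndarray, ge: np.ndarray,
                   cumlen: np.ndarray) -> np.ndarray:
    """Gap bases in [0, x) for merged sorted gaps (vectorised over x)."""
    idx = np.searchsorted(ge, x, side="left")
    full = cumlen[idx]
    partial = np.where(
        (idx < len(gs)) & (gs[np.minimum(idx, len(gs) - 1)] < x),
        x - gs[np.minimum(idx, len(gs) - 1)], 0)
    return full + np.clip(partial, 0, None)


def callable_mask(gaps_a: IntervalSet, gaps_b: IntervalSet,
                  windows: GenomeWindows) -> np.ndarray:
    """Per-window count of bases callable in both strains.

    A base is callable when it lies outside the union of both strains'
    zero-coverage gaps: ``callable = window length - |window ∩ (gaps_a ∪
    gaps_b)|``.  Gaps on chromosomes absent from the window grid are
    skipped with a warning.
    """
    both = IntervalSet(pd.concat([gaps_a.df, gaps_b.df], ignore_index=True))
    for chrom in both.df["chrom"].unique():
        if chrom not in windows.chrom_sizes:
            warnings.warn(f"gap interval on unknown chromosome {chrom!r} skipped")
    merged = both.merged().by_chrom()

    tbl = windows.table
    out = (tbl["end"] - tbl["start"]).to_numpy().copy()
    for chrom, sub in tbl.groupby("chrom", sort=False):
        if chrom not in merged:
            continue
        gs, ge = merged[chrom]
        clen = windows.chrom_sizes[chrom]
        if len(gs) and (gs.min() < 0 or ge.max() > clen):
            raise ValueError(
                f"gap interval outside chromosome {chrom} bounds (0, {clen})")
        cumlen = np.concatenate([[0], np.cumsum(ge - gs)])
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        masked = (_masked_before(ends, gs, ge, cumlen)
                  - _masked_before(starts, gs, ge, cumlen))
        out[sub.index] -= masked
    return out
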