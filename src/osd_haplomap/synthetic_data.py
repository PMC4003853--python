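"""Mosaic-genome simulator for closely related inbred strains.

Inbred strains bred from one outbred founder colony carry genomes that are
mosaics of two kinds of segment: identity-by-descent (IBD) tracts inherited
from the same founder haplotype, where the only differences are mutations
fixed after strain separation (a few per Mb), and divergent-ancestry tracts
fixed from different founder haplotypes, where differences run three
orders of magnitude denser.  The simulator tiles each chromosome with
alternating shared/divergent segments, drops homozygous SNVs as Poisson
processes at the two regime rates, and places per-strain zero-coverage gap
intervals, returning the ground-truth segmentation alongside.

Defaults mirror the pairwise comparisons of closely related rat strains
this model was built for: between-strain SNV rates of 5x10^-6 /bp (IBD)
and 1.5x10^-3 /bp (divergent), divergent segments averaging 0.9 Mb and
covering ~15% of the genome.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .genomic_io import IntervalSet, VariantSite, write_chrom_sizes

__all__ = [
    "MosaicParams",
    "MosaicTruth",
    "MosaicResult",
    "InfeasibleParametersError",
    "simulate_mosaic",
    "write_fixture",
    "rat_scale_chrom_sizes",
]

_ACGT = np.array(list("ACGT"))


class InfeasibleParametersError(ValueError):
    """The requested mosaic cannot fit on the given chromosomes."""


@dataclass(frozen=True)
class MosaicParams:
    """Parameters of the two-regime mosaic model.

    Rates are SNVs per bp *between two strains*; lengths in bp.
    ``indel_fraction`` routes that share of generated variants through the
    same placement process but emits them as 1-bp indels, since SNPs and
    indels are tallied separately downstream.
    """

    chrom_lengths: Mapping[str, int]
    n_strains: int = 2
    divergent_fraction: float = 0.15
    seg_length_mean: float = 900_000.0
    rate_divergent: float = 1.5e-3
    rate_ibd: float = 5e-6
    gap_fraction: float = 0.02
    gap_length_mean: float = 5_000.0
    indel_fraction: float = 0.0
    seed: int = 0
    strain_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths must not be empty")
        if any(int(v) <= 0 for v in self.chrom_lengths.values()):
            raise ValueError("all chromosome lengths must be positive")
        if not 0.0 <= self.divergent_fraction <= 1.0:
            raise InfeasibleParametersError(
                f"divergent_fraction must be in [0, 1], got {self.divergent_fraction}")
        if not self.rate_divergent > self.rate_ibd >= 0:
            raise ValueError("require rate_divergent > rate_ibd >= 0")
        if self.seg_length_mean <= 0 or self.gap_length_mean <= 0:
            raise ValueError("segment and gap mean lengths must be positive")
        if not 0.0 <= self.gap_fraction < 1.0:
            raise ValueError("gap_fraction must be in [0, 1)")
        if not 0.0 <= self.indel_fraction <= 1.0:
            raise ValueError("indel_fraction must be in [0, 1]")
        if self.n_strains < 2:
            raise ValueError("need at least two strains")
        if self.strain_names is not None and len(self.strain_names) != self.n_strains:
            raise ValueError("strain_names length must equal n_strains")

    @property
    def strains(self) -> tuple[str, ...]:
        if self.strain_names is not None:
            return tuple(self.strain_names)
        return tuple(f"strain{i + 1}" for i in range(self.n_strains))


@dataclass
class MosaicTruth:
    """Ground-truth divergent-ancestry segments, one interval set per pair."""

    divergent_segments: dict[tuple[str, str], IntervalSet]
    params: MosaicParams

    def divergent_bp(self, pair: tuple[str, str]) -> int:
        return self.divergent_segments[pair].total_bp()


@dataclass
class MosaicResult:
    """Everything one simulation produced."""

    variants: list[VariantSite]
    gaps: dict[str, IntervalSet]
    truth: MosaicTruth
    params: MosaicParams

    @property
    def strains(self) -> tuple[str, ...]:
        return self.params.strains


def _rng(seed: int, *scope: str) -> np.random.Generator:
    """Deterministic substream keyed by name, independent of loop order."""
    keys = [seed] + [zlib.crc32(s.encode()) for s in scope]
    return np.random.default_rng(keys)


def _place_intervals(rng: np.random.Generator, chrom_len: int,
                     target_bp: int, mean_len: float) -> list[tuple[int, int]]:
    """Place non-overlapping intervals totalling exactly ``target_bp``.

    Lengths are exponential with the stated mean (truncated so the running
    total hits the target exactly); the leftover space is split uniformly
    at random among the flanking/intervening spacers, i.e. interval starts
    follow uniform spacings.
    """
    if target_bp <= 0:
        return []
    if target_bp > chrom_len:
        raise InfeasibleParametersError(
            f"cannot place {target_bp} bp of segments on a "
            f"{chrom_len} bp chromosome")
    lengths: list[int] = []
    total = 0
    while total < target_bp:
        ln = max(1, int(round(rng.exponential(mean_len))))
        ln = min(ln, target_bp - total)
        lengths.append(ln)
        total += ln
    k = len(lengths)
    spare = chrom_len - target_bp
    cuts = np.sort(rng.random(k))
    props = np.diff(np.concatenate([[0.0], cuts, [1.0]]))
    spacers = np.floor(props * spare).astype(int)
    spacers[-1] += spare - spacers.sum()
    out = []
    pos = 0
    for spacer, ln in zip(spacers.tolist(), lengths):
        pos += spacer
        out.append((pos, pos + ln))
        pos += ln
    return out


def _poisson_positions(rng: np.random.Generator, start: int, end: int,
                       rate: float) -> np.ndarray:
    """Sorted unique 0-based positions of a Poisson process on [start, end)."""
    if rate <= 0 or end <= start:
        return np.empty(0, dtype=np.int64)
    n = rng.poisson(rate * (end - start))
    if n == 0:
        return np.empty(0, dtype=np.int64)
    return np.unique(rng.integers(start, end, size=n))


def simulate_mosaic(params: MosaicParams) -> MosaicResult:
    """Simulate a multi-strain mosaic genome.

    For every unordered strain pair, chromosomes are tiled by alternating
    shared/divergent segments (divergent lengths exponential with mean
    ``seg_length_mean``, total fixed at ``divergent_fraction`` of the
    chromosome), and homozygous SNV differences arise as Poisson processes
    at ``rate_divergent`` / ``rate_ibd`` per bp.  Exactly one strain of the
    pair is homozygous-alternate at each site; strains outside the pair are
    recorded as missing so pairwise comparisons stay independent.  Gap
    intervals are placed per strain from independent substreams, so the gap
    mask never perturbs variant positions.  The same seed always yields
    bit-identical output.
    """
    strains = params.strains
    pairs = [(strains[i], strains[j])
             for i in range(len(strains)) for j in range(i + 1, len(strains))]

    truth_segments: dict[tuple[str, str], IntervalSet] = {}
    variants: list[VariantSite] = []
    taken: dict[str, set[int]] = {c: set() for c in params.chrom_lengths}

    for pair in pairs:
        pair_tag = f"{pair[0]}|{pair[1]}"
        seg_rows = []
        for chrom, chrom_len in params.chrom_lengths.items():
            chrom_len = int(chrom_len)
            rng_seg = _rng(params.seed, "segments", chrom, pair_tag)
            target = int(round(params.divergent_fraction * chrom_len))
            segments = _place_intervals(rng_seg, chrom_len, target,
                                        params.seg_length_mean)
            seg_rows.extend((chrom, s, e, "") for s, e in segments)

            rng_var = _rng(params.seed, "variants", chrom, pair_tag)
            positions: list[np.ndarray] = []
            prev = 0
            for s, e in segments + [(chrom_len, chrom_len)]:
                positions.append(
                    _poisson_positions(rng_var, prev, s, params.rate_ibd))
                positions.append(
                    _poisson_positions(rng_var, s, e, params.rate_divergent))
                prev = e
            pos = np.concatenate(positions)
            pos.sort()
            carriers = rng_var.integers(0, 2, size=pos.size)
            ref_idx = rng_var.integers(0, 4, size=pos.size)
            alt_off = rng_var.integers(1, 4, size=pos.size)
            is_indel = (rng_var.random(pos.size) < params.indel_fraction
                        if params.indel_fraction > 0
                        else np.zeros(pos.size, dtype=bool))
            used = taken[chrom]
            for p, carrier, ri, ao, ind in zip(
                    pos.tolist(), carriers.tolist(), ref_idx.tolist(),
                    alt_off.tolist(), is_indel.tolist()):
                while p in used and p < chrom_len - 1:
                    p += 1  # resolve rare cross-pair collisions deterministically
                if p in used:
                    continue
                used.add(p)
                ref = _ACGT[ri]
                alt = _ACGT[(ri + ao) % 4]
                if ind:
                    ref, alt = (ref, ref + alt) if ao % 2 else (ref + alt, ref)
                gts = {s: "missing" for s in strains}
                gts[pair[carrier]] = "hom_alt"
                gts[pair[1 - carrier]] = "hom_ref"
                variants.append(VariantSite(
                    chrom=chrom, pos=p + 1, ref=str(ref), alt=str(alt),
                    genotypes=gts,
                    variant_class="indel" if ind else "SNV"))
        truth_segments[pair] = IntervalSet.from_tuples(seg_rows)

    chrom_order = {c: i for i, c in enumerate(params.chrom_lengths)}
    variants.sort(key=lambda v: (chrom_order[v.chrom], v.pos))

    gaps: dict[str, IntervalSet] = {}
    for strain in strains:
        rows = []
        for chrom, chrom_len in params.chrom_lengths.items():
            rng_gap = _rng(params.seed, "gaps", chrom, strain)
            target = int(round(params.gap_fraction * int(chrom_len)))
            rows.extend((chrom, s, e, "") for s, e in _place_intervals(
                rng_gap, int(chrom_len), target, params.gap_length_mean))
        gaps[strain] = IntervalSet.from_tuples(rows)

    truth = MosaicTruth(truth_segments, params)
    return MosaicResult(variants, gaps, truth, params)


# ---------------------------------------------------------------------------
# fixture output

_GT_CODE = {"hom_ref": "0/0", "hom_alt": "1/1", "het": "0/1", "missing": "./."}


def write_fixture(result: MosaicResult, outdir: str | Path) -> dict[str, Path]:
    """Write a simulation to disk as VCF + per-strain gap BEDs + truth BEDs.

    The files round-trip losslessly through the package's readers.
    Returns a dict of logical name -> path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = result.params
    strains = result.strains

    vcf_path = outdir / "variants.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=osd-haplomap-simulate\n")
        for chrom, length in params.chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={int(length)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(strains) + "\n")
        for v in result.variants:
            gt_cols = "\t".join(_GT_CODE[v.genotypes[s]] for s in strains)
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\t"
                     f"GT\t{gt_cols}\n")

    paths: dict[str, Path] = {"vcf": vcf_path}
    sizes_path = outdir / "chrom.sizes"
    write_chrom_sizes(params.chrom_lengths, sizes_path)
    paths["chrom_sizes"] = sizes_path

    for strain in strains:
        p = outdir / f"gaps_{strain}.bed"
        result.gaps[strain].to_bed(p)
        paths[f"gaps_{strain}"] = p

    for pair, segs in result.truth.divergent_segments.items():
        p = outdir / f"truth_{pair[0]}_{pair[1]}.bed"
        segs.to_bed(p)
        paths[f"truth_{pair[0]}_{pair[1]}"] = p
    return paths


def rat_scale_chrom_sizes() -> dict[str, int]:
    """Synthetic chromosome sizes at rat-genome scale (~2.72 Gb).

    Twenty-one chromosomes with lengths near the rat autosomes + X,
    adjusted so the 100-kb grid holds exactly 27,199 full windows — handy
    for exercising the genome-wide window grid without real data.
    """
    approx_mb = {
        "chr1": 267.9, "chr2": 258.2, "chr3": 171.1, "chr4": 187.1,
        "chr5": 173.1, "chr6": 147.6, "chr7": 143.1, "chr8": 129.1,
        "chr9": 113.4, "chr10": 110.7, "chr11": 87.8, "chr12": 46.8,
        "chr13": 111.2, "chr14": 112.2, "chr15": 109.8, "chr16": 90.2,
        "chr17": 97.3, "chr18": 87.3, "chr19": 59.2, "chr20": 55.3,
        "chrX": 160.7,
    }
    sizes = {c: int(mb * 1e6) + 50_000 for c, mb in approx_mb.items()}
    target = 27_199
    have = sum(s // 100_000 for s in sizes.values())
    sizes["chr1"] += (target - have) * 100_000
    if sizes["chr1"] <= 0:
        raise RuntimeError("size adjustment failed")
    return sizes
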