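"""Observed Strain Difference (OSD) segmentation.

The OSD of a genomic window is the number of homozygous SNV differences
between two strains divided by the number of bases in the window callable
in both strains — a local nucleotide-diversity measure.  Between two
closely related inbred strains its genome-wide distribution is bimodal:
a peak near zero from identity-by-descent (IBD) regions and a high peak
from segments fixed from different ancestral haplotypes.  The valley
between the two peaks of the smoothed distribution — the Polymorphism
Enrichment Threshold (PET) — classifies windows, and maximal runs of
contiguous supra-PET windows are merged into divergent haplotype blocks.

Smoothing follows the classical binned kernel density estimate: linear
binning of the OSD values onto 401 equally spaced grid points followed by
Gaussian-kernel smoothing, with the oversmoothed bandwidth selector
``h = 1.144 * sd * n^(-1/5)`` (the Gaussian-kernel specialisation of the
oversmoothing principle; an upper bound on the asymptotically optimal
bandwidth, deliberately conservative so spurious wiggles never masquerade
as a valley).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genomic_io import GenomeWindows, VariantSite

__all__ = [
    "DensityProfile",
    "HaplotypeBlock",
    "ComparisonSummary",
    "NoValleyError",
    "compute_osd",
    "estimate_density",
    "find_pet",
    "merge_blocks",
    "summarize_comparison",
    "density_peak_modes",
    "DEFAULT_GRID_POINTS",
    "OVERSMOOTH_CONST",
    "DEFAULT_MIN_CALLABLE_FRAC",
]

DEFAULT_GRID_POINTS = 401
#: Gaussian-kernel oversmoothed bandwidth constant, (243 / (70 sqrt(pi)))^(1/5)
OVERSMOOTH_CONST = (243.0 / (70.0 * math.sqrt(math.pi))) ** 0.2
#: windows with fewer callable bases than this fraction of the window size
#: are flagged unusable (their OSD denominator is too unstable)
DEFAULT_MIN_CALLABLE_FRAC = 0.10


class NoValleyError(RuntimeError):
    """The smoothed OSD distribution has no valley after its first peak.

    Raised for unimodal distributions, i.e. when no divergent-ancestry
    class is detectable between the strains.
    """


@dataclass
class DensityProfile:
    """Smoothed OSD distribution on an equally spaced grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n: int
    pet: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"osd": self.grid, "density": self.density})


@dataclass
class HaplotypeBlock:
    """A maximal run of contiguous supra-PET windows."""

    chrom: str
    start: int
    end: int
    n_windows: int
    snv_count: int
    mean_osd: float
    contains_partial: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ComparisonSummary:
    """Per-comparison summary in the layout of a strain-comparison table."""

    pet: float | None
    n_windows: int
    n_windows_above: int
    pct_windows_above: float
    n_blocks: int
    mean_block_length: float
    sd_block_length: float
    mean_osd_below: float
    mean_osd_above: float
    n_snps_total: int
    n_snps_in_blocks: int
    pct_snps_in_blocks: float
    unimodal: bool = False

    def as_dict(self) -> dict:
        return dict(vars(self))


# ---------------------------------------------------------------------------
# per-window OSD


def compute_osd(variants: Sequence[VariantSite], windows: GenomeWindows,
                callable_bases: np.ndarray,
                min_callable_frac: float = DEFAULT_MIN_CALLABLE_FRAC,
                ) -> pd.DataFrame:
    """Assign SNVs to windows and compute per-window OSD.

    ``variants`` must already be filtered to homozygous differences (the
    reader guarantees this).  Returns the window table with ``snv_count``,
    ``callable_bases``, ``osd`` and ``usable`` columns added; OSD is NaN
    for unusable windows (callable bases below ``min_callable_frac`` of
    the window size), which are excluded from density estimation and break
    block runs.
    """
    callable_bases = np.asarray(callable_bases)
    if len(callable_bases) != len(windows):
        raise ValueError("callable_bases length does not match window count")
    counts = np.zeros(len(windows), dtype=np.int64)
    for v in variants:
        try:
            counts[windows.window_index(v.chrom, v.pos)] += 1
        except (KeyError, ValueError) as exc:
            raise ValueError(
                f"variant {v.chrom}:{v.pos} ({v.ref}>{v.alt}) does not fall "
                f"on the window grid: {exc}") from exc

    table = windows.table.copy()
    table["snv_count"] = counts
    table["callable_bases"] = callable_bases
    floor = min_callable_frac * windows.window_size
    usable = callable_bases >= max(floor, 1)
    table["usable"] = usable
    with np.errstate(divide="ignore", invalid="ignore"):
        osd = counts / callable_bases.astype(float)
    osd[~usable] = np.nan
    table["osd"] = osd
    return table


# ---------------------------------------------------------------------------
# binned kernel density estimate


def oversmoothed_bandwidth(values: np.ndarray) -> float:
    """Oversmoothed bandwidth for the Gaussian kernel: 1.144 * sd * n^(-1/5)."""
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1)
    return OVERSMOOTH_CONST * sd * values.size ** (-0.2)


def estimate_density(osd_values: Sequence[float] | np.ndarray,
                     grid_points: int = DEFAULT_GRID_POINTS,
                     bandwidth: float | None = None,
                     min_bandwidth: float | None = None) -> DensityProfile:
    """Binned Gaussian kernel density of the OSD values on [0, max].

    Values are linearly binned onto ``grid_points`` equally spaced points
    starting at zero (so the IBD spike at OSD ~ 0 stays inside the first
    peak) and smoothed with a Gaussian kernel.  Bandwidth defaults to the
    oversmoothed selector; pass ``bandwidth`` to override, e.g. when all
    values coincide and the selector degenerates.

    ``min_bandwidth`` floors the *selected* bandwidth (an explicit
    ``bandwidth`` is taken as given).  OSD is a count ratio, so its values
    are quantised in steps of one SNV per callable window; when a
    comparison has no divergent class the selector shrinks to that
    quantisation scale and the kernel would resolve each integer-count
    spike as a separate mode.  Callers working with window OSD pass the
    quantum (1 / window size) here so count discreteness can never
    masquerade as a diversity class.
    """
    v = np.asarray(osd_values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least two defined OSD values")
    if (v < 0).any():
        raise ValueError("OSD values must be non-negative")
    vmax = float(v.max())
    if vmax <= 0:
        raise ValueError(
            "all OSD values are zero; the density grid [0, max] is "
            "degenerate — supply a positive bandwidth and non-trivial data")
    if bandwidth is None:
        bandwidth = oversmoothed_bandwidth(v)
        if min_bandwidth is not None:
            bandwidth = max(bandwidth, min_bandwidth)
        if not bandwidth > 0:
            raise ValueError(
                "oversmoothed bandwidth degenerated to zero (identical "
                "values); pass an explicit bandwidth override")
    elif bandwidth <= 0:
        raise ValueError("bandwidth must be positive")

    grid = np.linspace(0.0, vmax, grid_points)
    delta = grid[1] - grid[0]

    # linear binning: each value splits its unit mass between the two
    # neighbouring grid points in proportion to proximity
    pos = v / delta
    lo = np.floor(pos).astype(int)
    frac = pos - lo
    lo = np.clip(lo, 0, grid_points - 1)
    hi = np.clip(lo + 1, 0, grid_points - 1)
    weights = np.zeros(grid_points)
    np.add.at(weights, lo, 1.0 - frac)
    np.add.at(weights, hi, frac)

    diff = (grid[:, None] - grid[None, :]) / bandwidth
    kernel = np.exp(-0.5 * diff * diff) / (bandwidth * math.sqrt(2.0 * math.pi))
    density = kernel @ weights / v.size
    return DensityProfile(grid=grid, density=density,
                          bandwidth=float(bandwidth), n=int(v.size))


def _compress_plateaus(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse runs of equal values to their first index."""
    keep = np.concatenate([[True], d[1:] != d[:-1]])
    idx = np.flatnonzero(keep)
    return idx, d[idx]


def find_pet(profile: DensityProfile) -> float:
    """Locate the PET: the first density valley after the first peak.

    Scanning the grid from index 0 upward, a local maximum (resp. minimum)
    is a point strictly greater (resp. smaller) than both neighbours, with
    plateau runs collapsed to their first index; the grid boundaries count
    with their single neighbour.  Returns the grid OSD value at the first
    local minimum strictly after the first local maximum and stores it on
    the profile.  Raises :class:`NoValleyError` for unimodal profiles —
    callers treat that as "no divergent class detectable".
    """
    idx, d = _compress_plateaus(profile.density)
    m = len(d)
    first_max = None
    for k in range(m - 1):  # a trailing maximum cannot be followed by a valley
        if (k == 0 or d[k] > d[k - 1]) and d[k] > d[k + 1]:
            first_max = k
            break
    if first_max is None:
        raise NoValleyError("no local maximum in the OSD density profile")
    for k in range(first_max + 1, m - 1):
        if d[k] < d[k - 1] and d[k] < d[k + 1]:
            pet = float(profile.grid[idx[k]])
            profile.pet = pet
            return pet
    raise NoValleyError(
        "no local minimum after the first density peak (unimodal OSD "
        "distribution; no divergent class detectable)")


def density_peak_modes(profile: DensityProfile) -> tuple[float, float]:
    """Grid locations of the two density modes flanking the PET.

    Alternative location statistic for the two OSD regimes (the density
    modes rather than the per-window OSD means on each side of the PET).
    Requires a PET, computing it if absent.
    """
    pet = profile.pet if profile.pet is not None else find_pet(profile)
    below = profile.grid <= pet
    lo = profile.grid[below][np.argmax(profile.density[below])]
    hi = profile.grid[~below][np.argmax(profile.density[~below])]
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# block merging and summaries


def merge_blocks(window_table: pd.DataFrame, pet: float) -> list[HaplotypeBlock]:
    """Merge maximal runs of contiguous windows with OSD >= PET into blocks.

    Adjacent means same chromosome and the end of one window equals the
    start of the next.  Windows with undefined OSD (unusable) break runs.
    The input must be sorted by chromosome then start, as produced by
    :func:`compute_osd`.
    """
    _check_sorted(window_table)
    blocks: list[HaplotypeBlock] = []
    cur: HaplotypeBlock | None = None
    for row in window_table.itertuples(index=False):
        above = np.isfinite(row.osd) and row.osd >= pet
        if (cur is not None and above and row.chrom == cur.chrom
                and row.start == cur.end):
            cur.end = row.end
            cur.n_windows += 1
            cur.snv_count += int(row.snv_count)
            cur.mean_osd += row.osd
            cur.contains_partial |= bool(row.partial)
        elif above:
            cur = HaplotypeBlock(row.chrom, int(row.start), int(row.end), 1,
                                 int(row.snv_count), float(row.osd),
                                 bool(row.partial))
            blocks.append(cur)
        else:
            cur = None
    for b in blocks:
        b.mean_osd /= b.n_windows
    return blocks


def _check_sorted(window_table: pd.DataFrame) -> None:
    seen: list[str] = []
    for chrom, sub in window_table.groupby("chrom", sort=False):
        if chrom in seen:
            raise ValueError("window table not sorted: chromosome "
                             f"{chrom!r} appears in two runs")
        seen.append(chrom)
        starts = sub["start"].to_numpy()
        if len(starts) > 1 and (np.diff(starts) <= 0).any():
            raise ValueError(f"window table not sorted within {chrom!r}")


def blocks_to_frame(blocks: Sequence[HaplotypeBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [(b.chrom, b.start, b.end, b.length, b.n_windows, b.snv_count,
          b.mean_osd, b.contains_partial) for b in blocks],
        columns=["chrom", "start", "end", "length", "n_windows",
                 "snv_count", "mean_osd", "contains_partial"])


def _sites_in_blocks(variants: Sequence[VariantSite],
                     blocks: Sequence[HaplotypeBlock]) -> int:
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom in {b.chrom for b in blocks}:
        bs = sorted((b.start, b.end) for b in blocks if b.chrom == chrom)
        starts[chrom] = np.array([s for s, _ in bs])
        ends[chrom] = np.array([e for _, e in bs])
    n = 0
    for v in variants:
        if v.chrom not in starts:
            continue
        i = np.searchsorted(starts[v.chrom], v.start, side="right") - 1
        if i >= 0 and v.start < ends[v.chrom][i]:
            n += 1
    return n


def summarize_comparison(window_table: pd.DataFrame,
                         blocks: Sequence[HaplotypeBlock],
                         variants: Sequence[VariantSite],
                         pet: float | None,
                         exclude_partial_from_lengths: bool = True,
                         ) -> ComparisonSummary:
    """Summary statistics for one strain-pair comparison.

    Percentages are 100x the ratio of their count fields; the two regime
    means are arithmetic means of window OSD on each side of the PET.
    Blocks containing a trailing partial window are excluded from the
    block-length mean/SD by default (their length is not a whole number of
    windows).  ``pet=None`` denotes the unimodal (no-valley) case: no
    windows are classified above and there are no blocks.
    """
    n_windows = len(window_table)
    osd = window_table["osd"].to_numpy()
    defined = np.isfinite(osd)
    if pet is None:
        n_above = 0
        mean_below = float(np.nanmean(osd)) if defined.any() else math.nan
        mean_above = math.nan
        blocks = []
    else:
        above = defined & (osd >= pet)
        n_above = int(above.sum())
        below = defined & (osd < pet)
        mean_below = float(osd[below].mean()) if below.any() else math.nan
        mean_above = float(osd[above].mean()) if above.any() else math.nan

    lengths = [b.length for b in blocks
               if not (exclude_partial_from_lengths and b.contains_partial)]
    mean_len = float(np.mean(lengths)) if lengths else math.nan
    sd_len = float(np.std(lengths, ddof=1)) if len(lengths) > 1 else math.nan

    n_total = len(variants)
    n_in = _sites_in_blocks(variants, blocks) if blocks else 0
    return ComparisonSummary(
        pet=pet,
        n_windows=n_windows,
        n_windows_above=n_above,
        pct_windows_above=100.0 * n_above / n_windows if n_windows else 0.0,
        n_blocks=len(blocks),
        mean_block_length=mean_len,
        sd_block_length=sd_len,
        mean_osd_below=mean_below,
        mean_osd_above=mean_above,
        n_snps_total=n_total,
        n_snps_in_blocks=n_in,
        pct_snps_in_blocks=100.0 * n_in / n_total if n_total else 0.0,
        unimodal=pet is None,
    )
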