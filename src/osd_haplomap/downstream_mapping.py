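"""QTL fine-mapping and candidate-variant prioritisation.

Divergent haplotype blocks mark the only regions where two inbred strains
carry different ancestral haplotypes, so any QTL mapped in a cross between
them can be narrowed to its intersection with the blocks.  Candidate
variants inside the narrowed intervals are filtered by predicted
consequence class and tested for enrichment of the carrier allele among
phenotype-grouped strains of a sequenced panel with a two-tailed Fisher's
exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .genomic_io import IntervalSet, VariantSite, overlap_bp
from .osd_core import HaplotypeBlock

__all__ = [
    "QTLSet",
    "PanelGenotypes",
    "StrainPanel",
    "EnrichmentResult",
    "CONSEQUENCE_VOCABULARY",
    "read_qtl",
    "intersect_qtl",
    "panel_blocks",
    "compare_blocksets",
    "read_annotation_table",
    "annotate_variants",
    "filter_consequences",
    "fisher_exact_two_tailed",
    "fisher_enrichment",
    "enrich_many",
    "mets_phenotype_groups",
]

# consequence-class vocabulary: class label -> predictor output terms
CONSEQUENCE_VOCABULARY: dict[str, frozenset[str]] = {
    "non_synonymous": frozenset({"NON_SYNONYMOUS_CODING"}),
    "splice_site": frozenset({"SPLICE_SITE", "ESSENTIAL_SPLICE_SITE"}),
    "frameshift": frozenset({"FRAMESHIFT_CODING"}),
    "stop_gained": frozenset({"STOP_GAINED"}),
}

#: tie tolerance when summing tables as extreme as the observed one;
#: guards against floating-point near-ties in the hypergeometric pmf
_FISHER_TIE_RELTOL = 1e-7


@dataclass
class QTLSet:
    """QTL intervals with trait labels (0-based half-open)."""

    intervals: IntervalSet

    @classmethod
    def from_tsv(cls, path: str | Path) -> "QTLSet":
        return cls(IntervalSet.from_bed(path))

    def __len__(self) -> int:
        return len(self.intervals)


def read_qtl(path: str | Path) -> QTLSet:
    """Read QTL intervals from a BED-like TSV (chrom, start, end, trait)."""
    return QTLSet.from_tsv(path)


@dataclass
class PanelGenotypes:
    """Genotyping-panel SNP alleles: one row per SNP, one column per strain.

    ``table`` columns: chrom, pos (1-based), then strain columns holding
    single-letter alleles ('N', '-' or empty = missing).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if not {"chrom", "pos"} <= set(t.columns):
            raise ValueError("panel table needs 'chrom' and 'pos' columns")
        for chrom, sub in t.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if len(pos) > 1 and (np.diff(pos) <= 0).any():
                raise ValueError(
                    f"panel positions not strictly increasing on {chrom!r}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PanelGenotypes":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}))

    @property
    def strains(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("chrom", "pos")]


@dataclass
class StrainPanel:
    """A sequenced strain panel with phenotype groupings and exclusions.

    ``exclusions`` are removed from both the panel and every group before
    any enrichment table is built (e.g. reference-identical substrains, or
    strains with confounding phenotypes).
    """

    strains: tuple[str, ...]
    phenotype_groups: dict[str, frozenset[str]]
    exclusions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        members = set().union(*self.phenotype_groups.values()) \
            if self.phenotype_groups else set()
        unknown = members - set(self.strains)
        if unknown:
            raise ValueError(f"group members not in panel: {sorted(unknown)}")

    def effective_strains(self) -> tuple[str, ...]:
        return tuple(s for s in self.strains if s not in self.exclusions)

    def group(self, name: str) -> frozenset[str]:
        if name not in self.phenotype_groups:
            raise KeyError(
                f"unknown group {name!r}; have {sorted(self.phenotype_groups)}")
        return self.phenotype_groups[name] - self.exclusions


def mets_phenotype_groups() -> dict[str, frozenset[str]]:
    """Standard metabolic-syndrome phenotype groupings of inbred rat strains."""
    return {
        "obese": frozenset({"LH", "SBH", "SS", "SHR", "LL", "LEW"}),
        "dyslipidemic": frozenset({"LH", "SS", "SHR"}),
        "hypertensive": frozenset(
            {"LH", "FHH", "MHS", "SBH", "SHR", "SHRSP", "SS"}),
    }


@dataclass
class EnrichmentResult:
    """A 2x2 carrier-by-group table and its two-tailed exact p-value."""

    variant_id: str
    group: str
    table: tuple[tuple[int, int], tuple[int, int]]
    p_two_tailed: float
    n_excluded_calls: int = 0


# ---------------------------------------------------------------------------
# QTL intersection


def intersect_qtl(blocks: Sequence[HaplotypeBlock] | IntervalSet,
                  qtl: QTLSet) -> dict:
    """Overlap divergent haplotype blocks with QTL intervals.

    Returns a dict with ``per_qtl`` (DataFrame: one row per QTL interval
    with covered bp, % covered, % narrowing and the overlapping block
    list) and genome-wide totals computed on the *union* of the QTL
    intervals (overlapping QTL are merged so shared bases count once).
    """
    if isinstance(blocks, IntervalSet):
        block_set = blocks
    else:
        block_set = IntervalSet.from_tuples(
            [(b.chrom, b.start, b.end) for b in blocks])
    block_by_chrom = block_set.merged().by_chrom()

    rows = []
    for q in qtl.intervals.df.itertuples(index=False):
        covered = 0
        hits = []
        if q.chrom in block_by_chrom:
            bs, be = block_by_chrom[q.chrom]
            ov = np.clip(np.minimum(be, q.end) - np.maximum(bs, q.start),
                         0, None)
            covered = int(ov.sum())
            hits = [(int(s), int(e)) for s, e, o in zip(bs, be, ov) if o > 0]
        qtl_bp = int(q.end - q.start)
        pct_cov = 100.0 * covered / qtl_bp
        rows.append((q.chrom, q.start, q.end, q.label, qtl_bp, covered,
                     pct_cov, 100.0 - pct_cov, hits))
    per_qtl = pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "trait", "qtl_bp", "covered_bp",
        "pct_covered", "pct_narrowing", "blocks"])

    total_bp = qtl.intervals.total_bp()
    covered_bp = overlap_bp(qtl.intervals, block_set)
    pct_covered = 100.0 * covered_bp / total_bp if total_bp else 0.0
    return {
        "per_qtl": per_qtl,
        "total_qtl_bp": total_bp,
        "covered_bp": covered_bp,
        "pct_covered": pct_covered,
        "pct_narrowing": 100.0 - pct_covered if total_bp else 0.0,
    }


# ---------------------------------------------------------------------------
# genotyping-panel blocks


def panel_blocks(panel: PanelGenotypes, strain_pair: tuple[str, str],
                 chrom_sizes: Mapping[str, int] | None = None,
                 ) -> list[tuple[str, int, int]]:
    """Haplotype blocks implied by a genotyping panel for one strain pair.

    Each maximal run of SNPs polymorphic between the pair yields one block
    spanning from the nearest flanking monomorphic SNP on the left to the
    nearest on the right; a run at a chromosome edge uses the chromosome
    bound (or the run's own edge SNP if no sizes are given) on the missing
    side.  SNPs with a missing call in either strain are uninformative and
    are ignored.  Returned intervals are 0-based half-open.
    """
    a, b = strain_pair
    for s in (a, b):
        if s not in panel.strains:
            raise ValueError(f"strain {s!r} not in panel; have {panel.strains}")
    blocks: list[tuple[str, int, int]] = []
    missing = {"", "N", "-", None}
    for chrom, sub in panel.table.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        ga = sub[a].astype(str).str.upper().to_numpy()
        gb = sub[b].astype(str).str.upper().to_numpy()
        informative = ~(np.isin(ga, list(missing)) | np.isin(gb, list(missing)))
        pos, ga, gb = pos[informative], ga[informative], gb[informative]
        poly = ga != gb
        left_bound = 0
        right_default = (int(chrom_sizes[chrom]) if chrom_sizes and
                         chrom in chrom_sizes else None)
        i = 0
        n = len(pos)
        while i < n:
            if not poly[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and poly[j + 1]:
                j += 1
            left = int(pos[i - 1]) - 1 if i > 0 else left_bound
            if j + 1 < n:
                right = int(pos[j + 1])  # 1-based mono SNP -> half-open end
            else:
                right = right_default if right_default is not None else int(pos[j])
            blocks.append((str(chrom), left, right))
            i = j + 1
    return blocks


def compare_blocksets(osd_blocks: Sequence[HaplotypeBlock],
                      geno_blocks: Sequence[tuple[str, int, int]],
                      ) -> pd.DataFrame:
    """Classify each OSD block against genotyping-panel blocks.

    Labels: ``novel`` (no overlapping panel block), ``refined`` (strictly
    inside a longer panel block), ``extended`` (reaches beyond its best
    panel partner on at least one side), ``concordant`` (same span as the
    partner).  The partner is the panel block with the largest overlap.
    """
    rows = []
    for blk in osd_blocks:
        partner = None
        best_ov = 0
        for chrom, s, e in geno_blocks:
            if chrom != blk.chrom:
                continue
            ov = min(e, blk.end) - max(s, blk.start)
            if ov > best_ov:
                best_ov = ov
                partner = (s, e)
        if partner is None:
            label = "novel"
        elif blk.start > partner[0] and blk.end < partner[1]:
            label = "refined"
        elif blk.start < partner[0] or blk.end > partner[1]:
            label = "extended"
        else:
            label = "concordant"
        rows.append((blk.chrom, blk.start, blk.end, label,
                     partner[0] if partner else pd.NA,
                     partner[1] if partner else pd.NA))
    return pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "label", "partner_start", "partner_end"])


# ---------------------------------------------------------------------------
# consequence filtering


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read a variant-consequence table (chrom, pos, alt, consequences,
    damage_class); ``consequences`` is a comma/ampersand-separated term list."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "consequences"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation table needs columns {sorted(required)}")
    return df


def annotate_variants(variants: Sequence[VariantSite],
                      annotations: pd.DataFrame) -> list[VariantSite]:
    """Attach consequence terms / damage class to matching variants in place."""
    key_cols = ["chrom", "pos"] + (["alt"] if "alt" in annotations else [])
    index: dict[tuple, tuple] = {}
    for row in annotations.itertuples(index=False):
        terms = tuple(t for t in str(row.consequences).replace("&", ",").split(",")
                      if t and t != "nan")
        damage = getattr(row, "damage_class", None)
        key = tuple(getattr(row, c) for c in key_cols)
        index[key] = (terms, damage if isinstance(damage, str) else None)
    for v in variants:
        key = tuple(getattr(v, c) for c in key_cols)
        if key in index:
            v.consequences, v.damage_class = index[key]
    return list(variants)


def filter_consequences(variants: Sequence[VariantSite],
                        wanted_classes: Iterable[str]) -> list[VariantSite]:
    """Keep variants whose annotation contains a term of a wanted class.

    ``wanted_classes`` are class labels from :data:`CONSEQUENCE_VOCABULARY`
    (``non_synonymous``, ``splice_site``, ``frameshift``, ``stop_gained``).
    Retained variants get all matching class labels attached
    (``consequence_classes``); a variant annotated with terms of several
    wanted classes is kept once with every label.
    """
    wanted = list(wanted_classes)
    unknown = [c for c in wanted if c not in CONSEQUENCE_VOCABULARY]
    if unknown:
        raise ValueError(
            f"unknown consequence class(es) {unknown}; vocabulary: "
            f"{ {k: sorted(v) for k, v in CONSEQUENCE_VOCABULARY.items()} }")
    out = []
    for v in variants:
        terms = set(v.consequences or ())
        labels = tuple(c for c in wanted if terms & CONSEQUENCE_VOCABULARY[c])
        if labels:
            v.consequence_classes = labels
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# Fisher's exact test


def _two_tailed_from_pmf(pmf: np.ndarray, observed_idx: int) -> float:
    p_obs = pmf[observed_idx]
    p = pmf[pmf <= p_obs * (1.0 + _FISHER_TIE_RELTOL)].sum()
    return float(min(p, 1.0))


def fisher_exact_two_tailed(table: Sequence[Sequence[int]]) -> float:
    """Two-tailed Fisher's exact p for a 2x2 table.

    Convention: the sum of the hypergeometric probabilities of all tables
    with the same margins whose point probability is at most that of the
    observed table (with a 1e-7 relative tie tolerance against floating-
    point near-ties).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    n_total = a + b + c + d
    if n_total == 0:
        return 1.0
    row1 = a + b
    col1 = a + c
    kmin = max(0, col1 - (c + d))
    kmax = min(row1, col1)
    support = np.arange(kmin, kmax + 1)
    pmf = hypergeom.pmf(support, n_total, row1, col1)
    return _two_tailed_from_pmf(pmf, a - kmin)


def fisher_enrichment(carrier_strains: Iterable[str], panel: StrainPanel,
                      group_name: str, variant_id: str = "",
                      uncalled_strains: Iterable[str] = (),
                      ) -> EnrichmentResult:
    """Test carrier-allele enrichment in one phenotype group.

    Carrier status means homozygous for the minor allele at the variant;
    strains with heterozygous or missing calls there (``uncalled_strains``)
    are excluded from the table and counted.  The 2x2 table is
    carrier/non-carrier x in-group/out-group over the panel after
    exclusions.
    """
    group = panel.group(group_name)
    if not group:
        raise ValueError(f"group {group_name!r} is empty after exclusions")
    uncalled = set(uncalled_strains)
    effective = [s for s in panel.effective_strains() if s not in uncalled]
    carriers = set(carrier_strains) - panel.exclusions - uncalled
    stray = carriers - set(effective)
    if stray:
        raise ValueError(f"carrier strains not in panel: {sorted(stray)}")
    a = sum(1 for s in effective if s in carriers and s in group)
    b = sum(1 for s in effective if s in carriers and s not in group)
    c = sum(1 for s in effective if s not in carriers and s in group)
    d = sum(1 for s in effective if s not in carriers and s not in group)
    table = ((a, b), (c, d))
    return EnrichmentResult(
        variant_id=variant_id, group=group_name, table=table,
        p_two_tailed=fisher_exact_two_tailed(table),
        n_excluded_calls=len(uncalled & set(panel.effective_strains())))


def enrich_many(carriers_by_variant: Mapping[str, Iterable[str]],
                panel: StrainPanel, group_names: Iterable[str] | None = None,
                fdr: bool = False) -> pd.DataFrame:
    """Enrichment of every variant in every phenotype group.

    Raw two-tailed p-values by default; ``fdr=True`` adds a
    Benjamini-Hochberg adjusted column.
    """
    groups = list(group_names or panel.phenotype_groups)
    rows = []
    for vid, carriers in carriers_by_variant.items():
        carriers = list(carriers)
        for g in groups:
            r = fisher_enrichment(carriers, panel, g, variant_id=vid)
            (a, b), (c, d) = r.table
            rows.append((vid, g, a, b, c, d, r.p_two_tailed))
    df = pd.DataFrame(rows, columns=["variant", "group", "a", "b", "c", "d",
                                     "p_two_tailed"])
    if fdr and len(df):
        from statsmodels.stats.multitest import multipletests
        df["p_bh"] = multipletests(df["p_two_tailed"], method="fdr_bh")[1]
    return df
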