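"""QTL intersection, panel blocks, consequence filtering, Fisher enrichment."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact

from osd_haplomap.downstream_mapping import (CONSEQUENCE_VOCABULARY,
                                             PanelGenotypes, QTLSet,
                                             StrainPanel, compare_blocksets,
                                             enrich_many, fisher_enrichment,
                                             fisher_exact_two_tailed,
                                             filter_consequences,
                                             intersect_qtl,
                                             mets_phenotype_groups,
                                             panel_blocks)
from osd_haplomap.genomic_io import IntervalSet, VariantSite
from osd_haplomap.osd_core import HaplotypeBlock


def _block(chrom, start, end):
    n = max(1, (end - start) // 100_000)
    return HaplotypeBlock(chrom, start, end, n, 0, 1e-3)


def _qtl(tuples):
    return QTLSet(IntervalSet.from_tuples(tuples))


# ---------------------------------------------------------------------------
# QTL intersection


def test_intersect_qtl_interval_arithmetic():
    """QTL [10,20) Mb against blocks [12,13) and [19,21) -> 2 Mb, 80% narrowing."""
    blocks = [_block("c", 12_000_000, 13_000_000),
              _block("c", 19_000_000, 21_000_000)]
    rep = intersect_qtl(blocks, _qtl([("c", 10_000_000, 20_000_000, "bp")]))
    row = rep["per_qtl"].iloc[0]
    assert row.covered_bp == 2_000_000
    assert row.pct_narrowing == pytest.approx(80.0)
    assert rep["pct_narrowing"] == pytest.approx(80.0)
    assert row.blocks == [(12_000_000, 13_000_000), (19_000_000, 21_000_000)]


def test_intersect_qtl_disjoint_chromosomes():
    rep = intersect_qtl([_block("a", 0, 1_000_000)], _qtl([("b", 0, 2_000_000, "t")]))
    assert rep["covered_bp"] == 0
    assert rep["pct_narrowing"] == pytest.approx(100.0)


def test_intersect_qtl_union_semantics():
    """Overlapping QTL count shared bases once in the genome-wide total."""
    blocks = [_block("c", 0, 1_000_000)]
    rep = intersect_qtl(blocks, _qtl([("c", 0, 2_000_000, "t1"),
                                      ("c", 1_000_000, 3_000_000, "t2")]))
    assert rep["total_qtl_bp"] == 3_000_000
    assert rep["covered_bp"] == 1_000_000


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_intersect_qtl_perbase_oracle(seed):
    """Randomized intervals on a 10-Mb toy equal a boolean-array oracle."""
    rng = np.random.default_rng(seed)
    L = 10_000_000

    def rand_intervals(n, max_len):
        s = rng.integers(0, L - max_len, n)
        ln = rng.integers(1, max_len, n)
        return [("c", int(a), int(a + b)) for a, b in zip(s, ln)]

    qtl_t = rand_intervals(8, 2_000_000)
    blk_t = rand_intervals(30, 400_000)
    rep = intersect_qtl(IntervalSet.from_tuples(blk_t),
                        _qtl([(c, s, e, "t") for c, s, e in qtl_t]))
    qmask = np.zeros(L, dtype=bool)
    bmask = np.zeros(L, dtype=bool)
    for _, s, e in qtl_t:
        qmask[s:e] = True
    for _, s, e in blk_t:
        bmask[s:e] = True
    assert rep["total_qtl_bp"] == int(qmask.sum())
    assert rep["covered_bp"] == int((qmask & bmask).sum())
    # bp symmetry: summing per-QTL overlap over merged QTL = genome-wide overlap
    merged_qtl = IntervalSet.from_tuples(qtl_t).merged()
    rep2 = intersect_qtl(IntervalSet.from_tuples(blk_t),
                         QTLSet(merged_qtl))
    assert int(rep2["per_qtl"]["covered_bp"].sum()) == rep["covered_bp"]


# ---------------------------------------------------------------------------
# genotyping-panel blocks


def _panel(rows, strains=("LH", "LN")):
    return PanelGenotypes(pd.DataFrame(rows, columns=["chrom", "pos", *strains]))


def test_panel_block_between_flanking_monomorphic_snps():
    panel = _panel([
        ("17", 29_700_000, "A", "A"),
        ("17", 29_900_000, "A", "G"),
        ("17", 30_000_000, "C", "T"),
        ("17", 30_200_000, "T", "T"),
    ])
    blocks = panel_blocks(panel, ("LH", "LN"))
    assert blocks == [("17", 29_699_999, 30_200_000)]


def test_panel_blocks_all_monomorphic_and_edges():
    assert panel_blocks(_panel([("1", 10, "A", "A"), ("1", 20, "C", "C")]),
                        ("LH", "LN")) == []
    # polymorphic run at both chromosome edges uses the chromosome bounds
    panel = _panel([("1", 10, "A", "G"), ("1", 20, "C", "C"),
                    ("1", 30, "A", "T")])
    blocks = panel_blocks(panel, ("LH", "LN"), chrom_sizes={"1": 100})
    assert blocks == [("1", 0, 20), ("1", 19, 100)]


def test_panel_blocks_missing_calls_ignored():
    panel = _panel([("1", 10, "A", "A"), ("1", 20, "N", "G"),
                    ("1", 30, "A", "G"), ("1", 40, "C", "C")])
    assert panel_blocks(panel, ("LH", "LN")) == [("1", 9, 40)]


@pytest.mark.parametrize("seed", [0, 1])
def test_panel_blocks_run_length_oracle(seed):
    """Alternating patterns match a brute-force run-length scan."""
    rng = np.random.default_rng(seed)
    n = 60
    pos = np.sort(rng.choice(np.arange(1, 10_000), n, replace=False))
    poly = rng.random(n) < 0.4
    rows = [("2", int(p), "A", "G" if q else "A") for p, q in zip(pos, poly)]
    got = panel_blocks(_panel(rows), ("LH", "LN"), chrom_sizes={"2": 10_000})

    runs = []
    i = 0
    while i < n:
        if poly[i]:
            j = i
            while j + 1 < n and poly[j + 1]:
                j += 1
            left = int(pos[i - 1]) - 1 if i > 0 else 0
            right = int(pos[j + 1]) if j + 1 < n else 10_000
            runs.append(("2", left, right))
            i = j + 1
        else:
            i += 1
    assert got == runs
    # a run of polymorphic SNPs is never split across two blocks
    starts = np.array([s for _, s, _ in got])
    ends = np.array([e for _, _, e in got])
    for p, q in zip(pos, poly):
        if q:
            assert (((starts < p) & (p <= ends)).sum()) == 1


# ---------------------------------------------------------------------------
# OSD vs genotyping block comparison


def test_compare_blocksets_labels():
    geno = [("17", 38_200_000, 39_800_000), ("17", 42_200_000, 43_200_000)]
    osd = [_block("17", 53_400_000, 53_800_000),   # no overlap -> novel
           _block("17", 39_400_000, 39_600_000),   # strictly inside -> refined
           _block("17", 41_700_000, 43_100_000),   # extends 5' end -> extended
           _block("17", 42_200_000, 43_200_000)]   # identical -> concordant
    labels = compare_blocksets(osd, geno)["label"].tolist()
    assert labels == ["novel", "refined", "extended", "concordant"]


# ---------------------------------------------------------------------------
# consequence filtering


def _annotated(terms, pos=100):
    return VariantSite("17", pos, "G", "T",
                       {"LH": "hom_alt", "LN": "hom_ref"},
                       consequences=tuple(terms))


def test_filter_consequences_vocabulary():
    variants = [
        _annotated(["NON_SYNONYMOUS_CODING"], 1),
        _annotated(["SYNONYMOUS_CODING"], 2),
        _annotated(["NON_SYNONYMOUS_CODING", "SPLICE_SITE"], 3),
        _annotated(["ESSENTIAL_SPLICE_SITE"], 4),
        _annotated(["FRAMESHIFT_CODING"], 5),
        _annotated([], 6),
    ]
    kept = filter_consequences(variants, ["non_synonymous", "splice_site"])
    assert [v.pos for v in kept] == [1, 3, 4]
    assert kept[1].consequence_classes == ("non_synonymous", "splice_site")
    kept = filter_consequences(variants, ["frameshift"])
    assert [v.pos for v in kept] == [5]


def test_filter_consequences_unknown_class_lists_vocabulary():
    with pytest.raises(ValueError, match="NON_SYNONYMOUS_CODING"):
        filter_consequences([], ["nonsense_mediated_decay"])
    assert set(CONSEQUENCE_VOCABULARY) == {
        "non_synonymous", "splice_site", "frameshift", "stop_gained"}


# ---------------------------------------------------------------------------
# Fisher's exact test


def _enumeration_p(a, b, c, d, tie=1e-7):
    """Exact-integer enumeration over all tables with the observed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    den = comb(r1 + r2, c1)
    support = range(max(0, c1 - r2), min(r1, c1) + 1)
    nums = {k: comb(r1, k) * comb(r2, c1 - k) for k in support}
    return min(1.0, sum(v for v in nums.values()
                        if v <= nums[a] * (1 + tie)) / den)


@pytest.mark.parametrize("table", [
    ((3, 4), (0, 21)),
    ((5, 0), (0, 7)),      # diagonal table
    ((2, 2), (2, 2)),
    ((0, 0), (3, 25)),     # zero carriers anywhere
    ((10, 2), (3, 9)),
    ((1, 0), (0, 1)),
])
def test_fisher_matches_enumeration(table):
    (a, b), (c, d) = table
    got = fisher_exact_two_tailed(table)
    assert got == pytest.approx(_enumeration_p(a, b, c, d), abs=1e-12)


def test_fisher_zero_carriers_is_one():
    assert fisher_exact_two_tailed(((0, 0), (7, 21))) == 1.0


@settings(deadline=None, max_examples=200, derandomize=True)
@given(st.tuples(*[st.integers(min_value=0, max_value=25)] * 4))
def test_fisher_matches_scipy(cells):
    a, b, c, d = cells
    got = fisher_exact_two_tailed(((a, b), (c, d)))
    want = fisher_exact([[a, b], [c, d]])[1]
    assert got == pytest.approx(want, rel=1e-9, abs=1e-12)


def test_fisher_enrichment_builds_table_after_exclusions():
    strains = ("LH", "SS", "SHR", "LN", "LL", "BN", "BN-Lx", "BBDP/Rhw",
               "FHH", "LEW")
    panel = StrainPanel(
        strains=strains,
        phenotype_groups={"dyslipidemic": frozenset({"LH", "SS", "SHR"})},
        exclusions=frozenset({"BN", "BN-Lx", "BBDP/Rhw"}))
    res = fisher_enrichment(["LH", "SS", "SHR"], panel, "dyslipidemic",
                            variant_id="17:G65701876T")
    (a, b), (c, d) = res.table
    assert (a, b, c, d) == (3, 0, 0, 4)
    assert a + b + c + d == len(panel.effective_strains())
    assert res.p_two_tailed == pytest.approx(_enumeration_p(3, 0, 0, 4))


def test_fisher_enrichment_empty_group_errors():
    panel = StrainPanel(strains=("A", "B"), phenotype_groups={"g": frozenset({"A"})},
                        exclusions=frozenset({"A"}))
    with pytest.raises(ValueError, match="empty"):
        fisher_enrichment([], panel, "g")


def test_enrich_many_with_fdr():
    groups = {"hypertensive": mets_phenotype_groups()["hypertensive"]}
    strains = tuple(sorted(groups["hypertensive"])) + ("LN", "WKY")
    panel = StrainPanel(strains=strains, phenotype_groups=groups)
    df = enrich_many({"v1": ["LH", "SS"], "v2": ["LN"]}, panel,
                     ["hypertensive"], fdr=True)
    assert set(df["variant"]) == {"v1", "v2"}
    assert ((0 <= df["p_two_tailed"]) & (df["p_two_tailed"] <= 1)).all()
    assert (df["p_bh"] >= df["p_two_tailed"] - 1e-15).all()
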