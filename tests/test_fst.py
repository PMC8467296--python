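"""Weir–Cockerham estimator, window tiling, and their invariants."""

import math

import numpy as np
import pandas as pd
import pytest

from coldrank.errors import DegenerateSampleError, InvalidConfigError, MissingWindowError
from coldrank.fst import (
    SiteGroupCounts,
    WindowFst,
    site_fst,
    site_group_counts,
    snp_window_value,
    window_starts,
    windowed_fst,
)
from coldrank.io import VariantRecord

from conftest import SAMPLES


def naive_wc84_theta(n1, p1, h1, n2, p2, h2):
    """Independent, literal transcription of the two-population
    Weir–Cockerham (1984) variance components. Test oracle only."""
    r = 2
    n = [n1, n2]
    p = [p1, p2]
    h = [h1, h2]
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni * ni for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    denom = a + b + c
    return (a, b, c, a / denom if denom != 0 else math.nan)


def random_counts(rng):
    """A random but internally consistent SiteGroupCounts (genotype counts
    drawn first, so h ≤ 2·min(p, 1−p) automatically holds)."""
    vals = []
    for _ in range(2):
        n = int(rng.integers(2, 21))
        counts = rng.multinomial(n, [1 / 3, 1 / 3, 1 / 3])  # hom-ref, het, hom-alt
        p = (2 * counts[0] + counts[1]) / (2 * n)
        h = counts[1] / n
        vals.extend([n, p, h])
    return SiteGroupCounts(*vals)


@pytest.mark.parametrize(
    "counts, expect_a, expect_theta",
    [
        (SiteGroupCounts(6, 1.0, 0.0, 6, 0.0, 0.0), 0.5, 1.0),  # fixed difference
        (SiteGroupCounts(6, 1.0, 0.0, 6, 0.5, 0.0), 0.1, 0.4),  # hand-derived
        (SiteGroupCounts(6, 0.5, 1.0, 6, 0.5, 1.0), 0.0, 0.0),  # no between-group var
    ],
)
def test_site_fst_hand_cases(counts, expect_a, expect_theta):
    comp = site_fst(counts)
    assert comp.a == pytest.approx(expect_a, abs=1e-12)
    assert comp.theta == pytest.approx(expect_theta, abs=1e-12)


def test_site_fst_matches_naive_transcription():
    rng = np.random.default_rng(20240601)
    checked = 0
    for _ in range(1000):
        counts = random_counts(rng)
        comp = site_fst(counts)
        a, b, c, theta = naive_wc84_theta(
            counts.n1, counts.p1, counts.h1, counts.n2, counts.p2, counts.h2
        )
        assert comp.a == pytest.approx(a, abs=1e-12)
        assert comp.b == pytest.approx(b, abs=1e-12)
        assert comp.c == pytest.approx(c, abs=1e-12)
        if math.isnan(theta):
            assert not comp.defined
        else:
            assert comp.theta == pytest.approx(theta, abs=1e-12)
            checked += 1
    assert checked > 900  # almost all random sites are polymorphic


def test_group_label_permutation_leaves_theta_unchanged():
    rng = np.random.default_rng(7)
    for _ in range(50):
        c = random_counts(rng)
        swapped = SiteGroupCounts(c.n2, c.p2, c.h2, c.n1, c.p1, c.h1)
        t1, t2 = site_fst(c).theta, site_fst(swapped).theta
        assert (math.isnan(t1) and math.isnan(t2)) or t1 == pytest.approx(
            t2, abs=1e-12
        )


def test_monomorphic_site_has_undefined_theta():
    comp = site_fst(SiteGroupCounts(6, 1.0, 0.0, 6, 1.0, 0.0))
    assert not comp.defined
    assert comp.denom == 0.0


def test_negative_theta_is_preserved():
    # identical compositions with heterozygotes: a ≤ 0, θ may dip below 0
    comp = site_fst(SiteGroupCounts(6, 0.5, 0.5, 6, 0.5, 0.5))
    assert comp.a <= 0.0
    assert comp.theta <= 0.0


def test_degenerate_sample_sizes_rejected():
    with pytest.raises(DegenerateSampleError):
        site_fst(SiteGroupCounts(1, 1.0, 0.0, 1, 0.0, 0.0))


def _record(genotypes, chrom="1", pos=1000):
    return VariantRecord(
        chrom=chrom, pos=pos, ref="A", alts=("G",),
        genotypes=genotypes, samples=SAMPLES,
    )


def test_site_group_counts_counting(groups12):
    # sensitive group (S00..S05): five 0/0 and one 0/1; tolerant all 0/0
    gts = [(0, 0)] * 5 + [(0, 1)] + [(0, 0)] * 6
    c = site_group_counts(_record(gts), groups12)
    assert (c.n1, c.h1) == (6, 1 / 6)
    assert c.p1 == pytest.approx(11 / 12)
    assert (c.n2, c.p2, c.h2) == (6, 1.0, 0.0)


def test_site_group_counts_skips_missing(groups12):
    gts = [None] + [(0, 0)] * 5 + [(0, 0)] * 6
    c = site_group_counts(_record(gts), groups12)
    assert (c.n1, c.p1, c.h1) == (5, 1.0, 0.0)


def test_site_group_counts_reported_candidate_frequencies(groups12):
    # constructed like a candidate locus printed as 0.08 vs 0.80:
    # sensitive: one het + five hom-alt (p = 1/12); tolerant: one missing,
    # three hom-ref + two het over 5 called (p = 8/10)
    gts = (
        [(0, 1)] + [(1, 1)] * 5
        + [None, (0, 0), (0, 0), (0, 0), (0, 1), (0, 1)]
    )
    c = site_group_counts(_record(gts), groups12)
    assert round(c.p1, 2) == 0.08
    assert round(c.p2, 2) == 0.80


def test_fully_missing_group_raises(groups12):
    gts = [None] * 6 + [(0, 0)] * 6
    with pytest.raises(DegenerateSampleError):
        site_group_counts(_record(gts), groups12)


# ---------------------------------------------------------------------------
# windows


def test_window_membership_interior_and_edge():
    assert window_starts(30_000, 50_000, 25_000) == [1, 25_001]
    assert window_starts(10_000, 50_000, 25_000) == [1]


def test_windowed_weighted_fst_ratio_of_sums():
    # two co-windowed sites (a=0.5, d=0.5) and (a=0, d=0.25): Σa/Σd = 2/3
    sites = pd.DataFrame(
        {
            "chrom": ["1", "1", "1"],
            "pos": [10_000, 12_000, 60_000],
            "a": [0.5, 0.0, 0.2],
            "b": [0.0, 0.125, 0.0],
            "c": [0.0, 0.125, 0.2],
            "theta": [1.0, 0.0, 0.5],
        }
    )
    windows = windowed_fst(sites)
    w1 = [w for w in windows if w.start == 1][0]
    assert w1.n_sites == 2
    assert w1.weighted_theta == pytest.approx(0.5 / 0.75)
    assert w1.mean_theta == pytest.approx(0.5)
    # the site at 60 kb belongs to the [25001, 75000] and [50001, 100000] tiles
    covering = [w for w in windows if w.start <= 60_000 <= w.end]
    assert {w.start for w in covering} == {25_001, 50_001}
    for w in covering:
        assert w.weighted_theta == pytest.approx(0.5)


def test_single_site_window_equals_site_theta():
    sites = pd.DataFrame(
        {"chrom": ["2"], "pos": [70_000], "a": [0.3], "b": [0.1], "c": [0.2],
         "theta": [0.5]}
    )
    for w in windowed_fst(sites):
        assert w.weighted_theta == pytest.approx(0.5)
        assert w.n_sites == 1


def test_undefined_sites_excluded_from_windows():
    sites = pd.DataFrame(
        {"chrom": ["1", "1"], "pos": [1000, 2000], "a": [0.5, 0.0],
         "b": [0.0, 0.0], "c": [0.0, 0.0], "theta": [1.0, float("nan")]}
    )
    windows = windowed_fst(sites)
    assert all(w.n_sites == 1 for w in windows)


def test_step_larger_than_window_rejected():
    with pytest.raises(InvalidConfigError):
        windowed_fst(pd.DataFrame(columns=["chrom", "pos", "a", "b", "c", "theta"]),
                     window_size=100, step=200)


def test_snp_window_value_takes_higher_window():
    windows = [
        WindowFst("1", 1, 50_000, 3, 0.2, 0.1),
        WindowFst("1", 25_001, 75_000, 4, 0.54, 0.3),
    ]
    assert snp_window_value("1", 30_000, windows) == pytest.approx(0.54)
    assert snp_window_value("1", 10_000, windows) == pytest.approx(0.2)
    with pytest.raises(MissingWindowError):
        snp_window_value("1", 90_000, windows)
    with pytest.raises(MissingWindowError):
        snp_window_value("2", 30_000, windows)
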