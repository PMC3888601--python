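from math import comb, isclose

import pytest
from hypothesis import given, settings, strategies as st

from paranno.stats import (
    GroupEnrichment,
    Region,
    RegionSet,
    build_stats_report,
    enrichment_vs_expected,
    expected_by_status,
    fisher_exact,
    ppv,
    region_enrichment,
    region_enrichment_from_counts,
    region_of,
)
from paranno.variants import PositionError


@pytest.fixture
def ryr2_hotspots():
    return RegionSet(
        "RYR2",
        (
            Region("N-terminal hotspot", 77, 466, "hotspots"),
            Region("Central hotspot", 2246, 2534, "hotspots"),
            Region("Channel hotspot", 3778, 4959, "hotspots"),
        ),
        4967,
    )


def test_region_of(ryr2_hotspots):
    assert region_of(2420, ryr2_hotspots) == "Central hotspot"
    assert region_of(549, ryr2_hotspots) == "OUTSIDE"
    assert region_of(77, ryr2_hotspots) == "N-terminal hotspot"  # inclusive start
    assert region_of(466, ryr2_hotspots) == "N-terminal hotspot"  # inclusive end
    assert region_of(467, ryr2_hotspots) == "OUTSIDE"
    with pytest.raises(PositionError):
        region_of(0, ryr2_hotspots)
    with pytest.raises(PositionError):
        region_of(5000, ryr2_hotspots)


def test_region_set_invariants():
    with pytest.raises(ValueError, match="overlap"):
        RegionSet("G", (Region("a", 1, 10, "x"), Region("b", 10, 20, "x")), 30)
    with pytest.raises(ValueError, match="duplicate"):
        RegionSet("G", (Region("a", 1, 5, "x"), Region("a", 6, 9, "x")), 30)
    with pytest.raises(ValueError, match="outside"):
        RegionSet("G", (Region("a", 1, 50, "x"),), 30)


def test_expected_by_status_properties():
    exact, rounded = expected_by_status(100, (25, 25, 25, 25), 100)
    assert exact == (25.0, 25.0, 25.0, 25.0) and rounded == (25, 25, 25, 25)
    exact, _ = expected_by_status(37, (10, 20, 30, 40), 100)
    assert isclose(sum(exact), 37.0, abs_tol=1e-12)  # mass conservation, exact
    assert expected_by_status(0, (10, 90), 100)[1] == (0, 0)
    with pytest.raises(ValueError):
        expected_by_status(10, (5, 5), 100)  # counts must sum to length
    with pytest.raises(ValueError):
        expected_by_status(10, (), 0)


def test_enrichment_and_ppv_basics():
    assert enrichment_vs_expected(10, 10) == 1.0
    assert enrichment_vs_expected(7, 0) is None
    assert ppv(35, 0) == 100.0
    assert ppv(0, 0) is None
    # scale invariance of PPV
    assert ppv(3, 1) == ppv(300, 100)


def test_region_enrichment_uniform_is_one():
    rs = RegionSet("G", (Region("all", 1, 50, "g"),), 50)
    enr = region_enrichment(range(1, 51), rs)
    assert enr["g"].factor == 1.0
    assert "outside" not in enr


def test_region_enrichment_conservation_of_mass(ryr2_hotspots):
    """Factors weighted by length fractions sum to the total observed mass."""
    positions = [100, 200, 2300, 4000, 4100, 600, 1000]
    enr = region_enrichment(positions, ryr2_hotspots)
    mass = sum(g.observed_fraction for g in enr.values())
    assert isclose(mass, 1.0, abs_tol=1e-12)
    # factors weighted by length fractions average to 1 (up to factor rounding)
    weighted = sum(g.factor * g.length_fraction for g in enr.values())
    assert isclose(weighted, 1.0, abs_tol=0.02)


def test_region_enrichment_empty_is_na(ryr2_hotspots):
    enr = region_enrichment([], ryr2_hotspots)
    assert all(g.factor is None for g in enr.values())


def test_region_enrichment_counts_rejects_unknown_group(ryr2_hotspots):
    with pytest.raises(ValueError):
        region_enrichment_from_counts({"nope": 3}, ryr2_hotspots)


# --- Fisher's exact test vs full margin enumeration ------------------------

def fisher_enumeration(a, b, c, d):
    """Independent oracle: enumerate all tables with the observed margins and
    sum hypergeometric probabilities <= the observed table's."""
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, c1)
    def prob(x):
        return comb(r1, x) * comb(n - r1, c1 - x) / denom
    p_obs = prob(a)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-7))


def test_fisher_exact_known_tables():
    assert fisher_exact([[1, 0], [0, 1]]) == pytest.approx(1.0)
    assert fisher_exact([[5, 0], [0, 5]]) == pytest.approx(1 / 126)
    # enumeration for [[2,3],[4,1]]: margins 5/5, 6; p = 110/210
    assert fisher_enumeration(2, 3, 4, 1) == pytest.approx(110 / 210)
    assert fisher_exact([[2, 3], [4, 1]]) == pytest.approx(110 / 210)


def test_fisher_exact_rejects_bad_tables():
    with pytest.raises(ValueError):
        fisher_exact([[-1, 2], [3, 4]])
    with pytest.raises(ValueError):
        fisher_exact([[1.5, 2], [3, 4]])


@settings(derandomize=True, max_examples=150)
@given(
    a=st.integers(0, 10), b=st.integers(0, 10),
    c=st.integers(0, 10), d=st.integers(0, 10),
)
def test_fisher_exact_matches_enumeration(a, b, c, d):
    """Agreement with the brute-force oracle on all tables with total <= 40."""
    if a + b + c + d == 0:
        return
    assert fisher_exact([[a, b], [c, d]]) == pytest.approx(
        fisher_enumeration(a, b, c, d), abs=1e-9
    )


def test_build_stats_report_assembles(ryr2_hotspots):
    rep = build_stats_report(
        "RYR2", 4967, (139, 20, 71, 4737), (35, 1, 1, 238),
        regions=ryr2_hotspots,
        region_counts={"hotspots": 157, "outside": 118},
        fisher_table=[[35, 1], [104, 19]],
    )
    assert rep.total_annotated == 275
    assert sum(rep.expected_exact) == pytest.approx(275)
    assert rep.expected_rounded == (8, 1, 4, 262)
    assert rep.enrichment_paper_compat[0] == 4.4
    assert rep.region_enrichments["hotspots"].factor == 1.52
    assert 0 <= rep.fisher_p <= 1
    text = rep.render_text()
    assert "enrichment 4.4" in text and "1.52" in text
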