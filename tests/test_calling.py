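"""Pathway completeness calling, pair propagation, alphabet sizes."""

import itertools
import random

import pytest

from glycoscan.calling import (
    GenomeAlphabet,
    alphabet_size,
    call_genome,
    call_routes,
    presence_matrix,
    propagate_pairs,
)

from conftest import attributed_for_families


def route_families(reg, route_id):
    """One concrete family choice per step (first alternative)."""
    route = reg.route_map()[route_id]
    return [sorted(s.families)[0] for s in route.steps]


# ---------------------------------------------------------------------------
# independent brute-force oracle: enumerate every route x step x hit combo
# ---------------------------------------------------------------------------


def brute_force_present(attributed, reg, genome_id):
    hits = [h for h in attributed if h.genome_id == genome_id]
    present = set()
    for ns in reg.nucleotide_sugars.values():
        for route in ns.routes:
            complete = True
            for step in route.steps:
                found = False
                for fam in step.families:
                    for h in hits:
                        if h.resolved_gpe_id != fam:
                            continue
                        if (
                            h.allowed_pathways is not None
                            and ns.monosaccharide_id not in h.allowed_pathways
                        ):
                            continue
                        found = True
                if not found:
                    complete = False
            if complete:
                present.add(ns.monosaccharide_id)
    # closures, iterated naively until nothing changes
    while True:
        before = set(present)
        for a, b in reg.product_pairs:
            if a in present or b in present:
                present |= {a, b}
        for pre, prod in reg.precursor_pairs:
            if prod in present:
                present.add(pre)
        if present == before:
            return present


class TestCallRoutes:
    def test_complete_route_makes_sugar_present(self, reg):
        fams = route_families(reg, "udp-glca.a")
        ga = call_genome(attributed_for_families(reg, fams), reg, "G1")
        assert "glca" in ga.present
        assert ga.provenance["glca"] == "detected"

    def test_missing_step_means_absent_and_partial(self, reg):
        fams = route_families(reg, "udp-xyl.a")  # 4 steps
        dropped = fams[:-1]  # lose the decarboxylase
        ga = call_genome(attributed_for_families(reg, dropped), reg, "G1")
        assert "xyl" not in ga.present
        assert ("udp-xyl", 1) in ga.partial

    def test_alternative_families_both_satisfy_step(self, reg):
        """Non-orthologous enzymes: either uridylyltransferase completes the
        UDP-glucose activation step."""
        for fam in ("GPE00510", "GPE00530"):
            ga = call_genome(attributed_for_families(reg, [fam]), reg, "G1")
            assert "glc" in ga.present

    def test_either_route_suffices(self, reg):
        """TDP-6-deoxy-l-talose: reduction of the 4-keto intermediate or C4
        epimerization of TDP-l-rhamnose both work."""
        for rid in ("tdp-6d-l-tal.a", "tdp-6d-l-tal.b"):
            ga = call_genome(
                attributed_for_families(reg, route_families(reg, rid)), reg, "G1"
            )
            assert "6d-l-tal" in ga.present

    def test_empty_hits_empty_alphabet(self, reg):
        ga = call_genome([], reg, "G1")
        assert ga.present == set() and alphabet_size(ga) == 0

    def test_step_calls_record_supporting_proteins(self, reg):
        fams = route_families(reg, "udp-glca.a")
        attributed = attributed_for_families(reg, fams)
        calls = call_routes(attributed, reg, "G1")
        for sc in calls["udp-glca.a"]:
            assert sc.satisfied and sc.supporting_protein_ids


class TestPropagation:
    def test_product_implies_precursor(self, reg):
        """A complete tyvelose route also marks paratose present."""
        fams = route_families(reg, "cdp-tyv.a")
        ga = call_genome(attributed_for_families(reg, fams), reg, "G1")
        assert {"tyv", "par"} <= ga.present
        # and abequose rides along: it shares the paratose pathway
        assert "abe" in ga.present

    def test_product_pair_co_called(self, reg):
        fams = route_families(reg, "gdp-rha.a")
        ga = call_genome(attributed_for_families(reg, fams), reg, "G1")
        assert {"rha", "6d-tal"} <= ga.present

    def test_implied_provenance_distinguished(self, reg):
        fams = route_families(reg, "cdp-tyv.a")
        ga = call_genome(attributed_for_families(reg, fams), reg, "G1")
        assert ga.provenance["tyv"] == "detected"
        # paratose's own (identical) route is also complete -> detected;
        # bacillosamine from a planted legionaminic-acid route is implied only
        fams = route_families(reg, "cmp-leg5ac7ac.b")
        ga = call_genome(attributed_for_families(reg, fams), reg, "G1")
        assert ga.provenance["leg5ac7ac"] == "detected"
        assert ga.provenance["bac2ac4ac"] == "implied_precursor"

    def test_propagation_fixed_point(self, reg):
        fams = route_families(reg, "cdp-tyv.a") + route_families(reg, "udp-glca.a")
        ga = call_genome(attributed_for_families(reg, fams), reg, "G1")
        once = set(propagate_pairs(ga, reg).present)
        twice = set(propagate_pairs(propagate_pairs(ga, reg), reg).present)
        assert once == twice


class TestAlphabetSize:
    def test_dedup_across_nucleotide_forms(self, reg):
        """l-rhamnose made via both UDP and TDP routes counts once."""
        fams = route_families(reg, "udp-l-rha.a") + route_families(reg, "tdp-l-rha.a")
        ga = call_genome(attributed_for_families(reg, fams), reg, "G1")
        assert "l-rha" in ga.present
        assert alphabet_size(ga) == len(ga.present)
        both = [s.sugar_id for s in reg.sugars_of_mono("l-rha")]
        assert len(both) == 2  # two complete routes, one alphabet letter

    def test_monotonicity_adding_hits(self, reg):
        """Adding hits never removes a monosaccharide from the alphabet."""
        rng = random.Random(1)
        all_f = sorted(reg.hmm_families())
        fams: list[str] = []
        prev: set[str] = set()
        for _ in range(12):
            fams.append(rng.choice(all_f))
            ga = call_genome(attributed_for_families(reg, set(fams)), reg, "G1")
            assert prev <= ga.present
            prev = set(ga.present)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_random_hit_subsets_match_brute_force(self, reg, seed):
        """Calls equal an exhaustive route x step x hit enumeration."""
        rng = random.Random(seed)
        fams = rng.sample(sorted(reg.enzyme_families), k=rng.randint(1, 25))
        attributed = attributed_for_families(reg, fams)
        ga = call_genome(attributed, reg, "G1")
        assert ga.present == brute_force_present(attributed, reg, "G1")

    def test_full_family_set_matches_brute_force(self, reg):
        attributed = attributed_for_families(reg, sorted(reg.enzyme_families))
        ga = call_genome(attributed, reg, "G1")
        assert ga.present == brute_force_present(attributed, reg, "G1")
        assert ga.present == set(reg.monosaccharides)  # everything recoverable


def test_presence_matrix_shape(reg):
    ga1 = call_genome(
        attributed_for_families(reg, route_families(reg, "udp-glca.a"), "G1"), reg, "G1"
    )
    ga2 = call_genome([], reg, "G2")
    m = presence_matrix([ga1, ga2], reg)
    assert m.shape == (2, 55)
    assert m.loc["G1", "glca"] == 1 and m.loc["G2"].sum() == 0
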