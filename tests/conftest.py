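import pytest

from glycoscan.hits import ProteinHit
from glycoscan.registry import load_registry
from glycoscan.resolve import apply_context_rules, resolve_multi_profile


@pytest.fixture(scope="session")
def reg():
    return load_registry()


def make_hit(reg, gpe_id, protein_id="WP_000000001.1", genome_id="G1",
             margin=20.0, **kw):
    """A passing hit `margin` above the family's threshold (HMM or blast)."""
    fam = reg.enzyme_families[gpe_id]
    if fam.is_hmm:
        score = fam.threshold_bits + margin
        return ProteinHit(
            genome_id=genome_id, protein_id=protein_id, gpe_id=gpe_id,
            best1dom_bits=score, full_bits=score + 1.0, evalue=1e-50,
            passes_threshold=True, **kw,
        )
    return ProteinHit(
        genome_id=genome_id, protein_id=protein_id, gpe_id=gpe_id,
        similarity_pct=fam.blast_min_similarity + margin,
        coverage_pct=min(fam.blast_min_coverage + 5.0, 100.0),
        passes_threshold=True, **kw,
    )


def attributed_for_families(reg, families, genome_id="G1", features=None):
    """One passing, resolved, context-attributed hit per family id."""
    hits = [
        make_hit(reg, f, protein_id=f"WP_{i:09d}.1", genome_id=genome_id)
        for i, f in enumerate(sorted(families), start=1)
    ]
    return apply_context_rules(resolve_multi_profile(hits, reg), reg, features)
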