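"""Shared fixtures: a pea-like synthetic study generated once per session."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from rhizoquant import ncr_mining
from rhizoquant.synthetic_data import (
    generate_itraq,
    generate_ncr_corpus,
    generate_proteome,
    generate_psm_tables,
    preset,
)


@pytest.fixture(scope="session")
def pea_like_spec():
    return preset("pea-like", seed=1)


@pytest.fixture(scope="session")
def pea_like_proteome(pea_like_spec):
    return generate_proteome(pea_like_spec)


@pytest.fixture(scope="session")
def pea_like_psm(pea_like_spec, pea_like_proteome):
    proteome, _ = pea_like_proteome
    return generate_psm_tables(proteome, pea_like_spec)


@pytest.fixture(scope="session")
def pea_like_corpus(pea_like_spec):
    return generate_ncr_corpus(pea_like_spec)


@pytest.fixture(scope="session")
def pea_like_mining(pea_like_corpus):
    """Full NCR mining run over the pea-like corpus (tags -> candidates)."""
    corpus = pea_like_corpus
    tags = ncr_mining.build_tag_set(corpus.reference_alignment)
    hits = ncr_mining.tag_search(corpus.denovo_peptides, tags)
    orfs = ncr_mining.translate_contigs(corpus.contigs)
    candidates = ncr_mining.match_candidates(hits, orfs)
    return tags, hits, orfs, candidates
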