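"""Shared fixtures: planted-truth benchmark corpora, built once per session."""

from __future__ import annotations

import pytest

from cpscan.benchmarks import (
    clone_spec,
    evolution_spec,
    recovery_spec,
    similarity_spec,
)
from cpscan.mex import MexParams, extract_motifs
from cpscan.pipeline import build_cp_space
from cpscan.synthetic import generate

SESSION_SEED = 11


@pytest.fixture(scope="session")
def recovery_design():
    return recovery_spec(seed=SESSION_SEED)


@pytest.fixture(scope="session")
def recovery_corpus(recovery_design):
    records, truth, sites = generate(recovery_design.spec)
    return records, truth


@pytest.fixture(scope="session")
def recovery_motifs(recovery_corpus):
    """Per-family motif extraction over the recovery benchmark corpus."""
    records, _truth = recovery_corpus
    by_family: dict[str, list] = {}
    for r in records:
        by_family.setdefault(r.family, []).append(r)
    return {
        fam: extract_motifs(members, MexParams())
        for fam, members in sorted(by_family.items())
    }


@pytest.fixture(scope="session")
def evolution_design():
    return evolution_spec(seed=SESSION_SEED)


@pytest.fixture(scope="session")
def evolution_corpus(evolution_design):
    records, truth, sites = generate(evolution_design.spec)
    return records, truth, sites


@pytest.fixture(scope="session")
def evolution_space(evolution_corpus):
    records, _truth, _sites = evolution_corpus
    return build_cp_space(records)


@pytest.fixture(scope="session")
def similarity_design():
    return similarity_spec(seed=SESSION_SEED)


@pytest.fixture(scope="session")
def similarity_space(similarity_design):
    records, _truth, _sites = generate(similarity_design.spec)
    return build_cp_space(records)


@pytest.fixture(scope="session")
def clone_corpus():
    records, truth, _sites = generate(clone_spec(seed=SESSION_SEED))
    return records, truth
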