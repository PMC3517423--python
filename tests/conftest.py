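"""Shared fixtures: the default synthetic genome is generated once per session."""

from __future__ import annotations

import pytest

from phagearch.synthetic import SyntheticSpec, generate_genome, write_fixture


@pytest.fixture(scope="session")
def default_spec() -> SyntheticSpec:
    return SyntheticSpec()


@pytest.fixture(scope="session")
def fixture_genome(default_spec):
    """(GenomeRecord, TruthTable) for the default study conditions."""
    return generate_genome(default_spec)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, fixture_genome, default_spec):
    """The default fixture written to disk (FASTA + GFF3 + truth TSV)."""
    genome, truth = fixture_genome
    out = tmp_path_factory.mktemp("fixture")
    write_fixture(genome, truth, out, spec=default_spec)
    return out
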