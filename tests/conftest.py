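"""Shared fixtures: one default study bundle, searched once per session."""

from __future__ import annotations

import pytest

from marinepde import annotate, synthetic

#: One fixed bundle seed for the whole suite (the generator itself is
#: exercised across many seeds in test_synthetic).
BUNDLE_SEED = 11


@pytest.fixture(scope="session")
def bundle() -> synthetic.StudyBundle:
    return synthetic.make_study_bundle(seed=BUNDLE_SEED)


@pytest.fixture(scope="session")
def bundle_hits(bundle) -> dict[str, list]:
    """Internal-aligner hit tables per genome, identity-unfiltered so the
    same search serves annotation and the threshold sweep."""
    return {
        gid: annotate.search_proteome(bundle.proteomes[gid], bundle.refset,
                                      max_evalue=10.0)
        for gid in bundle.genome_ids
    }


@pytest.fixture(scope="session")
def bundle_annotations(bundle, bundle_hits) -> list[annotate.PDEAnnotation]:
    """Default-threshold annotations for every bundle genome."""
    out = []
    for gid in bundle.genome_ids:
        out.extend(
            annotate.annotate_from_hits(
                bundle_hits[gid], bundle.query_domains, bundle.refset,
                genome_id=gid,
            )
        )
    return out
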