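"""Shared fixtures and generators for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pteridosurvey.io import (
    AlignedSequenceSet,
    IncidenceMatrix,
    SurveyChecklist,
    TaxonRecord,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

BASES = "ACGT"


def random_alignment(
    rng: np.random.Generator,
    n_seqs: int,
    length: int,
    missing_fraction: float = 0.0,
) -> AlignedSequenceSet:
    """Uniform-random alignment, optionally peppered with gap/N/?."""
    rows = []
    for i in range(n_seqs):
        chars = [BASES[k] for k in rng.integers(0, 4, size=length)]
        if missing_fraction:
            miss = rng.random(length) < missing_fraction
            symbols = np.array(list("-N?"))
            for j in np.flatnonzero(miss):
                chars[j] = str(symbols[rng.integers(3)])
        rows.append("".join(chars))
    ids = tuple(f"sp{i:03d}" for i in range(n_seqs))
    return AlignedSequenceSet(ids, tuple(rows))


def make_checklist(
    taxon_to_specimens: dict[str, list[str]],
    flora: str = "site",
    **record_overrides,
) -> SurveyChecklist:
    """Minimal valid checklist: every taxon a terrestrial native species."""
    records = {}
    smap = {}
    sflora = {}
    for i, (taxon, specimens) in enumerate(sorted(taxon_to_specimens.items())):
        records[taxon] = TaxonRecord(
            name=taxon,
            rank="species",
            genus=record_overrides.get("genus", f"Genus{i:02d}"),
            family=record_overrides.get("family", "Dryopteridaceae"),
            growth_habits=frozenset({"terrestrial"}),
            native=True,
            floras=frozenset({flora}),
        )
        for sid in specimens:
            smap[sid] = taxon
            sflora[sid] = flora
    return SurveyChecklist(records, smap, sflora)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)


@pytest.fixture
def tiny_alignment() -> AlignedSequenceSet:
    return AlignedSequenceSet(
        ("a1", "a2", "b1", "c1"),
        (
            "ACGTACGTACGT",
            "ACGTACGTACGT",
            "ACGTACGTACGA",
            "TTTTACGTACGA",
        ),
    )


@pytest.fixture
def tiny_incidence() -> IncidenceMatrix:
    m = np.array(
        [
            [1, 1, 1, 1],
            [1, 0, 0, 0],
            [0, 1, 1, 0],
            [1, 1, 0, 1],
            [0, 0, 1, 0],
        ],
        dtype=np.int8,
    )
    return IncidenceMatrix(
        ("t1", "t2", "t3", "t4", "t5"),
        ("d1", "d2", "d3", "d4"),
        m,
    )
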