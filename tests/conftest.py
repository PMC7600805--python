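"""Shared fixtures: one medium synthetic genome (with its scan results) is
built once per session and reused by the unit tests; the acceptance tests
build their own scenario-specific genomes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from numt_atlas import (
    SimConfig,
    SimResult,
    filter_hits,
    records_from_hits,
    scan_numts,
    simulate_genome,
)


def overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def reciprocal_match(rec, truth, frac: float = 0.8) -> bool:
    """True if rec and truth overlap by >= frac of both intervals."""
    if rec.scaffold != truth.scaffold:
        return False
    o = overlap(rec.nuc_interval, truth.nuc_interval)
    lr = rec.nuc_interval[1] - rec.nuc_interval[0]
    lt = truth.nuc_interval[1] - truth.nuc_interval[0]
    return o >= frac * lr and o >= frac * lt


def match_truth(records, truth, frac: float = 0.8) -> dict:
    """Map record id -> matching TruthRecord (or None)."""
    out = {}
    for r in records:
        out[r.numt_id] = next((t for t in truth if reciprocal_match(r, t, frac)), None)
    return out


@dataclass
class SimBundle:
    result: SimResult
    hits: list
    records: list


@pytest.fixture(scope="session")
def bundle() -> SimBundle:
    """A 1 Mb genome with all feature types planted, scanned and filtered."""
    cfg = SimConfig(
        seed=11,
        n_scaffolds=2,
        scaffold_lengths=(500_000, 500_000),
        n_insertions=30,
        n_duplications=8,
        n_complex=4,
        n_te_background=40,
        n_genes=25,
    )
    res = simulate_genome(cfg)
    hits = filter_hits(scan_numts(res.mito, res.nuclear))
    return SimBundle(result=res, hits=hits, records=records_from_hits(hits))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
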