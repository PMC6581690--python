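"""Shared fixtures: small synthetic sequence universes and simulated
hybridizations, generated programmatically at fixed seeds."""

from __future__ import annotations

import numpy as np
import pytest

from fgarray.hyb_sim import (
    CommunityMix,
    HybModel,
    MixComponent,
    make_synthetic_pools,
    simulate_samples,
)
from fgarray.probe_design import (
    build_array_layout,
    generate_mm_probe,
    select_sequence_specific,
)
from fgarray.sequences import TargetSequence
from fgarray.specificity import SpecificityThresholds


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


@pytest.fixture(scope="session")
def pools():
    """4 gene families × 3 members at 98 % within-family identity, plus a
    divergent nontarget pool."""
    return make_synthetic_pools(
        n_families=4,
        members_per_family=3,
        within_family_identity=98.0,
        nontarget_divergence=40.0,
        gc_targets=(0.5,),
        seed=11,
        gene_length=240,
        nontargets_per_family=2,
    )


@pytest.fixture(scope="session")
def designed_probes(pools):
    """One sequence-specific probe per target (coarse candidate step for
    speed; the probes still pass the full screen)."""
    probes = []
    for t in pools.targets:
        probes.extend(
            select_sequence_specific(
                t, pools.nontargets, SpecificityThresholds(), k=1, step=10
            )
        )
    assert probes, "fixture universe must yield at least one probe"
    return probes


@pytest.fixture(scope="session")
def pm_mm_layout(designed_probes):
    """Array layout holding PM/MM pairs for the designed probes plus
    negative and CORS controls."""
    pairs = [generate_mm_probe(p, seed=500 + i) for i, p in enumerate(designed_probes)]
    probes = [q for pair in pairs for q in (pair.pm, pair.mm)]
    layout = build_array_layout(
        probes,
        {"negative_control": 8, "cors_control": 8},
        n_subarrays=2,
        seed=7,
    )
    return layout, pairs


@pytest.fixture(scope="session")
def present_absent_signals(pm_mm_layout, pools):
    """Hybridizations with the target community present (100 ng) and
    absent (carrier only), 3 replicates each."""
    layout, pairs = pm_mm_layout
    model = HybModel()
    mixes = {
        "present": CommunityMix(
            components=[MixComponent("targets", 100.0)],
            background=MixComponent("nontargets", 900.0),
        ),
        "absent": CommunityMix(
            background=MixComponent("nontargets", 1000.0),
        ),
    }
    sm = simulate_samples(
        layout, mixes, pools.pools, model, n_replicates=3, seed=21
    )
    return sm, pairs
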