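"""Synthetic community pools and hybridization-signal simulation.

The wet-lab evaluation experiments behind a functional gene array — dose
response of positive-call counts, PM/MM specificity checks, spike-in
sensitivity, and log-log quantitation — all reduce to one generative
model: a probe's expected signal is proportional to the amount of
complementary DNA in the hybridization mix, attenuated by how divergent
the best-matching strand is and by probe GC content (AT-rich duplexes
bind more weakly, so low-GC probes are less sensitive).

Expected specific signal of probe p under mix M:

    E[p] = gain · gc_factor(p) · Σ_seqs mass(seq) · yield(identity(p, seq))

with gc_factor(p) = (GC(p) / 0.5) ** gc_exponent, yield(100 %) = 1,
yield decaying geometrically (``crosshyb_decay`` per identity point below
100) and clamped to 0 below ``crosshyb_identity_floor``. Observed
intensity adds multiplicative lognormal noise (mean 1, CV ``noise_cv``),
additive Gaussian background, an optional per-array scale factor (what
CORS normalization removes), clipping at zero and a 16-bit saturation
ceiling. Negative controls receive background only; CORS probes receive a
fixed spike independent of the mix. Everything is deterministic under a
fixed seed.

Mix component masses are split equally over the sequences of their pool,
mimicking equal genome representation of the genes in a labeled extract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CrossRefError, DomainError
from .probe_design import ArrayLayout
from .sequences import GeneFamilyGroup, TargetSequence
from .specificity import best_identity

__all__ = [
    "MixComponent",
    "CommunityMix",
    "HybModel",
    "SignalMatrix",
    "SyntheticPools",
    "simulate_hybridization",
    "simulate_samples",
    "make_synthetic_pools",
]


@dataclass(frozen=True)
class MixComponent:
    pool_id: str
    mass_ng: float


@dataclass
class CommunityMix:
    """DNA mixture loaded on one array: spiked components plus an optional
    background carrier (soil community, salmon sperm, ...)."""

    components: list[MixComponent] = field(default_factory=list)
    background: MixComponent | None = None

    @property
    def total_ng(self) -> float:
        total = sum(c.mass_ng for c in self.components)
        if self.background:
            total += self.background.mass_ng
        return total

    def validate(self) -> None:
        for c in self.all_components():
            if not (math.isfinite(c.mass_ng) and c.mass_ng >= 0):
                raise DomainError(f"component {c.pool_id}: invalid mass {c.mass_ng}")
        if not self.total_ng > 0:
            raise DomainError("community mix has zero total mass")

    def all_components(self) -> list[MixComponent]:
        return self.components + ([self.background] if self.background else [])


@dataclass
class HybModel:
    """Hybridization response parameters.

    gain: intensity units per ng of perfectly matched target DNA.
    gc_exponent: exponent of the (GC/0.5) sensitivity factor; 4 gives a
        roughly order-of-magnitude gap between GC 0.37 and 0.63 probes.
    crosshyb_identity_floor: percent identity below which a strand
        contributes no signal.
    crosshyb_decay: fractional yield retained per identity point below
        100 %; the default 0.1**(1/10) puts yield(90 %) at 0.10, so a
        5-mismatch MM control reports ~10 % of its PM mate's signal.
    background_mean/background_sd: additive background (intensity units).
    noise_cv: CV of the multiplicative lognormal spot noise.
    saturation: intensity ceiling (16-bit scanner scale).
    cors_intensity: fixed spike given to CORS reference probes.
    array_scale_cv: CV of a per-array lognormal scale factor (labeling /
        scanning variation between arrays); 0 disables it.
    """

    gain: float = 2000.0
    gc_exponent: float = 4.0
    crosshyb_identity_floor: float = 85.0
    crosshyb_decay: float = 0.1 ** 0.1
    background_mean: float = 100.0
    background_sd: float = 25.0
    noise_cv: float = 0.1
    saturation: float = 65535.0
    cors_intensity: float = 5000.0
    array_scale_cv: float = 0.0
    seed: int | None = None

    def validate(self) -> None:
        for name in ("gain", "gc_exponent", "background_mean", "background_sd",
                     "noise_cv", "saturation", "cors_intensity", "array_scale_cv"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise DomainError(f"HybModel.{name} must be finite and nonnegative, got {v}")
        if not 0 <= self.noise_cv < 1:
            raise DomainError("noise_cv must be in [0, 1)")
        if not self.saturation > self.background_mean:
            raise DomainError("saturation must exceed background_mean")
        if not 0 <= self.crosshyb_identity_floor <= 100:
            raise DomainError("crosshyb_identity_floor must be a percent")
        if not 0 < self.crosshyb_decay <= 1:
            raise DomainError("crosshyb_decay must be in (0, 1]")

    def hybridization_yield(self, identity_pct: float) -> float:
        """Fractional signal yield of a strand at the given best identity."""
        if identity_pct < self.crosshyb_identity_floor:
            return 0.0
        return self.crosshyb_decay ** (100.0 - identity_pct)

    def gc_factor(self, gc_fraction: float) -> float:
        return (gc_fraction / 0.5) ** self.gc_exponent


@dataclass
class SignalMatrix:
    """Long-format probe × (sample, replicate) intensity table.

    ``data`` columns: probe_id, probe_class, subarray, sample, replicate,
    intensity. ``provenance`` records the generating model and seed.
    """

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample"]))

    @property
    def n_replicates(self) -> int:
        return int(self.data["replicate"].nunique())

    def validate(self) -> None:
        vals = self.data["intensity"].to_numpy()
        if not np.all(np.isfinite(vals)) or (vals < 0).any():
            raise DomainError("intensities must be finite and nonnegative")
        for (sample, rep, sub), grp in self.data.groupby(["sample", "replicate", "subarray"]):
            if not (grp["probe_class"] == "negative_control").any():
                raise DomainError(
                    f"subarray {sub} of array ({sample}, {rep}) has no negative controls"
                )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for k, v in self.provenance.items():
                fh.write(f"# {k}={v}\n")
            self.data.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignalMatrix":
        provenance = {}
        with open(path) as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("=")
                    provenance[key] = val
                    pos = fh.tell()
                else:
                    fh.seek(pos)
                    break
            data = pd.read_csv(fh, sep="\t")
        data["probe_id"] = data["probe_id"].astype(str)
        data["sample"] = data["sample"].astype(str)
        return cls(data=data, provenance=provenance)


@lru_cache(maxsize=200_000)
def _identity_pct(probe_seq: str, subject_seq: str) -> float:
    return best_identity(probe_seq, subject_seq).identity_pct


def _expected_specific(
    layout: ArrayLayout,
    mix: CommunityMix,
    pools: Mapping[str, Sequence[TargetSequence]],
    model: HybModel,
) -> np.ndarray:
    """Noise-free expected specific signal per layout probe (background,
    CORS spike, and noise excluded)."""
    expected = np.zeros(len(layout.probes))
    for comp in mix.all_components():
        if comp.pool_id not in pools:
            raise CrossRefError(f"mix references unknown pool '{comp.pool_id}'")
        pool = pools[comp.pool_id]
        if not pool or comp.mass_ng == 0:
            continue
        mass_per_seq = comp.mass_ng / len(pool)
        for i, probe in enumerate(layout.probes):
            if probe.probe_class in ("negative_control", "cors_control"):
                continue
            total_yield = sum(
                model.hybridization_yield(_identity_pct(probe.sequence, s.sequence))
                for s in pool
            )
            expected[i] += (
                model.gain
                * mass_per_seq
                * total_yield
                * model.gc_factor(probe.gc_fraction)
            )
    return expected


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative lognormal noise with mean exactly 1 and CV ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_hybridization(
    layout: ArrayLayout,
    mix: CommunityMix,
    pools: Mapping[str, Sequence[TargetSequence]],
    model: HybModel = HybModel(),
    n_replicates: int = 3,
    sample: str = "sample1",
    seed: int | None = None,
) -> SignalMatrix:
    """Simulate hybridizing one community mix to the array, in replicates.

    Seed precedence: explicit ``seed`` argument, then ``model.seed``.
    """
    return simulate_samples(
        layout, {sample: mix}, pools, model, n_replicates=n_replicates, seed=seed
    )


def simulate_samples(
    layout: ArrayLayout,
    mixes: Mapping[str, CommunityMix],
    pools: Mapping[str, Sequence[TargetSequence]],
    model: HybModel = HybModel(),
    n_replicates: int = 3,
    seed: int | None = None,
) -> SignalMatrix:
    """Simulate several samples (mixes) on identical arrays into one
    SignalMatrix. One array = one (sample, replicate)."""
    model.validate()
    rng = np.random.default_rng(seed if seed is not None else model.seed)
    n = len(layout.probes)
    classes = np.array([p.probe_class for p in layout.probes])
    is_neg = classes == "negative_control"
    is_cors = classes == "cors_control"
    rows = []
    for sample, mix in mixes.items():
        mix.validate()
        expected = _expected_specific(layout, mix, pools, model)
        expected[is_cors] = model.cors_intensity
        expected[is_neg] = 0.0
        for rep in range(1, n_replicates + 1):
            scale = _lognormal_factors(rng, model.array_scale_cv, 1)[0]
            spot_noise = _lognormal_factors(rng, model.noise_cv, n)
            background = rng.normal(model.background_mean, model.background_sd, n) \
                if model.background_sd > 0 else np.full(n, model.background_mean)
            raw = expected * scale * spot_noise + background * scale
            raw = np.clip(raw, 0.0, model.saturation)
            for i, p in enumerate(layout.probes):
                rows.append(
                    (
                        p.probe_id, p.probe_class,
                        layout.subarray_of[p.probe_id],
                        sample, rep, raw[i],
                    )
                )
    data = pd.DataFrame(
        rows,
        columns=["probe_id", "probe_class", "subarray", "sample", "replicate", "intensity"],
    )
    sm = SignalMatrix(
        data=data,
        provenance={"model": asdict(model), "seed": seed if seed is not None else model.seed},
    )
    sm.validate()
    return sm


# ---------------------------------------------------------------------------
# Synthetic sequence pools


@dataclass
class SyntheticPools:
    """Fixture universe for end-to-end runs: target gene families, their
    group structure, and a divergent nontarget background pool."""

    targets: list[TargetSequence]
    nontargets: list[TargetSequence]
    groups: list[GeneFamilyGroup]

    @property
    def pools(self) -> dict[str, list[TargetSequence]]:
        return {"targets": self.targets, "nontargets": self.nontargets}


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    """Random sequence with exact GC composition round(gc*length)/length
    (so the realized pool GC tracks the request tightly)."""
    n_gc = round(gc * length)
    strong = np.array(list("GC"))[rng.integers(0, 2, n_gc)]
    weak = np.array(list("AT"))[rng.integers(0, 2, length - n_gc)]
    bases = np.concatenate([strong, weak])
    return "".join(bases[rng.permutation(length)])


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Substitute exactly n_subs positions (chosen without replacement)
    with a uniformly drawn different base."""
    chars = list(seq)
    for pos in rng.choice(len(chars), size=n_subs, replace=False):
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[int(rng.integers(3))]
    return "".join(chars)


def _hamming_identity(a: str, b: str) -> float:
    matches = sum(x == y for x, y in zip(a, b))
    return 100.0 * matches / len(a)


def make_synthetic_pools(
    n_families: int = 6,
    members_per_family: int = 4,
    within_family_identity: float = 98.0,
    nontarget_divergence: float = 40.0,
    gc_targets: Sequence[float] = (0.5,),
    seed: int | None = None,
    gene_length: int = 300,
    nontargets_per_family: int = 2,
) -> SyntheticPools:
    """Generate target gene families and a divergent nontarget pool.

    Each family descends from a random ancestor drawn at one of the
    requested GC fractions (assigned round-robin). Members carry an exact
    per-member substitution load chosen so that realized pairwise
    identities land within ±2 points of ``within_family_identity``;
    nontargets are ancestor copies mutated to ``nontarget_divergence``
    percent substitutions (identity 100 − divergence to the family).
    Deterministic under seed.
    """
    if not (0 < within_family_identity <= 100):
        raise DomainError("within_family_identity must be in (0, 100]")
    if not (0 <= nontarget_divergence < 100):
        raise DomainError("nontarget_divergence must be in [0, 100)")
    for gc in gc_targets:
        if not 0.1 <= gc <= 0.9:
            raise DomainError(f"gc target {gc} outside the realizable range [0.1, 0.9]")
    rng = np.random.default_rng(seed)
    # per-member substitution rate q with pairwise identity
    # (1-q)^2 + q^2/3 = t  (two members differ unless untouched at a site,
    # or both mutated to the same base)
    t = within_family_identity / 100.0
    disc = 1.0 - (4.0 / 3.0) * (1.0 - t)
    q = (2.0 - 2.0 * math.sqrt(max(disc, 0.0))) / (8.0 / 3.0)
    n_member_subs = round(q * gene_length)
    n_nontarget_subs = round(nontarget_divergence / 100.0 * gene_length)

    targets: list[TargetSequence] = []
    nontargets: list[TargetSequence] = []
    groups: list[GeneFamilyGroup] = []
    for f in range(n_families):
        gc = gc_targets[f % len(gc_targets)]
        family = f"fam{f:02d}"
        ancestor = _random_sequence(rng, gene_length, gc)
        members = []
        for m in range(members_per_family):
            seq = _mutate(rng, ancestor, n_member_subs)
            tgt = TargetSequence(
                seq_id=f"{family}_g{m}", sequence=seq, gene_family=family
            )
            members.append(tgt)
        # generator contract: realized pairwise identities within ±2 of request
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                ident = _hamming_identity(members[i].sequence, members[j].sequence)
                if abs(ident - within_family_identity) > 2.0:
                    raise DomainError(
                        f"{family}: realized identity {ident:.1f} deviates >2 points "
                        f"from requested {within_family_identity}"
                    )
        targets.extend(members)
        groups.append(
            GeneFamilyGroup(
                family_id=family, member_ids=[m.seq_id for m in members]
            )
        )
        for k in range(nontargets_per_family):
            seq = _mutate(rng, ancestor, n_nontarget_subs)
            ident = _hamming_identity(seq, ancestor)
            if abs(ident - (100.0 - nontarget_divergence)) > 2.0:
                raise DomainError(
                    f"{family}: nontarget identity {ident:.1f} deviates >2 points"
                )
            nontargets.append(
                TargetSequence(seq_id=f"{family}_nt{k}", sequence=seq, gene_family="")
            )
    # generator contract: realized GC of each family stays near its target
    for f in range(n_families):
        gc = gc_targets[f % len(gc_targets)]
        fam_targets = [t for t in targets if t.gene_family == f"fam{f:02d}"]
        mean_gc = float(np.mean([t.gc_fraction for t in fam_targets]))
        if abs(mean_gc - gc) > 0.03:
            raise DomainError(
                f"fam{f:02d}: realized GC {mean_gc:.3f} deviates >0.03 from target {gc}"
            )
    return SyntheticPools(targets=targets, nontargets=nontargets, groups=groups)
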