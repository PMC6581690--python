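"""Probe enumeration, selection, legacy validation, PM/MM controls, layout.

The design path runs per target (or per gene-family group): enumerate all
candidate 50-mer windows, apply composition filters (GC range, homopolymer
cap, self-complementarity cap), screen each candidate against the
nontarget pool (and, for group probes, against the group members), and
keep the top-k passing candidates ranked by how far they sit from the
screening thresholds — probes far from every threshold are the most robust
to sequence-space the screen has not seen.

Mismatch (MM) control probes are built from a perfect-match (PM) probe by
cutting it into 5 equal segments and substituting one randomly chosen base
per segment, for exactly 5 mismatches (10 % of a 50-mer). On the array,
MM signal estimates nonspecific cross-hybridization for its PM mate, and
the PM/MM net-intensity ratio is the specificity call statistic.

The array layout assigns every probe to a subarray; each subarray must
contain at least one negative control (background estimation) and one
common-oligo reference standard, CORS (across-array normalization).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigError, DomainError, FormatError, PairingError
from .sequences import (
    GeneFamilyGroup,
    LegacyProbe,
    TargetSequence,
    PROBE_LENGTH,
)
from .specificity import (
    SpecificityReport,
    SpecificityThresholds,
    longest_stretch,
    screen_group_specific,
    screen_sequence_specific,
    self_complementary_stretch,
)
from .thermo import NNParameterSet, UNIFIED

logger = logging.getLogger("fgarray")

PROBE_CLASSES = (
    "sequence_specific",
    "group_specific",
    "pm_control",
    "mm_control",
    "positive_16S",
    "negative_control",
    "genome_control",
    "cors_control",
)

DESIGNED_CLASSES = ("sequence_specific", "group_specific")


@dataclass
class Probe:
    """A 50-mer array probe.

    ``source_id`` is the seq_id the probe was cut from (or the family_id
    for group-specific probes); ``start`` is its 0-based half-open start on
    that source. Control probes may omit provenance.
    """

    probe_id: str
    sequence: str
    probe_class: str
    source_id: str = ""
    start: int = 0
    report: SpecificityReport | None = None

    def __post_init__(self) -> None:
        if self.probe_class not in PROBE_CLASSES:
            raise DomainError(f"unknown probe class '{self.probe_class}'")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc_fraction(self) -> float:
        s = self.sequence
        return (s.count("G") + s.count("C")) / len(s)


@dataclass
class MismatchPair:
    """A PM probe and its 5-mismatch control."""

    pm: Probe
    mm: Probe
    mismatch_positions: list[int]
    seed: int | None = None


@dataclass
class CandidateFilters:
    """Composition filters applied before specificity screening."""

    gc_min_pct: float = 30.0
    gc_max_pct: float = 70.0
    max_homopolymer: int = 6
    max_self_revcomp: int = 12  # exclusive cap on self-reverse-complement stretch


@dataclass
class ArrayLayout:
    """Probes arranged into subarrays."""

    probes: list[Probe]
    subarray_of: dict[str, int]
    n_subarrays: int

    def validate(self) -> None:
        ids = [p.probe_id for p in self.probes]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate probe ids in layout")
        for k in range(self.n_subarrays):
            classes = {
                p.probe_class for p in self.probes if self.subarray_of[p.probe_id] == k
            }
            if "negative_control" not in classes:
                raise ConfigError(f"subarray {k} has no negative control")
            if "cors_control" not in classes:
                raise ConfigError(f"subarray {k} has no CORS control")


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def enumerate_candidates(
    target: TargetSequence,
    length: int = PROBE_LENGTH,
    filters: CandidateFilters | None = None,
    step: int = 1,
) -> list[Probe]:
    """All windows of ``length`` at the given step, filtered by GC range,
    homopolymer cap, and self-complementarity cap. Returns [] with a
    warning when the target is shorter than the probe length."""
    f = filters or CandidateFilters()
    seq = target.sequence
    if len(seq) < length:
        logger.warning(
            "target %s (%d nt) shorter than probe length %d; no candidates",
            target.seq_id, len(seq), length,
        )
        return []
    out: list[Probe] = []
    for start in range(0, len(seq) - length + 1, step):
        window = seq[start : start + length]
        gc_pct = 100.0 * (window.count("G") + window.count("C")) / length
        if not (f.gc_min_pct <= gc_pct <= f.gc_max_pct):
            continue
        if _max_homopolymer(window) > f.max_homopolymer:
            continue
        if self_complementary_stretch(window) >= f.max_self_revcomp:
            continue
        out.append(
            Probe(
                probe_id=f"{target.seq_id}:{start}",
                sequence=window,
                probe_class="sequence_specific",
                source_id=target.seq_id,
                start=start,
            )
        )
    return out


def specificity_margin(
    report: SpecificityReport, thresholds: SpecificityThresholds
) -> float:
    """Minimum over criteria of the normalized distance from the threshold
    (positive = safely inside). Probes maximizing this sit farthest from
    every screening boundary."""
    nt = report.vs_nontarget
    margins = [
        (thresholds.max_identity_pct - nt.max_identity_pct) / thresholds.max_identity_pct,
        (thresholds.max_stretch_bp - nt.max_stretch_bp) / thresholds.max_stretch_bp,
        (nt.min_dg_kcal - thresholds.min_dg_kcal) / abs(thresholds.min_dg_kcal),
    ]
    if report.vs_group is not None:
        g = report.vs_group
        margins += [
            (g.min_identity_pct - thresholds.group_min_identity_pct)
            / thresholds.group_min_identity_pct,
            (g.min_stretch_bp - thresholds.group_min_stretch_bp)
            / thresholds.group_min_stretch_bp,
            (thresholds.group_max_dg_kcal - g.max_dg_kcal)
            / abs(thresholds.group_max_dg_kcal),
        ]
    return min(margins)


def _select_top_k(
    candidates: list[tuple[Probe, float]], k: int
) -> list[Probe]:
    # rank: larger margin first, then leftmost start
    candidates.sort(key=lambda pm: (-pm[1], pm[0].start))
    return [p for p, _ in candidates[:k]]


def select_sequence_specific(
    target: TargetSequence,
    nontargets: Sequence[TargetSequence],
    thresholds: SpecificityThresholds = SpecificityThresholds(),
    k: int = 2,
    *,
    filters: CandidateFilters | None = None,
    params: NNParameterSet = UNIFIED,
    probe_length: int = PROBE_LENGTH,
    step: int = 1,
) -> list[Probe]:
    """Up to ``k`` sequence-specific probes for one target, each carrying
    its full specificity report. The nontarget pool is filtered to drop the
    target itself and anything sharing its gene family."""
    pool = [
        s for s in nontargets
        if s.seq_id != target.seq_id
        and not (target.gene_family and s.gene_family == target.gene_family)
    ]
    passing: list[tuple[Probe, float]] = []
    for cand in enumerate_candidates(target, probe_length, filters, step):
        report = screen_sequence_specific(
            cand.sequence, pool, thresholds,
            probe_id=cand.probe_id, params=params,
        )
        if report.passed:
            cand.report = report
            passing.append((cand, specificity_margin(report, thresholds)))
    if not passing:
        logger.info("target %s: no candidate passed specificity screening", target.seq_id)
    return _select_top_k(passing, k)


def select_group_specific(
    group: GeneFamilyGroup,
    targets: Sequence[TargetSequence],
    nontargets: Sequence[TargetSequence],
    thresholds: SpecificityThresholds = SpecificityThresholds(),
    k: int = 2,
    *,
    filters: CandidateFilters | None = None,
    params: NNParameterSet = UNIFIED,
    probe_length: int = PROBE_LENGTH,
    step: int = 1,
) -> list[Probe]:
    """Up to ``k`` group-specific probes covering every member of the
    group. Candidates are enumerated from the longest member (the
    reference member, which maximizes the candidate space); positions are
    reported on it."""
    if len(group.member_ids) < 2:
        raise DomainError(
            f"group {group.family_id}: group-specific design requires >=2 members"
        )
    by_id = {t.seq_id: t for t in targets}
    try:
        members = [by_id[m] for m in group.member_ids]
    except KeyError as e:
        raise DomainError(f"group {group.family_id}: unknown member {e}") from e
    reference = max(members, key=lambda t: (len(t.sequence), t.seq_id))
    member_ids = set(group.member_ids)
    pool = [
        s for s in nontargets
        if s.seq_id not in member_ids and s.gene_family != group.family_id
    ]
    passing: list[tuple[Probe, float]] = []
    for cand in enumerate_candidates(reference, probe_length, filters, step):
        report = screen_group_specific(
            cand.sequence, members, pool, thresholds,
            probe_id=f"{group.family_id}:{cand.start}", params=params,
        )
        if report.passed:
            probe = replace(
                cand,
                probe_id=f"{group.family_id}:{cand.start}",
                probe_class="group_specific",
                source_id=group.family_id,
                report=report,
            )
            passing.append((probe, specificity_margin(report, thresholds)))
    if not passing:
        logger.info("group %s: no candidate passed group screening", group.family_id)
    return _select_top_k(passing, k)


@dataclass
class LegacyValidation:
    valid: set[str]
    invalid: set[str]
    recycled_target_ids: set[str]
    covered_target_ids: set[str]  # targets covered by valid legacy probes


def validate_legacy_probes(
    legacy: Sequence[LegacyProbe],
    targets: Sequence[TargetSequence],
    nontargets: Sequence[TargetSequence],
    thresholds: SpecificityThresholds = SpecificityThresholds(),
    *,
    params: NNParameterSet = UNIFIED,
) -> LegacyValidation:
    """Revalidate a legacy probe set against the current sequence universe.

    A legacy probe stays valid iff (a) it still matches at least one
    current target exactly (a full-length stretch, i.e. verbatim
    containment on either strand) and (b) it still passes the nontarget
    screen. Targets covered only by invalid probes are returned for
    re-design; targets covered by valid probes need no new probes.
    """
    valid: set[str] = set()
    invalid: set[str] = set()
    covered_by_valid: set[str] = set()
    covered_by_invalid: set[str] = set()
    for lp in legacy:
        hits = [
            t.seq_id for t in targets
            if longest_stretch(lp.sequence, t.sequence) == len(lp.sequence)
        ]
        is_exact = bool(hits)
        hit_families = {t.gene_family for t in targets if t.seq_id in set(hits)}
        pool = [
            s for s in nontargets
            if s.seq_id not in set(hits)
            and not (s.gene_family and s.gene_family in hit_families)
        ]
        report = screen_sequence_specific(
            lp.sequence, pool, thresholds, probe_id=lp.probe_id, params=params
        )
        covered = set(hits) | lp.declared_target_ids
        if is_exact and report.passed:
            valid.add(lp.probe_id)
            covered_by_valid.update(covered)
        else:
            invalid.add(lp.probe_id)
            covered_by_invalid.update(covered)
    target_ids = {t.seq_id for t in targets}
    covered_by_valid &= target_ids
    recycled = (covered_by_invalid & target_ids) - covered_by_valid
    return LegacyValidation(
        valid=valid,
        invalid=invalid,
        recycled_target_ids=recycled,
        covered_target_ids=covered_by_valid,
    )


def generate_mm_probe(
    pm: Probe, seed: int | np.random.Generator | None = None
) -> MismatchPair:
    """Build the mismatch control for a PM probe: the probe is divided into
    5 equal segments and one position per segment, chosen uniformly,
    is substituted with a base drawn uniformly from the 3 alternatives.
    Deterministic under a fixed seed."""
    L = len(pm.sequence)
    if L % 5 != 0:
        raise DomainError(f"PM length {L} not divisible by 5")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seg = L // 5
    seq = list(pm.sequence)
    positions: list[int] = []
    for s in range(5):
        pos = s * seg + int(rng.integers(seg))
        alternatives = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = alternatives[int(rng.integers(3))]
        positions.append(pos)
    mm = Probe(
        probe_id=pm.probe_id + "_MM",
        sequence="".join(seq),
        probe_class="mm_control",
        source_id=pm.probe_id,
        start=pm.start,
    )
    pm_ctrl = replace(pm, probe_class="pm_control") if pm.probe_class not in (
        "pm_control",
    ) else pm
    return MismatchPair(
        pm=pm_ctrl,
        mm=mm,
        mismatch_positions=positions,
        seed=seed if isinstance(seed, int) else None,
    )


def _random_50mer(rng: np.random.Generator, length: int = PROBE_LENGTH) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def make_control_probes(
    controls_spec: Mapping[str, int],
    seed: int | np.random.Generator | None = None,
    length: int = PROBE_LENGTH,
    sequences: Mapping[str, Sequence[str]] | None = None,
) -> list[Probe]:
    """Instantiate control probes per class. Sequences may be supplied per
    class (e.g. real 16S probes); otherwise random 50-mers are generated
    (negative controls by construction match no biological target in the
    simulator, which assigns them background only)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[Probe] = []
    for cls, count in controls_spec.items():
        if cls not in PROBE_CLASSES or cls in DESIGNED_CLASSES:
            raise ConfigError(f"'{cls}' is not a control probe class")
        supplied = list(sequences.get(cls, [])) if sequences else []
        for i in range(count):
            seq = supplied[i] if i < len(supplied) else _random_50mer(rng, length)
            out.append(Probe(probe_id=f"{cls}_{i}", sequence=seq, probe_class=cls))
    return out


def build_array_layout(
    designed: Sequence[Probe],
    controls_spec: Mapping[str, int],
    n_subarrays: int = 4,
    seed: int | None = None,
    control_sequences: Mapping[str, Sequence[str]] | None = None,
) -> ArrayLayout:
    """Distribute designed probes and freshly instantiated controls over
    subarrays (round-robin after a seeded shuffle of the designed probes),
    guaranteeing every subarray holds >=1 negative control and >=1 CORS."""
    if n_subarrays < 1:
        raise ConfigError("need at least one subarray")
    for needed in ("negative_control", "cors_control"):
        if controls_spec.get(needed, 0) < n_subarrays:
            raise ConfigError(
                f"need at least {n_subarrays} {needed} probes "
                f"(one per subarray), got {controls_spec.get(needed, 0)}"
            )
    rng = np.random.default_rng(seed)
    controls = make_control_probes(controls_spec, rng, sequences=control_sequences)
    probes = list(designed)
    order = rng.permutation(len(probes))
    probes = [probes[i] for i in order]
    subarray_of: dict[str, int] = {}
    # controls first, round-robin per class, so the per-subarray guarantee holds
    counters: dict[str, int] = {}
    for p in controls:
        idx = counters.setdefault(p.probe_class, 0)
        subarray_of[p.probe_id] = idx % n_subarrays
        counters[p.probe_class] = idx + 1
    # MM controls are placed after everything else, on their PM mate's
    # subarray, so PM/MM ratios always compare against the same local
    # background
    deferred = [p for p in probes if p.probe_class == "mm_control"]
    j = 0
    for p in probes:
        if p.probe_class == "mm_control":
            continue
        if p.probe_id in subarray_of:
            raise ConfigError(f"duplicate probe id '{p.probe_id}'")
        subarray_of[p.probe_id] = j % n_subarrays
        j += 1
    for p in deferred:
        if p.probe_id in subarray_of:
            raise ConfigError(f"duplicate probe id '{p.probe_id}'")
        mate = subarray_of.get(p.source_id)
        subarray_of[p.probe_id] = mate if mate is not None else j % n_subarrays
        if mate is None:
            j += 1
    layout = ArrayLayout(
        probes=probes + controls, subarray_of=subarray_of, n_subarrays=n_subarrays
    )
    layout.validate()
    return layout


# ---------------------------------------------------------------------------
# TSV serialization


def write_probes_tsv(probes: Sequence[Probe], path: str | Path) -> None:
    cols = [
        "probe_id", "probe_class", "source_id", "start", "sequence",
        "nt_max_identity_pct", "nt_max_stretch_bp", "nt_min_dg_kcal",
        "grp_min_identity_pct", "grp_min_stretch_bp", "grp_max_dg_kcal",
        "passed",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for p in probes:
            r = p.report
            nt = r.vs_nontarget if r else None
            g = r.vs_group if r else None
            fh.write(
                "\t".join(
                    [
                        p.probe_id, p.probe_class, p.source_id, str(p.start), p.sequence,
                        f"{nt.max_identity_pct:.2f}" if nt else "",
                        str(nt.max_stretch_bp) if nt else "",
                        f"{nt.min_dg_kcal:.2f}" if nt else "",
                        f"{g.min_identity_pct:.2f}" if g else "",
                        str(g.min_stretch_bp) if g else "",
                        f"{g.max_dg_kcal:.2f}" if g else "",
                        ("1" if r.passed else "0") if r else "",
                    ]
                )
                + "\n"
            )


def read_probes_tsv(path: str | Path) -> list[Probe]:
    probes: list[Probe] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["probe_id", "probe_class"]:
            raise FormatError(f"{path}: not a probe TSV")
        for ln in fh:
            parts = ln.rstrip("\n").split("\t")
            row = dict(zip(header, parts))
            probes.append(
                Probe(
                    probe_id=row["probe_id"],
                    sequence=row["sequence"],
                    probe_class=row["probe_class"],
                    source_id=row.get("source_id", ""),
                    start=int(row["start"]) if row.get("start") else 0,
                )
            )
    return probes


def write_layout_tsv(layout: ArrayLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tprobe_class\tsubarray\tsequence\n")
        for p in layout.probes:
            fh.write(
                f"{p.probe_id}\t{p.probe_class}\t{layout.subarray_of[p.probe_id]}\t{p.sequence}\n"
            )


def read_layout_tsv(path: str | Path) -> ArrayLayout:
    probes: list[Probe] = []
    subarray_of: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["probe_id", "probe_class", "subarray", "sequence"]:
            raise FormatError(f"{path}: not a layout TSV")
        for ln in fh:
            pid, cls, sub, seq = ln.rstrip("\n").split("\t")
            probes.append(Probe(probe_id=pid, sequence=seq, probe_class=cls))
            subarray_of[pid] = int(sub)
    n_sub = max(subarray_of.values()) + 1 if subarray_of else 0
    layout = ArrayLayout(probes=probes, subarray_of=subarray_of, n_subarrays=n_sub)
    layout.validate()
    return layout


def pair_pm_mm(probes: Iterable[Probe]) -> list[tuple[Probe, Probe]]:
    """Match pm_control/mm_control probes by the ``_MM`` id convention."""
    by_id = {p.probe_id: p for p in probes}
    pairs = []
    for p in by_id.values():
        if p.probe_class == "pm_control":
            mate = by_id.get(p.probe_id + "_MM")
            if mate is None or mate.probe_class != "mm_control":
                raise PairingError(f"PM probe {p.probe_id} has no MM mate")
            pairs.append((p, mate))
    return pairs
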