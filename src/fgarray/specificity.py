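"""Cross-hybridization screening statistics and pass/fail criteria.

A candidate 50-mer is kept only if it is unlikely to hybridize to anything
but its intended target(s). Three statistics, computed between the probe
and every sequence in a pool, drive the decision:

* **identity** — percent identity of the best-scoring ungapped semi-global
  alignment of the probe along either strand of the subject;
* **stretch** — length of the longest exact common substring between the
  probe and either strand of the subject (long perfect stretches drive
  cross-hybridization even at low overall identity);
* **free energy** — nearest-neighbor ΔG°37 of the probe/subject duplex at
  the best-identity register (see :mod:`fgarray.thermo`).

Sequence-specific probes must stay *below* identity/stretch thresholds and
*above* a ΔG threshold against every nontarget (defaults <90 %, <20 bp,
>−35 kcal/mol, all strict). Group-specific probes must additionally bind
every member of their gene family strongly (defaults >94 %, >35 bp,
<−60 kcal/mol, strict). Boundary values fail: the criteria are applied
exactly as printed.

Pools at desk scale are scanned exactly — there is no heuristic seeding.
Identity uses a single numpy comparison over all registers (including
partial overlaps at the subject edges); stretch uses a suffix automaton of
the subject, built once per subject string and cached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import DomainError
from .sequences import TargetSequence, reverse_complement
from .thermo import NNParameterSet, UNIFIED, alignment_delta_g

logger = logging.getLogger("fgarray")

__all__ = [
    "SpecificityThresholds",
    "IdentityHit",
    "PoolStats",
    "GroupStats",
    "SpecificityReport",
    "best_identity",
    "best_identity_gapped",
    "longest_stretch",
    "screen_sequence_specific",
    "screen_group_specific",
    "write_report_tsv",
]

# criterion labels used in SpecificityReport.failed_criteria
NT_IDENTITY = "nontarget_identity"
NT_STRETCH = "nontarget_stretch"
NT_FREE_ENERGY = "nontarget_free_energy"
GRP_IDENTITY = "group_identity"
GRP_STRETCH = "group_stretch"
GRP_FREE_ENERGY = "group_free_energy"


@dataclass(frozen=True)
class SpecificityThresholds:
    """Screening thresholds. All comparisons are strict inequalities.

    Nontarget side (a probe passes when its worst-case statistic is on the
    safe side): identity < max_identity_pct, stretch < max_stretch_bp,
    minimum ΔG > min_dg_kcal. Group side (group-specific probes only):
    identity > group_min_identity_pct against every member, stretch >
    group_min_stretch_bp, maximum ΔG < group_max_dg_kcal.
    """

    max_identity_pct: float = 90.0
    max_stretch_bp: int = 20
    min_dg_kcal: float = -35.0
    group_min_identity_pct: float = 94.0
    group_min_stretch_bp: int = 35
    group_max_dg_kcal: float = -60.0

    def validate(self, probe_length: int = 50) -> None:
        if not (0 < self.max_identity_pct <= 100 and 0 < self.group_min_identity_pct <= 100):
            raise DomainError("identity thresholds must be in (0, 100]")
        if self.max_stretch_bp > probe_length or self.group_min_stretch_bp > probe_length:
            raise DomainError("stretch thresholds cannot exceed the probe length")
        if self.max_identity_pct >= self.group_min_identity_pct:
            raise DomainError(
                "nontarget identity threshold must be below the group identity threshold"
            )


@dataclass(frozen=True)
class IdentityHit:
    """Best ungapped register of a probe along a subject.

    ``subject_offset`` is the 0-based start of the aligned window on the
    searched strand (for strand '-', coordinates are on the
    reverse-complemented subject). ``shift`` may be negative when the probe
    overhangs the subject's left edge.
    """

    identity_pct: float
    matches: int
    subject_offset: int
    shift: int
    strand: str  # '+' or '-'


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def _register_matches(probe: np.ndarray, subject: np.ndarray) -> np.ndarray:
    """Match counts for every overlap register (shift -(L-1) .. M-1)."""
    L = probe.size
    pad = np.zeros(L - 1, dtype=np.uint8)  # sentinel: never matches a base
    padded = np.concatenate([pad, subject, pad])
    windows = sliding_window_view(padded, L)
    return (windows == probe).sum(axis=1)


def best_identity(probe: str, subject: str) -> IdentityHit:
    """Best ungapped semi-global identity of ``probe`` against either
    strand of ``subject``, as percent of probe length.

    All registers with any overlap are scored (matches / probe length), so
    an exact common substring of length k guarantees identity >= 100·k/L.
    Ties prefer the forward strand, then the smaller offset.
    """
    if not probe or not subject:
        raise DomainError("best_identity requires non-empty probe and subject")
    L = len(probe)
    p = _encode(probe)
    best: IdentityHit | None = None
    for strand, subj in (("+", subject), ("-", reverse_complement(subject))):
        counts = _register_matches(p, _encode(subj))
        idx = int(np.argmax(counts))  # first max = smallest shift
        m = int(counts[idx])
        if best is None or m > best.matches:
            shift = idx - (L - 1)
            best = IdentityHit(
                identity_pct=100.0 * m / L,
                matches=m,
                subject_offset=max(shift, 0),
                shift=shift,
                strand=strand,
            )
    return best


def best_identity_gapped(probe: str, subject: str) -> float:
    """Gap-tolerant identity: best local alignment (match +1, mismatch −1,
    gap −2) of the probe against either strand of the subject, with
    identity still defined as matched positions / probe length. Off the
    default screening path; use via ``screen_*(…, gapped=True)``."""
    if not probe or not subject:
        raise DomainError("best_identity_gapped requires non-empty inputs")
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-2,
        extend_gap_score=-2,
    )
    best = 0
    for subj in (subject, reverse_complement(subject)):
        alignments = aligner.align(probe, subj)
        if len(alignments) == 0:
            continue
        identities = alignments[0].counts().identities
        best = max(best, identities)
    return 100.0 * best / len(probe)


class _SuffixAutomaton:
    """Suffix automaton over a subject string; longest_match(t) returns the
    length of the longest substring of t that occurs in the subject."""

    __slots__ = ("next", "link", "length")

    def __init__(self, s: str) -> None:
        self.next: list[dict[str, int]] = [{}]
        self.link: list[int] = [-1]
        self.length: list[int] = [0]
        last = 0
        for ch in s:
            cur = len(self.next)
            self.next.append({})
            self.length.append(self.length[last] + 1)
            self.link.append(0)
            p = last
            while p != -1 and ch not in self.next[p]:
                self.next[p][ch] = cur
                p = self.link[p]
            if p != -1:
                q = self.next[p][ch]
                if self.length[p] + 1 == self.length[q]:
                    self.link[cur] = q
                else:
                    clone = len(self.next)
                    self.next.append(dict(self.next[q]))
                    self.length.append(self.length[p] + 1)
                    self.link.append(self.link[q])
                    while p != -1 and self.next[p].get(ch) == q:
                        self.next[p][ch] = clone
                        p = self.link[p]
                    self.link[q] = clone
                    self.link[cur] = clone
            last = cur

    def longest_match(self, t: str) -> int:
        v, cur, best = 0, 0, 0
        for ch in t:
            while v != 0 and ch not in self.next[v]:
                v = self.link[v]
                cur = self.length[v]
            if ch in self.next[v]:
                v = self.next[v][ch]
                cur += 1
                if cur > best:
                    best = cur
        return best


@lru_cache(maxsize=1024)
def _automaton(s: str) -> _SuffixAutomaton:
    return _SuffixAutomaton(s)


def longest_stretch(probe: str, subject: str) -> int:
    """Length of the longest exact common substring between ``probe`` and
    either strand of ``subject`` (0 if none)."""
    if not probe or not subject:
        raise DomainError("longest_stretch requires non-empty probe and subject")
    fwd = _automaton(subject).longest_match(probe)
    rev = _automaton(reverse_complement(subject)).longest_match(probe)
    return max(fwd, rev)


def self_complementary_stretch(sequence: str) -> int:
    """Longest substring of ``sequence`` whose reverse complement also
    occurs in it — long values mean the probe can fold back on itself or
    dimerize, competing with target hybridization."""
    if not sequence:
        raise DomainError("empty sequence")
    return _automaton(reverse_complement(sequence)).longest_match(sequence)


def _dg_at_best_register(
    probe: str, subject: str, hit: IdentityHit, params: NNParameterSet
) -> float:
    """ΔG of the probe/subject duplex at the best-identity register.

    Only the overlapping part of the register is evaluated (probe bases
    hanging off the subject cannot pair)."""
    subj = subject if hit.strand == "+" else reverse_complement(subject)
    L, M = len(probe), len(subj)
    p0 = max(0, -hit.shift)
    s0 = max(0, hit.shift)
    n = min(L - p0, M - s0)
    if n < 2:
        return 0.0
    # rounded to well below the 0.01 kcal/mol table resolution so that
    # strict threshold comparisons are not decided by float accumulation
    return round(alignment_delta_g(probe[p0 : p0 + n], subj[s0 : s0 + n], params), 6)


@dataclass
class PoolStats:
    """Worst-case statistics of a probe against the nontarget pool."""

    max_identity_pct: float = 0.0
    max_stretch_bp: int = 0
    min_dg_kcal: float = 0.0
    worst_identity_id: str | None = None
    worst_stretch_id: str | None = None
    worst_dg_id: str | None = None
    n_subjects: int = 0


@dataclass
class GroupStats:
    """Worst-case (weakest-binding) statistics of a group probe against its
    own group members."""

    min_identity_pct: float = 0.0
    min_stretch_bp: int = 0
    max_dg_kcal: float = 0.0
    worst_identity_id: str | None = None
    worst_stretch_id: str | None = None
    worst_dg_id: str | None = None
    n_members: int = 0


@dataclass
class SpecificityReport:
    probe_id: str
    vs_nontarget: PoolStats
    vs_group: GroupStats | None = None
    passed: bool = True
    failed_criteria: list[str] = field(default_factory=list)


def _scan_pool(
    probe: str,
    pool: Iterable[TargetSequence],
    params: NNParameterSet,
    gapped: bool = False,
) -> PoolStats:
    stats = PoolStats(min_dg_kcal=float("inf"))
    for subj in pool:
        hit = best_identity(probe, subj.sequence)
        identity = (
            best_identity_gapped(probe, subj.sequence) if gapped else hit.identity_pct
        )
        stretch = longest_stretch(probe, subj.sequence)
        dg = _dg_at_best_register(probe, subj.sequence, hit, params)
        if identity > stats.max_identity_pct or stats.worst_identity_id is None:
            stats.max_identity_pct = identity
            stats.worst_identity_id = subj.seq_id
        if stretch > stats.max_stretch_bp or stats.worst_stretch_id is None:
            stats.max_stretch_bp = stretch
            stats.worst_stretch_id = subj.seq_id
        if dg < stats.min_dg_kcal:
            stats.min_dg_kcal = dg
            stats.worst_dg_id = subj.seq_id
        stats.n_subjects += 1
    if stats.n_subjects == 0:
        stats.min_dg_kcal = 0.0
    return stats


def screen_sequence_specific(
    probe_sequence: str,
    nontargets: Sequence[TargetSequence],
    thresholds: SpecificityThresholds = SpecificityThresholds(),
    *,
    probe_id: str = "probe",
    probe_family: str | None = None,
    params: NNParameterSet = UNIFIED,
    gapped: bool = False,
) -> SpecificityReport:
    """Screen a probe against a nontarget pool.

    Sequences sharing the probe's gene family (``probe_family``) are
    excluded from the pool automatically; excluding the probe's own
    target(s) by seq_id is the caller's responsibility. All three
    statistics are always computed (the report is complete even when the
    first criterion already fails). An empty pool passes vacuously, with a
    warning.
    """
    pool = [
        s for s in nontargets
        if not (probe_family and s.gene_family and s.gene_family == probe_family)
    ]
    stats = _scan_pool(probe_sequence, pool, params, gapped=gapped)
    if stats.n_subjects == 0:
        logger.warning("probe %s: empty nontarget pool, specificity passes vacuously", probe_id)
    failed = []
    if not stats.max_identity_pct < thresholds.max_identity_pct:
        failed.append(NT_IDENTITY)
    if not stats.max_stretch_bp < thresholds.max_stretch_bp:
        failed.append(NT_STRETCH)
    if stats.n_subjects > 0 and not stats.min_dg_kcal > thresholds.min_dg_kcal:
        failed.append(NT_FREE_ENERGY)
    return SpecificityReport(
        probe_id=probe_id,
        vs_nontarget=stats,
        passed=not failed,
        failed_criteria=failed,
    )


def screen_group_specific(
    probe_sequence: str,
    group_members: Sequence[TargetSequence],
    nontargets: Sequence[TargetSequence],
    thresholds: SpecificityThresholds = SpecificityThresholds(),
    *,
    probe_id: str = "probe",
    probe_family: str | None = None,
    params: NNParameterSet = UNIFIED,
    gapped: bool = False,
) -> SpecificityReport:
    """Screen a group-specific probe: nontarget criteria as for
    sequence-specific probes, plus strong binding to every group member."""
    if len(group_members) < 2:
        raise DomainError(
            f"group-specific screening requires >=2 members, got {len(group_members)}"
        )
    report = screen_sequence_specific(
        probe_sequence, nontargets, thresholds,
        probe_id=probe_id, probe_family=probe_family, params=params, gapped=gapped,
    )
    grp = GroupStats(
        min_identity_pct=float("inf"), min_stretch_bp=10**9, max_dg_kcal=-float("inf")
    )
    for member in group_members:
        hit = best_identity(probe_sequence, member.sequence)
        identity = (
            best_identity_gapped(probe_sequence, member.sequence)
            if gapped else hit.identity_pct
        )
        stretch = longest_stretch(probe_sequence, member.sequence)
        dg = _dg_at_best_register(probe_sequence, member.sequence, hit, params)
        if identity < grp.min_identity_pct:
            grp.min_identity_pct = identity
            grp.worst_identity_id = member.seq_id
        if stretch < grp.min_stretch_bp:
            grp.min_stretch_bp = stretch
            grp.worst_stretch_id = member.seq_id
        if dg > grp.max_dg_kcal:
            grp.max_dg_kcal = dg
            grp.worst_dg_id = member.seq_id
        grp.n_members += 1
    failed = list(report.failed_criteria)
    if not grp.min_identity_pct > thresholds.group_min_identity_pct:
        failed.append(GRP_IDENTITY)
    if not grp.min_stretch_bp > thresholds.group_min_stretch_bp:
        failed.append(GRP_STRETCH)
    if not grp.max_dg_kcal < thresholds.group_max_dg_kcal:
        failed.append(GRP_FREE_ENERGY)
    report.vs_group = grp
    report.failed_criteria = failed
    report.passed = not failed
    return report


def write_report_tsv(reports: Sequence[SpecificityReport], path) -> None:
    """One row per probe with all six statistics, worst-case subject ids,
    pass flag, and failed criteria."""
    cols = [
        "probe_id",
        "nt_max_identity_pct", "nt_max_stretch_bp", "nt_min_dg_kcal",
        "nt_worst_identity_id", "nt_worst_stretch_id", "nt_worst_dg_id",
        "grp_min_identity_pct", "grp_min_stretch_bp", "grp_max_dg_kcal",
        "grp_worst_identity_id", "grp_worst_stretch_id", "grp_worst_dg_id",
        "passed", "failed_criteria",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in reports:
            nt, g = r.vs_nontarget, r.vs_group
            row = [
                r.probe_id,
                f"{nt.max_identity_pct:.2f}", str(nt.max_stretch_bp), f"{nt.min_dg_kcal:.2f}",
                nt.worst_identity_id or "", nt.worst_stretch_id or "", nt.worst_dg_id or "",
                f"{g.min_identity_pct:.2f}" if g else "",
                str(g.min_stretch_bp) if g else "",
                f"{g.max_dg_kcal:.2f}" if g else "",
                (g.worst_identity_id or "") if g else "",
                (g.worst_stretch_id or "") if g else "",
                (g.worst_dg_id or "") if g else "",
                "1" if r.passed else "0",
                ",".join(r.failed_criteria),
            ]
            fh.write("\t".join(row) + "\n")
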