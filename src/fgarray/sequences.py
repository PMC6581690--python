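"""Target sequences, gene-family groups, legacy probes, and strand utilities.

Probe design starts from a set of target coding sequences (the genes the
array should report on), optionally organised into gene-family groups for
group-specific probe design, plus a pool of nontarget background sequences
used for cross-hybridization screening. This module reads and validates
those inputs and provides the strand arithmetic the screening kernels need.

Only concrete bases {A, C, G, T} are accepted: probe selection and
nearest-neighbor free-energy computation both require fully specified
sequences, so IUPAC ambiguity codes are rejected at ingest rather than
expanded (resolving them is the caller's job).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import AlphabetError, CrossRefError, DomainError, FormatError

logger = logging.getLogger("fgarray")

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: default designed-probe length in bases
PROBE_LENGTH = 50


@dataclass
class TargetSequence:
    """A target gene sequence probes may be designed against.

    Attributes
    ----------
    seq_id : str
        Unique identifier (first whitespace-delimited FASTA header token).
    sequence : str
        Uppercase DNA over {A, C, G, T}.
    gene_family : str
        Gene family / group label; may be empty if unassigned.
    taxon_label : str
        Free-text organism annotation; may be empty.
    """

    seq_id: str
    sequence: str
    gene_family: str = ""
    taxon_label: str = ""

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc_fraction(self) -> float:
        s = self.sequence
        return (s.count("G") + s.count("C")) / len(s) if s else 0.0


@dataclass
class GeneFamilyGroup:
    """A named gene family whose members a group-specific probe must cover."""

    family_id: str
    member_ids: list[str] = field(default_factory=list)
    description: str = ""

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass
class LegacyProbe:
    """A probe carried over from a previous array version, pending
    revalidation against the current target and nontarget universe."""

    probe_id: str
    sequence: str
    declared_target_ids: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.sequence)


def _check_alphabet(seq: str, record_name: str) -> None:
    """Raise AlphabetError naming the record and the 1-based offending
    position. Ambiguity codes get an explicit message."""
    m = re.search("[^ACGT]", seq)
    if m is None:
        return
    pos = m.start() + 1
    ch = m.group()
    if ch in "NRYSWKMBDHV":
        raise AlphabetError(
            f"record '{record_name}': ambiguous base '{ch}' at position {pos}; "
            "ambiguity codes are not accepted (probe design requires concrete bases)"
        )
    raise AlphabetError(
        f"record '{record_name}': invalid character '{ch}' at position {pos}"
    )


def normalize_sequence(raw: str, record_name: str = "<sequence>") -> str:
    """Uppercase, convert RNA U to T, and enforce the {A,C,G,T} alphabet."""
    seq = raw.upper().replace("U", "T")
    _check_alphabet(seq, record_name)
    return seq


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a DNA string over {A, C, G, T}.

    An involution that preserves length and GC count.
    """
    _check_alphabet(sequence, "<sequence>")
    return sequence.translate(_COMPLEMENT)[::-1]


_KEYVAL_RE = re.compile(r"(\w+)=(\S+)")


def _parse_description(desc: str) -> dict[str, str]:
    """key=value pairs from a FASTA description (text after the id)."""
    return dict(_KEYVAL_RE.findall(desc))


def read_fasta(path: str | Path) -> list[TargetSequence]:
    """Read target sequences from FASTA.

    The first whitespace-delimited header token is the seq_id. ``key=value``
    pairs in the remaining description are parsed; ``family=`` sets
    gene_family and ``taxon=`` sets taxon_label. Sequences are uppercased
    and U is converted to T; any other non-ACGT character is an error.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    out: list[TargetSequence] = []
    seen: set[str] = set()
    for rec in records:
        seq = normalize_sequence(str(rec.seq), rec.id)
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate seq_id '{rec.id}'")
        seen.add(rec.id)
        meta = _parse_description(rec.description)
        out.append(
            TargetSequence(
                seq_id=rec.id,
                sequence=seq,
                gene_family=meta.get("family", ""),
                taxon_label=meta.get("taxon", ""),
            )
        )
    return out


def write_fasta(records: Iterable[TargetSequence], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA, embedding family/taxon as key=value pairs."""
    with open(path, "w") as fh:
        for rec in records:
            desc = ""
            if rec.gene_family:
                desc += f" family={rec.gene_family}"
            if rec.taxon_label:
                desc += f" taxon={rec.taxon_label}"
            fh.write(f">{rec.seq_id}{desc}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_group_manifest(
    path: str | Path, targets: Sequence[TargetSequence]
) -> list[GeneFamilyGroup]:
    """Read a two-column TSV (family_id, seq_id) assigning targets to groups.

    A header row is required; ``#`` comment lines are skipped. Member order
    within a group is first-seen. Rows referencing unknown seq_ids raise
    CrossRefError; duplicated (family_id, seq_id) rows are deduplicated with
    a warning. On conflict with a ``family=`` annotation from the FASTA
    description, the manifest wins (warning logged) and the target's
    gene_family is updated in place.
    """
    path = Path(path)
    known = {t.seq_id: t for t in targets}
    groups: dict[str, GeneFamilyGroup] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        return []
    header = lines[0].split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: expected a 2-column TSV with a header row")
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}: malformed row: {ln!r}")
        family_id, seq_id = parts[0].strip(), parts[1].strip()
        if seq_id not in known:
            raise CrossRefError(
                f"{path}: manifest references unknown seq_id '{seq_id}'"
            )
        grp = groups.setdefault(family_id, GeneFamilyGroup(family_id=family_id))
        if seq_id in grp.member_ids:
            logger.warning("manifest: duplicate row (%s, %s) ignored", family_id, seq_id)
            continue
        grp.member_ids.append(seq_id)
        tgt = known[seq_id]
        if tgt.gene_family and tgt.gene_family != family_id:
            logger.warning(
                "seq %s: FASTA family=%s overridden by manifest family %s",
                seq_id, tgt.gene_family, family_id,
            )
        tgt.gene_family = family_id
    return list(groups.values())


def read_legacy_probes(path: str | Path) -> list[LegacyProbe]:
    """Read legacy probes from FASTA; ``targets=`` in the description is a
    comma-separated list of declared target seq_ids."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        seq = normalize_sequence(str(rec.seq), rec.id)
        meta = _parse_description(rec.description)
        declared = set(filter(None, meta.get("targets", "").split(",")))
        out.append(LegacyProbe(probe_id=rec.id, sequence=seq, declared_target_ids=declared))
    return out


def validate_targets(targets: Sequence[TargetSequence], min_length: int = PROBE_LENGTH) -> None:
    """Enforce the target-set invariants: unique ids, minimum length."""
    seen: set[str] = set()
    for t in targets:
        if t.seq_id in seen:
            raise FormatError(f"duplicate seq_id '{t.seq_id}' in target set")
        seen.add(t.seq_id)
        if len(t.sequence) < min_length:
            raise DomainError(
                f"target '{t.seq_id}' is {len(t.sequence)} nt, shorter than the "
                f"probe length {min_length}"
            )
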