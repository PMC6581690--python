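"""Nearest-neighbor free-energy model for DNA duplexes.

Duplex stability is the third screening statistic (besides identity and
stretch length) used to decide whether a probe will cross-hybridize: a
probe passes the nontarget screen only if its most stable predicted duplex
with any nontarget is weaker (less negative ΔG) than the threshold, and a
group-specific probe must bind every group member more stably than the
group threshold.

ΔG°37 of a perfectly matched duplex is the sum of duplex-initiation terms
(one per terminal base pair) and one stacking term per dinucleotide step:

    ΔG(s) = init(s[0]) + init(s[-1]) + Σ_i stack(s[i:i+2])

The default parameters are the unified oligonucleotide nearest-neighbor
set (SantaLucia 1998), shipped as a TSV so alternative tables can be
swapped in.

For a probe aligned ungapped against a nontarget window, mismatched
positions are treated as contributing nothing and as breaking stacking:
ΔG is summed over maximal matched runs of length >= 2 only, with the
initiation terms charged once (at the outermost matched bases). A window
with no matched run of length >= 2 forms no stable duplex and gets ΔG = 0.
This is deliberately a coarse screen — tandem-mismatch and dangling-end
parameters are out of scope — matching how the screening thresholds were
originally calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .errors import ConfigError, DomainError
from .sequences import reverse_complement

__all__ = [
    "NNParameterSet",
    "load_parameter_set",
    "UNIFIED",
    "duplex_delta_g",
    "matched_runs",
    "alignment_delta_g",
]


@dataclass(frozen=True)
class NNParameterSet:
    """A nearest-neighbor ΔG°37 parameter table.

    stack_dg maps the 16 dinucleotide stacks (5'→3', top strand of a
    matched duplex) to kcal/mol; init_dg maps the terminal base to its
    duplex-initiation penalty.
    """

    stack_dg: dict[str, float]
    init_dg: dict[str, float]
    name: str = "custom"

    def validate(self) -> None:
        missing = {a + b for a in "ACGT" for b in "ACGT"} - set(self.stack_dg)
        if missing:
            raise ConfigError(f"parameter set '{self.name}' missing stacks: {sorted(missing)}")
        if set(self.init_dg) != set("ACGT"):
            raise ConfigError(f"parameter set '{self.name}' must define init terms for A,C,G,T")
        for k, v in self.stack_dg.items():
            if not v < 0:
                raise ConfigError(f"stack {k}: expected a stabilizing (negative) ΔG, got {v}")
        for k, v in self.init_dg.items():
            if not v > 0:
                raise ConfigError(f"init/{k}: expected a positive initiation penalty, got {v}")
        for st, v in self.stack_dg.items():
            rc = reverse_complement(st)
            if abs(self.stack_dg[rc] - v) > 1e-9:
                raise ConfigError(
                    f"complementary-stack symmetry violated: {st}={v} vs {rc}={self.stack_dg[rc]}"
                )


def load_parameter_set(path: str | Path | None = None, name: str | None = None) -> NNParameterSet:
    """Load a parameter table from TSV (columns: stack, dg; ``init/X`` rows
    carry initiation terms). With no path, loads the packaged unified table."""
    if path is None:
        src = resources.files("fgarray.data").joinpath("nn_unified_dg37.tsv")
        text = src.read_text()
        name = name or "unified-dG37"
    else:
        text = Path(path).read_text()
        name = name or Path(path).stem
    stacks: dict[str, float] = {}
    inits: dict[str, float] = {}
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#") or ln.lower().startswith("stack"):
            continue
        key, val = ln.split("\t")
        if key.startswith("init/"):
            inits[key[5:]] = float(val)
        else:
            stacks[key] = float(val)
    ps = NNParameterSet(stack_dg=stacks, init_dg=inits, name=name)
    ps.validate()
    return ps


#: the packaged unified oligonucleotide ΔG°37 table
UNIFIED = load_parameter_set()


def duplex_delta_g(sequence: str, params: NNParameterSet = UNIFIED) -> float:
    """ΔG°37 (kcal/mol) of the perfectly matched duplex formed by
    ``sequence`` and its complement. More negative = more stable."""
    if len(sequence) < 2:
        raise DomainError("duplex ΔG requires length >= 2")
    try:
        dg = params.init_dg[sequence[0]] + params.init_dg[sequence[-1]]
        for i in range(len(sequence) - 1):
            dg += params.stack_dg[sequence[i : i + 2]]
    except KeyError as e:
        raise DomainError(f"unknown base/stack {e} in sequence") from e
    return dg


def matched_runs(probe: str, window: str) -> list[tuple[int, int]]:
    """Maximal runs of consecutive matched positions (probe[i] == window[i])
    of length >= 2, as (start, end) half-open intervals."""
    if len(probe) != len(window):
        raise DomainError(
            f"alignment ΔG requires equal lengths, got {len(probe)} and {len(window)}"
        )
    runs: list[tuple[int, int]] = []
    start: int | None = None
    for i in range(len(probe) + 1):
        matched = i < len(probe) and probe[i] == window[i]
        if matched and start is None:
            start = i
        elif not matched and start is not None:
            if i - start >= 2:
                runs.append((start, i))
            start = None
    return runs


def alignment_delta_g(probe: str, window: str, params: NNParameterSet = UNIFIED) -> float:
    """ΔG°37 of the heteroduplex formed by ``probe`` and the target strand
    complementary to ``window``, aligned ungapped at equal length.

    Only stacks internal to matched runs (length >= 2) contribute;
    initiation is charged once, at the first base of the first run and the
    last base of the last run. Returns 0.0 when no run of length >= 2
    exists (no stable duplex).
    """
    runs = matched_runs(probe, window)
    if not runs:
        return 0.0
    dg = params.init_dg[probe[runs[0][0]]] + params.init_dg[probe[runs[-1][1] - 1]]
    for start, end in runs:
        for i in range(start, end - 1):
            dg += params.stack_dg[probe[i : i + 2]]
    return dg
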