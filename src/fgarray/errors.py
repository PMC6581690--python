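"""Exception hierarchy shared by all fgarray modules.

Errors are categorized so the CLI can map them to exit diagnostics:
input/format problems, alphabet violations, dangling references,
domain (precondition) violations, configuration problems, and
contract violations detected while processing otherwise-valid data.
"""


class FgArrayError(Exception):
    """Base class for all fgarray errors."""

    category = "error"


class FormatError(FgArrayError):
    """Malformed or empty input file."""

    category = "format"


class AlphabetError(FgArrayError):
    """Sequence contains a character outside {A, C, G, T}."""

    category = "alphabet"


class CrossRefError(FgArrayError):
    """An identifier refers to a record that does not exist."""

    category = "reference"


class DomainError(FgArrayError):
    """An operation was called outside its mathematical domain."""

    category = "domain"


class ConfigError(FgArrayError):
    """Invalid or infeasible configuration."""

    category = "config"


class ContractError(FgArrayError):
    """Data violates a structural contract (e.g. a subarray without
    negative controls)."""

    category = "contract"


class PairingError(FgArrayError):
    """A PM probe is missing its MM mate (or vice versa)."""

    category = "pairing"
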