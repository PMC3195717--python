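"""Exception hierarchy.

Exit-code mapping used by the CLI: InputError and subclasses -> 2,
NumericalError and subclasses -> 3.
"""


class DissipyError(Exception):
    """Base class for all package errors."""


class InputError(DissipyError):
    """Malformed or inconsistent user input (files, specs, ranges)."""


class FormatError(InputError):
    """Unparseable input text (e.g. bad PDB)."""


class SpecError(InputError):
    """Invalid region/annotation/fixture specification."""


class AlignmentError(InputError):
    """Mismatched time grids or residue counts between traces/curves."""


class PolicyError(InputError):
    """Invalid or underspecified detection policy."""


class GenerationError(InputError):
    """Synthetic fixture generation failed (e.g. infeasible packing)."""


class IndexErrorInput(InputError):
    """A residue index referenced an out-of-range or unknown residue."""


class NumericalError(DissipyError):
    """Numerical failure during integration or fitting."""


class IntegrationError(NumericalError):
    """Non-finite state encountered during time integration."""


class FitError(NumericalError):
    """Least-squares fit failed to converge or input is degenerate."""
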