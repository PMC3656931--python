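"""Exception hierarchy.

``InputError`` signals bad user-supplied data (malformed files, invalid
sequences, infeasible parameters); ``ContractError`` signals API misuse by
calling code (wrong enzyme scheme, unsorted fragments).  Both derive from
``RestfragError`` so the CLI can map any library failure to exit status 1.
"""


class RestfragError(Exception):
    """Base class for all errors raised by restfrag."""


class InputError(RestfragError):
    """Invalid user input: bad sequence characters, malformed tables, infeasible specs."""


class ContractError(RestfragError):
    """API precondition violated by the caller (e.g. wrong enzyme scheme)."""
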