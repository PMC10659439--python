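"""Exception hierarchy for rdgkit.

All library errors derive from :class:`RdgError` so callers (and the CLI)
can distinguish validation problems from programming errors.
"""


class RdgError(Exception):
    """Base class for all rdgkit errors."""


class AlphabetError(RdgError, ValueError):
    """Sequence contains characters outside A/C/G/U after normalization."""


class AnnotationError(RdgError, ValueError):
    """A branch annotation is inconsistent with the transcript sequence."""


class NotationParseError(RdgError, ValueError):
    """Compact branch notation could not be parsed.

    Attributes
    ----------
    offset : int
        0-based character offset of the first unparseable token.
    """

    def __init__(self, message: str, offset: int = 0):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


class UnsupportedShiftError(RdgError, ValueError):
    """Backward jump of 4+ nt cannot be interpreted as frameshifting."""


class PathExplosionError(RdgError, RuntimeError):
    """Path enumeration would exceed the requested limit."""

    def __init__(self, count: int, limit: int):
        super().__init__(
            f"graph contains {count} ribosome paths, exceeding limit {limit}; "
            "use count_paths() or raise the limit"
        )
        self.count = count
        self.limit = limit


class UnknownTranslonError(RdgError, KeyError):
    """Translon id not present in the graph."""


class PolicyError(RdgError, ValueError):
    """Operation requested on a node that does not support it."""


class RefMismatchError(RdgError, ValueError):
    """Variant reference allele disagrees with the transcript sequence."""

    def __init__(self, pos: int, expected: str, found: str):
        super().__init__(
            f"reference mismatch at position {pos}: variant says {expected!r}, "
            f"transcript has {found!r}"
        )
        self.pos = pos
        self.expected = expected
        self.found = found


class UnsupportedVariantError(RdgError, ValueError):
    """HGVS-like string uses a form outside the supported subset."""


class CdsAnchorError(RdgError, ValueError):
    """Edit destroys the CDS start used to anchor c. coordinates."""


class TooShortError(RdgError, ValueError):
    """Translon has no codons left after trimming."""


class UndefinedProbabilityError(RdgError, ZeroDivisionError):
    """Initiation probability undefined because no flux was observed."""


class IdentifiabilityError(RdgError, ValueError):
    """More free branch probabilities than independent observations."""

    def __init__(self, free_params, n_obs: int):
        super().__init__(
            f"{len(free_params)} free branch probabilities "
            f"({', '.join(map(str, free_params))}) cannot be identified from "
            f"{n_obs} translon efficiencies"
        )
        self.free_params = list(free_params)
        self.n_obs = n_obs


class UnknownFixtureError(RdgError, KeyError):
    """Requested fixture name is not recognized."""
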