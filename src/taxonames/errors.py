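"""Exception hierarchy shared by all taxonames modules.

Every error raised by the library derives from :class:`TaxonomyError`, so
pipeline code can catch a single base class. Match failures (no match /
ambiguous match) are deliberately *not* exceptions — see
:mod:`taxonames.match` — because unattended batch runs treat them as data.
"""

from __future__ import annotations


class TaxonomyError(Exception):
    """Base class for all taxonames errors."""


class DmpParseError(TaxonomyError):
    """A *.dmp line is not in the taxdump dialect."""

    def __init__(self, message: str, filename: str = "<string>", lineno: int = 0):
        super().__init__(f"{filename}:{lineno}: {message}")
        self.filename = filename
        self.lineno = lineno


class TaxdumpLoadError(TaxonomyError):
    """A mandatory taxdump file is missing or unreadable."""


class IntegrityError(TaxonomyError):
    """The loaded tables violate a structural invariant.

    Carries the offending tax_ids in :attr:`tax_ids`.
    """

    def __init__(self, message: str, tax_ids: list[int] | None = None):
        self.tax_ids = list(tax_ids or [])
        if self.tax_ids:
            message = f"{message} (tax_ids: {', '.join(map(str, self.tax_ids))})"
        super().__init__(message)


class UnknownTaxonError(TaxonomyError):
    """The tax_id is not current, merged or deleted — it is simply unknown."""

    def __init__(self, tax_id: int):
        super().__init__(f"unknown taxon id {tax_id}")
        self.tax_id = tax_id


class DeletedTaxonError(TaxonomyError):
    """The tax_id was removed from the taxonomy (delnodes.dmp)."""

    def __init__(self, tax_id: int):
        super().__init__(f"taxon id {tax_id} has been deleted from the taxonomy")
        self.tax_id = tax_id


class EmptyNameError(TaxonomyError):
    """A query string is empty or whitespace-only."""


class UnknownDivisionError(TaxonomyError):
    """A division name does not exist in the divisions table."""

    def __init__(self, name: str, valid: list[str]):
        super().__init__(
            f"unknown division {name!r}; valid divisions: {', '.join(sorted(valid))}"
        )
        self.name = name
        self.valid = sorted(valid)


class CacheVersionError(TaxonomyError):
    """The on-disk cache was written by an incompatible schema version."""

    def __init__(self, found: object, expected: object):
        super().__init__(
            f"cache schema version {found!r} is incompatible with expected "
            f"{expected!r}; rebuild the cache from the raw taxdump files"
        )
        self.found = found
        self.expected = expected


class ChecksumMismatchError(TaxonomyError):
    """A downloaded archive does not match its published checksum."""

    def __init__(self, expected: str, actual: str):
        super().__init__(f"checksum mismatch: expected {expected}, got {actual}")
        self.expected = expected
        self.actual = actual


class NotAnAncestorError(TaxonomyError):
    """`stop_at` is not on the lineage of the queried taxon."""

    def __init__(self, stop_at: object, taxon: object):
        super().__init__(f"{stop_at} is not an ancestor of {taxon}")
        self.stop_at = stop_at
        self.taxon = taxon
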