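"""Peril taxonomy: the fixed catalogue of loss-generating event classes.

Every matrix in the package is indexed against a :class:`PerilRegistry`, an
ordered catalogue of peril classes.  The packaged registry holds 19 generic
perils — 11 natural (geological/geomorphological, hydrological,
meteorological, biophysical/ecological, extraterrestrial origins) followed by
8 anthropogenic (technological, economical, social) — and its row order is the
canonical index order of every adjacency and interaction matrix, so that
outputs from different analyses line up cell for cell.

The registry ships as a TSV data file rather than hard-coded constants so
that users can extend the catalogue; an extended registry is no longer
*canonical* and the 19-peril structural invariants are only enforced for the
packaged file.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator

__all__ = [
    "Peril",
    "PerilRegistry",
    "TaxonomyError",
    "UnknownPerilError",
    "load_taxonomy",
    "resolve_id",
    "ALIASES",
]

logger = logging.getLogger(__name__)

#: Origins whose perils belong to the natural system, in catalogue order.
NATURAL_ORIGINS = (
    "geological/geomorphological",
    "hydrological",
    "meteorological",
    "biophysical/ecological",
    "extraterrestrial",
)
#: Origins whose perils belong to the anthropogenic system.
ANTHROPOGENIC_ORIGINS = ("technological", "economical", "social")

#: Alias map applied when resolving raw case-file tokens.  Historical case
#: encodings repeatedly write "ES" (economic shock/slowdown) for the peril the
#: taxonomy catalogues as EC, economic crisis; the token is treated as a
#: typographical alias.
ALIASES = {"ES": "EC"}

_alias_warned: set[str] = set()


class TaxonomyError(ValueError):
    """Malformed or inconsistent taxonomy data."""


class UnknownPerilError(KeyError):
    """A token does not resolve to any catalogued peril."""


@dataclass(frozen=True)
class Peril:
    """One peril class: a generic, loss-generating event category."""

    id: str
    name: str
    origin: str
    system: str

    def __post_init__(self) -> None:
        if len(self.id) != 2 or not self.id.isalpha() or not self.id.isupper():
            raise TaxonomyError(f"peril id must be two uppercase letters, got {self.id!r}")
        if self.origin in NATURAL_ORIGINS:
            expected = "natural"
        elif self.origin in ANTHROPOGENIC_ORIGINS:
            expected = "anthropogenic"
        else:
            raise TaxonomyError(f"unknown origin {self.origin!r} for peril {self.id}")
        if self.system != expected:
            raise TaxonomyError(
                f"peril {self.id}: origin {self.origin!r} implies system {expected!r}, "
                f"got {self.system!r}"
            )


class PerilRegistry:
    """Ordered, immutable catalogue of perils with id ↔ index bijection.

    Parameters
    ----------
    perils:
        Perils in canonical order.  Ids must be unique.
    canonical:
        True for the packaged 19-peril catalogue; enables the structural
        invariants (19 entries, 11 natural then 8 anthropogenic) that the
        historical analysis relies on.
    """

    def __init__(self, perils: list[Peril], canonical: bool = False):
        self._perils = tuple(perils)
        self._index = {p.id: i for i, p in enumerate(self._perils)}
        if len(self._index) != len(self._perils):
            seen: set[str] = set()
            dup = next(p.id for p in self._perils if p.id in seen or seen.add(p.id))
            raise TaxonomyError(f"duplicate peril id {dup!r} in registry")
        self.canonical = canonical
        if canonical:
            self._check_canonical()

    def _check_canonical(self) -> None:
        if len(self._perils) != 19:
            raise TaxonomyError(f"canonical registry must have 19 perils, got {len(self._perils)}")
        systems = [p.system for p in self._perils]
        if systems != ["natural"] * 11 + ["anthropogenic"] * 8:
            raise TaxonomyError("canonical registry must list 11 natural then 8 anthropogenic perils")

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._perils)

    def __iter__(self) -> Iterator[Peril]:
        return iter(self._perils)

    def __contains__(self, peril_id: str) -> bool:
        return peril_id in self._index

    def __getitem__(self, peril_id: str) -> Peril:
        try:
            return self._perils[self._index[peril_id]]
        except KeyError:
            raise UnknownPerilError(peril_id) from None

    # -- lookups ------------------------------------------------------------
    @property
    def n_perils(self) -> int:
        return len(self._perils)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(p.id for p in self._perils)

    def index_of(self, peril_id: str) -> int:
        try:
            return self._index[peril_id]
        except KeyError:
            raise UnknownPerilError(peril_id) from None

    def system(self, peril_id: str) -> str:
        return self[peril_id].system

    def origin(self, peril_id: str) -> str:
        return self[peril_id].origin

    def resolve(self, token: str, context: str | None = None) -> str:
        """Resolve a raw case-file token to a canonical peril id.

        Uppercases the token and applies the alias map (``ES`` → ``EC``).
        A warning is logged the first time each alias fires.
        """
        tok = token.strip().upper()
        if tok in ALIASES:
            canonical = ALIASES[tok]
            if tok not in _alias_warned:
                _alias_warned.add(tok)
                logger.warning("aliasing peril token %r to %r", tok, canonical)
            tok = canonical
        if tok not in self._index:
            where = f" in {context}" if context else ""
            raise UnknownPerilError(f"unknown peril token {token!r}{where}")
        return tok


def _packaged_path(name: str) -> Path:
    return Path(str(resources.files("cascadyn").joinpath("data", name)))


def load_taxonomy(path: str | Path | None = None, canonical: bool | None = None) -> PerilRegistry:
    """Load a peril registry from a taxonomy TSV.

    With no ``path`` the packaged 19-peril catalogue is loaded and marked
    canonical.  The file has columns ``id, name, origin, system``; lines
    starting with ``#`` are comments.
    """
    if path is None:
        path = _packaged_path("perils.tsv")
        if canonical is None:
            canonical = True
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        rows = [r for r in csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t")]
    if not rows:
        raise TaxonomyError(f"taxonomy file {path} contains no perils")
    required = {"id", "name", "origin", "system"}
    if rows and not required.issubset(rows[0].keys()):
        raise TaxonomyError(f"taxonomy file {path} missing columns {sorted(required - rows[0].keys())}")
    perils = [Peril(r["id"].strip(), r["name"].strip(), r["origin"].strip(), r["system"].strip())
              for r in rows]
    return PerilRegistry(perils, canonical=bool(canonical))


def resolve_id(token: str, registry: PerilRegistry | None = None, context: str | None = None) -> str:
    """Resolve a raw token against ``registry`` (packaged taxonomy if None)."""
    if registry is None:
        registry = load_taxonomy()
    return registry.resolve(token, context=context)
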