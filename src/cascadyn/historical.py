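"""Historical catastrophe encoding: case files → empirical adjacency matrix.

Each historical catastrophe is recorded as its chain-of-events reduced to a
list of directed peril pairs (source triggers target).  The packaged
transcription covers 29 infamous cascading disasters, from the 2011 Tohoku
earthquake-tsunami-nuclear sequence to the 2020 COVID-19 pandemic.

Because no one-to-one interaction recurs often enough across 29 cases to
support a frequency estimate, the empirical encoding is *binary*: the
adjacency cell (i, j) is set to a constant ad-hoc probability ``p`` if the
pair was observed in at least one case and to zero otherwise (the unweighted
union over cases).  Provenance — which cases cite which edge — is retained
separately for reporting.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .markov import ReducedAdjacency
from .taxonomy import PerilRegistry, UnknownPerilError, load_taxonomy

__all__ = [
    "CatastropheCase",
    "CaseParseError",
    "parse_case_file",
    "parse_raw_encoding",
    "write_case_file",
    "build_empirical_adjacency",
    "edge_provenance",
    "case_statistics",
    "packaged_case_path",
]

logger = logging.getLogger(__name__)

DEFAULT_P = 0.1

_RAW_PAIR_RE = re.compile(r"\(\s*([A-Za-z]{2})\s*[,;]\s*([A-Za-z]{2})\s*\)")


class CaseParseError(ValueError):
    """A case file is malformed or references unknown perils."""


@dataclass(frozen=True)
class CatastropheCase:
    """One catastrophe: an identifier, its initial trigger, and the ordered
    directed peril pairs of its observed chain-of-events.

    ``flagged_empty`` marks synthetic cases whose sampled chain died off
    immediately and therefore recorded no pairs; parsed historical cases must
    always carry at least one pair.
    """

    case_id: str
    name: str
    country: str
    trigger: str
    pairs: tuple[tuple[str, str], ...]
    flagged_empty: bool = False


def packaged_case_path() -> Path:
    return Path(str(resources.files("cascadyn").joinpath("data", "catastrophes.tsv")))


def parse_raw_encoding(text: str, registry: PerilRegistry,
                       context: str | None = None) -> tuple[tuple[str, str], ...]:
    """Parse the raw ``(XX, YY); (ZZ, WW)`` pair syntax.

    Accepts ``,`` or ``;`` as the in-pair separator (both occur in raw
    encodings), normalizes case and aliases, and preserves duplicates in
    order.
    """
    matches = _RAW_PAIR_RE.findall(text)
    if not matches and text.strip():
        raise CaseParseError(f"could not parse any pair from {text!r}"
                             + (f" in {context}" if context else ""))
    out = []
    for src, tgt in matches:
        out.append((registry.resolve(src, context=context),
                    registry.resolve(tgt, context=context)))
    return tuple(out)


def _parse_pair_tokens(text: str, registry: PerilRegistry, context: str) -> tuple[tuple[str, str], ...]:
    pairs = []
    for token in text.split("|"):
        token = token.strip()
        if not token:
            continue
        parts = re.split(r"[>,;\s]+", token)
        if len(parts) != 2:
            raise CaseParseError(f"malformed pair token {token!r} in {context}")
        pairs.append((registry.resolve(parts[0], context=context),
                      registry.resolve(parts[1], context=context)))
    return tuple(pairs)


def parse_case_file(path: str | Path | None = None,
                    registry: PerilRegistry | None = None) -> list[CatastropheCase]:
    """Parse a catastrophe case TSV into :class:`CatastropheCase` records.

    With no path, the packaged 29-case transcription is loaded.  The TSV has
    columns ``case_id, name, country, trigger, pairs`` (pairs as ``SRC>TGT``
    tokens separated by ``|``); ``#`` lines are comments.  Token
    normalization — uppercasing and the ``ES`` → ``EC`` alias — is applied
    here, and duplicates within a case are preserved as listed.
    """
    if registry is None:
        registry = load_taxonomy()
    if path is None:
        path = packaged_case_path()
    path = Path(path)
    cases: list[CatastropheCase] = []
    with path.open(encoding="utf-8") as fh:
        reader = csv.DictReader((ln for ln in fh if not ln.startswith("#")), delimiter="\t")
        for row in reader:
            case_id = (row.get("case_id") or "").strip()
            if not case_id:
                continue
            context = f"case {case_id!r}"
            try:
                trigger = registry.resolve(row["trigger"], context=context)
                pairs = _parse_pair_tokens(row.get("pairs", ""), registry, context)
            except UnknownPerilError as exc:
                raise CaseParseError(str(exc)) from exc
            if not pairs:
                raise CaseParseError(f"{context} lists no interaction pairs")
            cases.append(CatastropheCase(
                case_id=case_id,
                name=(row.get("name") or "").strip(),
                country=(row.get("country") or "").strip(),
                trigger=trigger,
                pairs=pairs,
            ))
    return cases


def write_case_file(cases: list[CatastropheCase], path: str | Path) -> None:
    """Write cases in the TSV dialect that :func:`parse_case_file` reads."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["case_id", "name", "country", "trigger", "pairs"])
        for case in cases:
            if not case.pairs:
                # immediately-absorbed synthetic cases carry no pairs and
                # cannot round-trip through the historical parser
                logger.info("skipping pair-less case %s on write", case.case_id)
                continue
            pair_text = "|".join(f"{s}>{t}" for s, t in case.pairs)
            writer.writerow([case.case_id, case.name, case.country, case.trigger, pair_text])


# ---------------------------------------------------------------------------
# empirical adjacency


def build_empirical_adjacency(cases: list[CatastropheCase], registry: PerilRegistry,
                              p: float = DEFAULT_P,
                              exclude_edges: set[tuple[str, str]] | None = None
                              ) -> ReducedAdjacency:
    """Binary union encoding: cell (i, j) = p iff (i, j) occurs in ≥ 1 case.

    Recurrence across cases does not increase the cell (unweighted adjacency);
    ``exclude_edges`` drops specific pairs, e.g. the extremely rare
    landslide-to-disease edge, before encoding.
    """
    if not 0 < p < 1:
        raise ValueError(f"p must lie in (0, 1), got {p}")
    excluded = {tuple(e) for e in (exclude_edges or set())}
    n = registry.n_perils
    values = np.zeros((n, n))
    for case in cases:
        for src, tgt in case.pairs:
            if (src, tgt) in excluded:
                continue
            values[registry.index_of(src), registry.index_of(tgt)] = p
    return ReducedAdjacency(registry.ids, values)


def edge_provenance(cases: list[CatastropheCase]) -> dict[tuple[str, str], list[str]]:
    """Map each directed pair to the sorted case_ids citing it."""
    prov: dict[tuple[str, str], set[str]] = {}
    for case in cases:
        for pair in case.pairs:
            prov.setdefault(pair, set()).add(case.case_id)
    return {pair: sorted(ids) for pair, ids in sorted(prov.items())}


def case_statistics(cases: list[CatastropheCase]) -> dict:
    """Deterministic summary counts over a case list."""
    distinct_pairs: set[tuple[str, str]] = set()
    trigger_counts: dict[str, int] = {}
    total_pairs = 0
    for case in cases:
        distinct_pairs.update(case.pairs)
        total_pairs += len(case.pairs)
        trigger_counts[case.trigger] = trigger_counts.get(case.trigger, 0) + 1
    return {
        "n_cases": len(cases),
        "n_distinct_pairs": len(distinct_pairs),
        "n_listed_pairs": total_pairs,
        "trigger_counts": dict(sorted(trigger_counts.items())),
    }
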